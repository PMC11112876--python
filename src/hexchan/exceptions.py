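"""Exception hierarchy for hexchan."""


class HexchanError(Exception):
    """Base class for all hexchan errors."""


class PDBParseError(HexchanError):
    """A PDB record could not be parsed (message names the offending line)."""


class StructureError(HexchanError):
    """Frames of a multi-model file do not share the same atom set."""


class PDBFormatError(HexchanError):
    """A trajectory cannot be represented in fixed-column PDB format."""


class SelectionError(HexchanError):
    """An atom selection required by a metric resolved to nothing."""


class MoietyError(HexchanError):
    """A residue has no terminal-moiety definition or is missing moiety atoms."""


class ConfigError(HexchanError):
    """Invalid channel or run configuration."""
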