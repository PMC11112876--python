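"""Hemichannel metrics: salt-bridge occupancy, TM geometry, pocket hydration.

These are the analyses that characterise the intracellular pocket of a
connexin-like hexameric hemichannel:

* **Salt bridges** — per-frame distance between the mass-weighted centers of
  the terminal side-chain moieties of a residue pair (guanidinium of Arg,
  carboxylate of Glu/Asp, amide of Gln, amine of Lys).  A pair is "at an
  interacting distance" when that distance is <= 4 Å; the occupancy of a
  bridge is the fraction of frames satisfying the criterion, and a protomer
  "forms" the bridge when occupancy >= 0.5 (configurable).
* **TM geometry** — the TM1–TM3 and TM2–TM4 distances, measured between the
  Cα atoms of one representative residue per helix (25/159 and 85/220: the
  residues closest to each helix's center of mass), and the inclination of
  TM2/TM3/TM4 relative to TM1, measured between total-least-squares axes
  through all Cα of each segment.
* **Pocket hydration** — the number of water molecules whose oxygen lies
  within 6.0 Å of the center of mass of the Cα atoms of the 30 pocket-lining
  residues of a protomer; a proxy for the pocket volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import ConfigError, MoietyError, SelectionError
from .geometry import (
    DistanceSeries,
    axis_angle,
    center_of_mass,
    fit_axis,
    pair_distance_series,
)
from .structure_io import Frame, Trajectory, select, water_oxygen_indices

logger = logging.getLogger(__name__)

#: Residues lining the intracellular pocket (PDB numbering): N9, E12, E13, E16,
#: S18, R23, L26, T27, F30, R33, I34, Q81, V85, S86, P88, S89, Y92, V93, L148,
#: Y151, H154, I155, K158, T159, E162, S216, L219, N220, E223, L227.
DEFAULT_POCKET_RESIDUES: tuple[int, ...] = (
    9, 12, 13, 16, 18, 23, 26, 27, 30, 33, 34,
    81, 85, 86, 88, 89, 92, 93,
    148, 151, 154, 155, 158, 159, 162,
    216, 219, 220, 223, 227,
)

#: Terminal-moiety heavy atoms per residue type.  Arg: guanidinium (with NE);
#: Glu/Asp: carboxylate including the carbon center; Gln: amide; Lys: amine.
DEFAULT_MOIETY_MAP: Mapping[str, tuple[str, ...]] = {
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "GLU": ("CD", "OE1", "OE2"),
    "GLN": ("CD", "OE1", "NE2"),
    "LYS": ("NZ",),
    "ASP": ("CG", "OD1", "OD2"),
}

DEFAULT_REPRESENTATIVE_RESIDUES: Mapping[str, int] = {
    "TM1": 25, "TM2": 85, "TM3": 159, "TM4": 220,
}

#: Residue pairs whose salt bridges organise the pocket: 33-162, 158-223, 158-162.
DEFAULT_BRIDGE_PAIRS: tuple[tuple[int, int], ...] = ((33, 162), (158, 223), (158, 162))

TM_DISTANCE_PAIRS: Mapping[str, tuple[str, str]] = {
    "TM1-TM3": ("TM1", "TM3"),
    "TM2-TM4": ("TM2", "TM4"),
}


@dataclass
class ChannelDefinition:
    """Geometry/threshold configuration of one hexameric channel.

    ``tm_segments`` has no universal default: helix boundaries are a property
    of the particular structure and must be supplied (the synthetic generator
    writes its own).
    """

    tm_segments: Mapping[str, tuple[int, int]]
    protomer_chains: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    representative_residues: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPRESENTATIVE_RESIDUES)
    )
    pocket_residues: tuple[int, ...] = DEFAULT_POCKET_RESIDUES
    bridge_cutoff: float = 4.0
    water_cutoff: float = 6.0
    occupancy_threshold: float = 0.5
    moieties: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOIETY_MAP)
    )

    def __post_init__(self) -> None:
        if len(self.protomer_chains) != 6:
            raise ConfigError("a hemichannel has exactly 6 protomer chains")
        if self.bridge_cutoff <= 0 or self.water_cutoff <= 0:
            raise ConfigError("distance cutoffs must be positive")
        if not 0 <= self.occupancy_threshold <= 1:
            raise ConfigError("occupancy threshold must lie in [0, 1]")
        segs = {k: (int(v[0]), int(v[1])) for k, v in self.tm_segments.items()}
        for name, (lo, hi) in segs.items():
            if lo > hi:
                raise ConfigError(f"{name}: empty residue range {lo}-{hi}")
        spans = sorted(segs.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise ConfigError("TM segments must be disjoint")
        for tm, res in self.representative_residues.items():
            if tm in segs:
                lo, hi = segs[tm]
                if not lo <= res <= hi:
                    raise ConfigError(
                        f"representative residue {res} of {tm} outside range {lo}-{hi}"
                    )
        self.tm_segments = segs

    def to_json(self, path: str) -> None:
        data = {
            "tm_segments": {k: list(v) for k, v in self.tm_segments.items()},
            "protomer_chains": list(self.protomer_chains),
            "representative_residues": dict(self.representative_residues),
            "pocket_residues": list(self.pocket_residues),
            "bridge_cutoff": self.bridge_cutoff,
            "water_cutoff": self.water_cutoff,
            "occupancy_threshold": self.occupancy_threshold,
            "moieties": {k: list(v) for k, v in self.moieties.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ChannelDefinition":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(
                tm_segments={k: tuple(v) for k, v in data["tm_segments"].items()},
                protomer_chains=tuple(data.get("protomer_chains", "ABCDEF")),
                representative_residues=dict(
                    data.get("representative_residues", DEFAULT_REPRESENTATIVE_RESIDUES)
                ),
                pocket_residues=tuple(
                    data.get("pocket_residues", DEFAULT_POCKET_RESIDUES)
                ),
                bridge_cutoff=float(data.get("bridge_cutoff", 4.0)),
                water_cutoff=float(data.get("water_cutoff", 6.0)),
                occupancy_threshold=float(data.get("occupancy_threshold", 0.5)),
                moieties={
                    k: tuple(v)
                    for k, v in data.get("moieties", DEFAULT_MOIETY_MAP).items()
                },
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid channel definition: {exc}") from exc


@dataclass
class BridgeReport:
    """Salt-bridge distance series and its occupancy classification."""

    pair: tuple[str, int, str, int]  # chainA, residueA, chainB, residueB
    series: DistanceSeries
    cutoff: float
    occupancy: float
    bridged: bool

    @property
    def mean(self) -> float:
        return self.series.mean

    @property
    def sd(self) -> float:
        return self.series.sd

    @property
    def median(self) -> float:
        return self.series.median


@dataclass
class CountSeries:
    """Per-frame per-protomer water counts, optionally pooled over replicas.

    ``counts`` has shape (n_replicas, n_frames, n_protomers).  ``per_frame_mean``
    and ``per_frame_sd`` aggregate across replicas with the sample (n-1)
    estimator; ``pooled`` concatenates all frames from all replicas and
    protomers.
    """

    counts: np.ndarray
    times_ps: np.ndarray
    protomers: tuple[str, ...]

    @property
    def per_frame_mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def per_frame_sd(self) -> np.ndarray:
        if self.counts.shape[0] < 2:
            return np.zeros_like(self.counts[0], dtype=float)
        return self.counts.std(axis=0, ddof=1)

    @property
    def pooled(self) -> np.ndarray:
        return self.counts.reshape(-1)


def _moiety_indices(
    traj: Trajectory, chanl: ChannelDefinition, chain: str, residue_number: int
) -> np.ndarray:
    """Indices of the terminal-moiety atoms of one residue; loud failures."""
    res_idx = select(traj.topology, chain=chain, residue_numbers=[residue_number])
    if res_idx.size == 0:
        raise SelectionError(f"residue {chain}:{residue_number} not found")
    resname = str(traj.topology.residue_name[res_idx[0]]).upper()
    if resname not in chanl.moieties:
        raise MoietyError(
            f"residue {chain}:{residue_number} ({resname}) has no terminal-moiety "
            f"definition; known types: {sorted(chanl.moieties)}"
        )
    wanted = chanl.moieties[resname]
    idx = select(
        traj.topology, chain=chain, residue_numbers=[residue_number], atom_names=wanted
    )
    present = {str(traj.topology.atom_name[i]) for i in idx}
    missing = [a for a in wanted if a not in present]
    if missing:
        raise MoietyError(
            f"residue {chain}:{residue_number} ({resname}) is missing moiety "
            f"atoms {missing}"
        )
    return idx


def saltbridge_series(
    traj: Trajectory,
    chanl: ChannelDefinition,
    resA: tuple[str, int],
    resB: tuple[str, int],
) -> BridgeReport:
    """Distance between terminal-moiety centers of mass of two residues.

    Residues may lie on the same or on different chains (inter-protomer
    contacts are legal).  Occupancy is the fraction of frames at distance
    <= ``bridge_cutoff``; the pair is classified as bridged when occupancy
    reaches ``occupancy_threshold``.
    """
    ia = _moiety_indices(traj, chanl, *resA)
    ib = _moiety_indices(traj, chanl, *resB)
    series = pair_distance_series(traj, ia, ib, mode="com")
    occupancy = float(np.mean(series.values <= chanl.bridge_cutoff))
    return BridgeReport(
        pair=(resA[0], resA[1], resB[0], resB[1]),
        series=series,
        cutoff=chanl.bridge_cutoff,
        occupancy=occupancy,
        bridged=occupancy >= chanl.occupancy_threshold,
    )


def bridged_protomers(
    traj: Trajectory,
    chanl: ChannelDefinition,
    residue_pair: tuple[int, int],
) -> dict[str, BridgeReport]:
    """Apply :func:`saltbridge_series` within each protomer chain."""
    return {
        chain: saltbridge_series(traj, chanl, (chain, residue_pair[0]), (chain, residue_pair[1]))
        for chain in chanl.protomer_chains
    }


def bridged_protomer_count(
    traj: Trajectory,
    chanl: ChannelDefinition,
    residue_pair: tuple[int, int],
) -> int:
    """How many of the six protomers form the given intra-protomer bridge."""
    reports = bridged_protomers(traj, chanl, residue_pair)
    return sum(1 for rep in reports.values() if rep.bridged)


def _representative_ca_index(
    frame_or_traj, chanl: ChannelDefinition, chain: str, tm: str
) -> int:
    res = chanl.representative_residues[tm]
    idx = select(frame_or_traj, chain=chain, residue_numbers=[res], atom_names=["CA"])
    if idx.size != 1:
        raise SelectionError(
            f"representative Cα of {tm} (residue {chain}:{res}) not found"
        )
    return int(idx[0])


def tm_distance(
    frame: Frame, chanl: ChannelDefinition, protomer: str, pair: str = "TM1-TM3"
) -> float:
    """Cα–Cα distance between the representative residues of a TM pair."""
    if pair not in TM_DISTANCE_PAIRS:
        raise ValueError(f"pair must be one of {sorted(TM_DISTANCE_PAIRS)}")
    tm_a, tm_b = TM_DISTANCE_PAIRS[pair]
    ia = _representative_ca_index(frame, chanl, protomer, tm_a)
    ib = _representative_ca_index(frame, chanl, protomer, tm_b)
    return float(np.linalg.norm(frame.coords[ia] - frame.coords[ib]))


def _segment_ca_indices(
    frame_or_traj, chanl: ChannelDefinition, chain: str, tm: str
) -> np.ndarray:
    lo, hi = chanl.tm_segments[tm]
    idx = select(
        frame_or_traj, chain=chain, residue_numbers=range(lo, hi + 1), atom_names=["CA"]
    )
    if idx.size < 3:
        raise SelectionError(
            f"{tm} of chain {chain} has {idx.size} Cα atoms; >= 3 required for an axis"
        )
    return idx


def tm_inclination(
    frame: Frame, chanl: ChannelDefinition, protomer: str, tm: str
) -> float:
    """Angle (degrees) between the best-fit axis of ``tm`` and that of TM1.

    Axes are fitted through all Cα of each segment and oriented N-terminal to
    C-terminal, so an antiparallel helix reads ~180°.
    """
    if tm not in ("TM2", "TM3", "TM4"):
        raise ValueError("inclination is defined for TM2, TM3 or TM4 relative to TM1")
    axis1 = fit_axis(frame.coords[_segment_ca_indices(frame, chanl, protomer, "TM1")])
    axisk = fit_axis(frame.coords[_segment_ca_indices(frame, chanl, protomer, tm)])
    return axis_angle(axis1, axisk)


def tm_metric_series(
    traj: Trajectory, chanl: ChannelDefinition
) -> dict[str, dict[str, np.ndarray]]:
    """Per-frame TM distances and inclinations for every protomer.

    Returns ``{metric: {protomer: values}}`` with metrics ``dist:TM1-TM3``,
    ``dist:TM2-TM4``, ``angle:TM1-TM2``, ``angle:TM1-TM3``, ``angle:TM1-TM4``.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for pair in TM_DISTANCE_PAIRS:
        tm_a, tm_b = TM_DISTANCE_PAIRS[pair]
        metric = f"dist:{pair}"
        out[metric] = {}
        for chain in chanl.protomer_chains:
            ia = _representative_ca_index(traj, chanl, chain, tm_a)
            ib = _representative_ca_index(traj, chanl, chain, tm_b)
            out[metric][chain] = np.linalg.norm(
                traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1
            )
    for tm in ("TM2", "TM3", "TM4"):
        metric = f"angle:TM1-{tm}"
        out[metric] = {}
        for chain in chanl.protomer_chains:
            i1 = _segment_ca_indices(traj, chanl, chain, "TM1")
            ik = _segment_ca_indices(traj, chanl, chain, tm)
            vals = np.empty(traj.n_frames)
            for k in range(traj.n_frames):
                vals[k] = axis_angle(
                    fit_axis(traj.coords[k, i1]), fit_axis(traj.coords[k, ik])
                )
            out[metric][chain] = vals
    return out


def _pocket_ca_indices(
    frame_or_traj, chanl: ChannelDefinition, protomer: str
) -> np.ndarray:
    idx = select(
        frame_or_traj,
        chain=protomer,
        residue_numbers=chanl.pocket_residues,
        atom_names=["CA"],
    )
    if idx.size == 0:
        raise SelectionError(f"no pocket residue Cα present in chain {protomer}")
    if idx.size < len(chanl.pocket_residues):
        top = frame_or_traj.topology if hasattr(frame_or_traj, "topology") else frame_or_traj
        present = {int(top.residue_number[i]) for i in idx}
        missing = sorted(set(chanl.pocket_residues) - present)
        logger.warning(
            "chain %s: %d pocket residues missing (%s); centroid uses those present",
            protomer, len(missing), missing,
        )
    return idx


def pocket_water_count(
    frame: Frame, chanl: ChannelDefinition, protomer: str
) -> int:
    """Waters within ``water_cutoff`` of the protomer's pocket-Cα centroid.

    The centroid is the center of mass of the Cα atoms of the pocket residues
    present in the chain; a water is counted through its oxygen atom, and the
    boundary distance (exactly 6.0 Å by default) is included.
    """
    ca = _pocket_ca_indices(frame, chanl, protomer)
    centroid = center_of_mass(frame.coords[ca], frame.topology.mass[ca])
    ow = water_oxygen_indices(frame.topology)
    if ow.size == 0:
        return 0
    dist = np.linalg.norm(frame.coords[ow] - centroid, axis=1)
    return int(np.count_nonzero(dist <= chanl.water_cutoff))


def pocket_water_series(
    trajs: "Trajectory | Sequence[Trajectory]",
    chanl: ChannelDefinition,
    fixed_centroid: bool = False,
) -> CountSeries:
    """Per-frame per-protomer pocket water counts across one or more replicas.

    The pocket centroid is recomputed each frame (it is bound to the moving Cα
    set); ``fixed_centroid=True`` instead freezes it at the frame-0 position of
    each replica.  Replicas must share frame count and timestep.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("at least one trajectory is required")
    n_frames = trajs[0].n_frames
    for t in trajs[1:]:
        if t.n_frames != n_frames:
            raise ValueError("replicas must have the same number of frames")
    chains = chanl.protomer_chains
    counts = np.zeros((len(trajs), n_frames, len(chains)), dtype=np.int64)
    for r, traj in enumerate(trajs):
        ow = water_oxygen_indices(traj.topology)
        for p, chain in enumerate(chains):
            ca = _pocket_ca_indices(traj, chanl, chain)
            masses = traj.topology.mass[ca]
            if fixed_centroid:
                c0 = center_of_mass(traj.coords[0, ca], masses)
                centroids = np.broadcast_to(c0, (n_frames, 3))
            else:
                centroids = (
                    traj.coords[:, ca, :] * masses[None, :, None]
                ).sum(axis=1) / masses.sum()
            if ow.size == 0:
                continue
            d = np.linalg.norm(
                traj.coords[:, ow, :] - centroids[:, None, :], axis=2
            )
            counts[r, :, p] = (d <= chanl.water_cutoff).sum(axis=1)
    return CountSeries(counts=counts, times_ps=trajs[0].times_ps, protomers=tuple(chains))
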