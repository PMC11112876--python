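"""Synthetic hexameric pseudo-channel trajectories with planted ground truth.

The generator emulates the statistical structure the analysis layer assumes —
six protomer chains arranged with 6-fold symmetry, four transmembrane helices
per protomer (TM2/TM4 antiparallel to TM1/TM3), a short N-terminal helix so
that every default pocket residue has a Cα, waters, planted salt bridges and
per-frame Gaussian positional jitter — with no physical realism (no sterics,
no force field, no membrane).

Construction guarantees, all exact up to floating-point rounding at zero
jitter:

* the representative-residue Cα atoms of each TM pair are placed exactly at
  the planted TM1–TM3 / TM2–TM4 separations, at equal height;
* every TM helix is a rigid (or inverted, for antiparallel helices) copy of a
  single canonical template whose fitted axis is aligned with +z, so planted
  inclination tilts are recovered exactly by the total-least-squares fit;
* planted salt bridges hold their target moiety-COM distance on the first
  ``ceil(dwell * n_frames)`` frames and sit at a far distance otherwise, so
  occupancies are exact counting fractions; moiety clusters receive
  COM-preserving jitter so this stays true at any jitter level;
* waters are rejection-sampled so each protomer's pocket contains a known
  integer number of molecules before jitter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .channel import (
    DEFAULT_MOIETY_MAP,
    DEFAULT_POCKET_RESIDUES,
    DEFAULT_REPRESENTATIVE_RESIDUES,
    ChannelDefinition,
)
from .exceptions import ConfigError
from .geometry import fit_axis
from .structure_io import Topology, Trajectory, atomic_mass, infer_element

#: Residue identities at the pocket-lining positions; other positions are ALA.
RESIDUE_NAMES: Mapping[int, str] = {
    9: "ASN", 12: "GLU", 13: "GLU", 16: "GLU", 18: "SER", 23: "ARG", 26: "LEU",
    27: "THR", 30: "PHE", 33: "ARG", 34: "ILE", 81: "GLN", 85: "VAL", 86: "SER",
    88: "PRO", 89: "SER", 92: "TYR", 93: "VAL", 148: "LEU", 151: "TYR",
    154: "HIS", 155: "ILE", 158: "LYS", 159: "THR", 162: "GLU", 216: "SER",
    219: "LEU", 220: "ASN", 223: "GLU", 227: "LEU",
}

#: Local offsets (Å) of each moiety atom around the moiety center of mass;
#: made exactly mass-weighted zero-mean at build time.
_MOIETY_OFFSETS: Mapping[str, np.ndarray] = {
    "ARG": 0.65 * np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ),
    "GLU": 0.65 * np.array([[0.0, 0.0, 1.0], [0.87, 0.0, -0.5], [-0.87, 0.0, -0.5]]),
    "GLN": 0.65 * np.array([[0.0, 0.0, 1.0], [0.87, 0.0, -0.5], [-0.87, 0.0, -0.5]]),
    "ASP": 0.65 * np.array([[0.0, 0.0, 1.0], [0.87, 0.0, -0.5], [-0.87, 0.0, -0.5]]),
    "LYS": np.zeros((1, 3)),
}

_TM_STARTS: Mapping[str, int] = {"TM1": 14, "TM2": 75, "TM3": 144, "TM4": 210}
_NT_START = 5


@dataclass(frozen=True)
class BridgePlant:
    """One planted intra-protomer salt bridge.

    ``dwell_fraction`` may be a scalar (applied to all six protomers) or a
    6-sequence of per-protomer fractions; moiety atoms are emitted in every
    protomer either way, so the pair is measurable even where it never forms.
    """

    residue_a: int
    residue_b: int
    distance: float = 3.5
    dwell_fraction: "float | tuple[float, ...]" = 1.0
    far_distance: float = 6.5

    def dwell_per_protomer(self, n_protomers: int) -> tuple[float, ...]:
        d = self.dwell_fraction
        if np.isscalar(d):
            d = (float(d),) * n_protomers
        d = tuple(float(x) for x in d)
        if len(d) != n_protomers:
            raise ConfigError(
                f"bridge {self.residue_a}-{self.residue_b}: dwell_fraction needs "
                f"1 or {n_protomers} values"
            )
        if any(not 0.0 <= x <= 1.0 for x in d):
            raise ConfigError("dwell fractions must lie in [0, 1]")
        return d


def default_bridge_plants() -> tuple[BridgePlant, ...]:
    """Wild-type-like plants: 33-162 stable in all six protomers; 158-223
    formed in four of the six."""
    return (
        BridgePlant(33, 162, distance=3.5, dwell_fraction=1.0),
        BridgePlant(158, 223, distance=3.5, dwell_fraction=(1, 1, 1, 1, 0, 0)),
    )


@dataclass
class SynthesisParams:
    """Generator settings; the seed fixes the full output bit-for-bit."""

    n_protomers: int = 6
    tm_length: int = 22  # residues per TM helix
    nt_length: int = 9  # N-terminal helix residues (5..13)
    rise_per_residue: float = 1.5  # Å
    twist_per_residue: float = 100.0  # degrees
    helix_radius: float = 2.3  # Å
    ring_radius: float = 25.0  # Å, protomer placement around the pore axis
    d13: float = 11.0  # planted TM1-TM3 representative-Cα distance, Å
    d24: float = 11.0  # planted TM2-TM4 representative-Cα distance, Å
    tm_tilts: Mapping[str, "float | tuple[float, ...]"] = field(default_factory=dict)
    protomer_twist_deg: "float | tuple[float, ...]" = 0.0
    protomer_tilt_deg: "float | tuple[float, ...]" = 0.0
    bridge_plants: tuple[BridgePlant, ...] = field(default_factory=default_bridge_plants)
    n_pocket_waters: "int | tuple[int, ...]" = 25  # per protomer, pre-jitter
    n_bulk_waters: int = 150
    jitter_sigma: float = 0.3  # Å, per-coordinate Gaussian
    n_frames: int = 100
    dt_ps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protomers != 6:
            raise ConfigError("the hemichannel generator builds exactly 6 protomers")
        if min(self.tm_length, self.nt_length) < 3:
            raise ConfigError("helix segments need >= 3 residues for axis fitting")
        for val, name in ((self.jitter_sigma, "jitter_sigma"), (self.d13, "d13"),
                          (self.d24, "d24"), (self.ring_radius, "ring_radius")):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        segs = self.tm_segments()
        for tm, rep in DEFAULT_REPRESENTATIVE_RESIDUES.items():
            lo, hi = segs[tm]
            if not lo <= rep <= hi:
                raise ConfigError(
                    f"tm_length={self.tm_length} leaves representative residue "
                    f"{rep} outside {tm} range {lo}-{hi}"
                )

    def tm_segments(self) -> dict[str, tuple[int, int]]:
        return {
            tm: (start, start + self.tm_length - 1) for tm, start in _TM_STARTS.items()
        }

    def nt_segment(self) -> tuple[int, int]:
        return (_NT_START, _NT_START + self.nt_length - 1)

    def tilts_per_protomer(self, tm: str) -> tuple[float, ...]:
        val = self.tm_tilts.get(tm, 0.0)
        if np.isscalar(val):
            return (float(val),) * self.n_protomers
        val = tuple(float(x) for x in val)
        if len(val) != self.n_protomers:
            raise ConfigError(f"tm_tilts[{tm}] needs 1 or {self.n_protomers} values")
        return val

    def _per_protomer(self, val) -> tuple[float, ...]:
        if np.isscalar(val):
            return (float(val),) * self.n_protomers
        out = tuple(float(x) for x in val)
        if len(out) != self.n_protomers:
            raise ConfigError(f"expected 1 or {self.n_protomers} values, got {len(out)}")
        return out

    def pocket_waters_per_protomer(self) -> tuple[int, ...]:
        val = self.n_pocket_waters
        if np.isscalar(val):
            return (int(val),) * self.n_protomers
        out = tuple(int(x) for x in val)
        if len(out) != self.n_protomers:
            raise ConfigError("n_pocket_waters needs 1 or 6 values")
        return out


@dataclass
class GroundTruthManifest:
    """Planted parameters of a synthetic trajectory, for recovery tests.

    Distances, inclinations, occupancies and pocket counts are the exact
    pre-jitter values of the as-built structure; axis directions are the
    nominal helix axes (the total-least-squares fit of a finite helix deviates
    from the nominal axis by a small constant angle that cancels in all
    inclination values).
    """

    seed: int
    jitter_sigma: float
    n_frames: int
    dt_ps: float
    tm_segments: dict
    tm_distances: dict  # chain -> {"TM1-TM3": Å, "TM2-TM4": Å}
    inclinations: dict  # chain -> {"TM1-TM2": deg, ...}
    axis_directions: dict  # chain -> {tm: [x, y, z]}
    bridges: list  # per (plant, chain) records
    pocket_counts: dict  # chain -> waters within cutoff before jitter

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def channel_definition(params: SynthesisParams) -> ChannelDefinition:
    """The ChannelDefinition matching a generated hexamer."""
    return ChannelDefinition(tm_segments=params.tm_segments())


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def ideal_helix(
    n: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """Cα positions of an ideal α-helix along +z (N-terminus at z = 0)."""
    i = np.arange(n, dtype=float)
    theta = np.radians(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def _canonical_template(n: int, rise: float, twist_deg: float, radius: float) -> np.ndarray:
    """Ideal helix rotated about z so its fitted axis has zero x-component.

    The total-least-squares axis of a finite helix deviates slightly from +z;
    putting that deviation entirely in the y–z plane makes tilts about the
    x-axis commute exactly with the fit, so planted inclinations are recovered
    to machine precision.
    """
    pts = ideal_helix(n, rise, twist_deg, radius)
    d = fit_axis(pts).direction
    if abs(d[0]) + abs(d[1]) > 0:
        # rotate the in-plane component of the axis onto +y
        phi = math.degrees(math.atan2(d[1], d[0]))
        pts = pts @ _rot_z(90.0 - phi).T
    return pts


def _moiety_cluster(resname: str) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """(atom names, zero-COM offsets, masses) of a residue's terminal moiety."""
    names = DEFAULT_MOIETY_MAP[resname]
    offsets = np.array(_MOIETY_OFFSETS[resname], dtype=float)
    masses = np.array([atomic_mass(infer_element(a)) for a in names])
    offsets = offsets - (offsets * masses[:, None]).sum(0) / masses.sum()
    return names, offsets, masses


def _residue_name(number: int) -> str:
    return RESIDUE_NAMES.get(number, "ALA")


def build_hexamer(params: SynthesisParams) -> tuple[Trajectory, GroundTruthManifest]:
    """Generate a seeded synthetic hemichannel trajectory and its ground truth."""
    rng = np.random.default_rng(params.seed)
    chains = ("A", "B", "C", "D", "E", "F")
    segs = params.tm_segments()
    nt_lo, nt_hi = params.nt_segment()
    reps = dict(DEFAULT_REPRESENTATIVE_RESIDUES)

    template = _canonical_template(
        params.tm_length, params.rise_per_residue, params.twist_per_residue,
        params.helix_radius,
    )
    nt_template = ideal_helix(
        params.nt_length, params.rise_per_residue, params.twist_per_residue,
        params.helix_radius,
    )
    d0 = fit_axis(template).direction  # ~ +z with tiny y-component

    # representative-residue anchor positions in the protomer-local frame:
    # TM1/TM3 on the x-axis, TM2/TM4 on the y-axis, all at z = 0
    rep_targets = {
        "TM1": np.array([-params.d13 / 2.0, 0.0, 0.0]),
        "TM3": np.array([+params.d13 / 2.0, 0.0, 0.0]),
        "TM2": np.array([0.0, -params.d24 / 2.0, 0.0]),
        "TM4": np.array([0.0, +params.d24 / 2.0, 0.0]),
    }
    antiparallel = {"TM1": False, "TM2": True, "TM3": False, "TM4": True}

    twists = params._per_protomer(params.protomer_twist_deg)
    wobbles = params._per_protomer(params.protomer_tilt_deg)

    # --- per-atom table and base (pre-jitter) coordinates -------------------
    names: list[str] = []
    resnames: list[str] = []
    chain_ids: list[str] = []
    resnums: list[int] = []
    het: list[bool] = []
    base: list[np.ndarray] = []

    # plant bookkeeping: (plant, chain) -> indices of moiety atoms of each side
    plant_atoms: dict[tuple[int, str, int], list[int]] = {}
    planted_residues: dict[int, int] = {}
    for ip, plant in enumerate(params.bridge_plants):
        for res in (plant.residue_a, plant.residue_b):
            if res in planted_residues and planted_residues[res] != ip:
                raise ConfigError(f"residue {res} participates in two bridge plants")
            planted_residues[res] = ip
            in_tm = any(lo <= res <= hi for lo, hi in segs.values())
            if not (in_tm or nt_lo <= res <= nt_hi):
                raise ConfigError(f"planted residue {res} lies outside every segment")
            resname = _residue_name(res)
            if resname not in DEFAULT_MOIETY_MAP:
                raise ConfigError(
                    f"planted residue {res} ({resname}) has no moiety definition"
                )

    manifest_dist: dict[str, dict] = {}
    manifest_incl: dict[str, dict] = {}
    manifest_axes: dict[str, dict] = {}

    for p, chain in enumerate(chains):
        rot_p = _rot_z(60.0 * p + twists[p])
        wobble_p = _rot_x(wobbles[p])
        ring = np.array(
            [
                params.ring_radius * math.cos(math.radians(60.0 * p)),
                params.ring_radius * math.sin(math.radians(60.0 * p)),
                0.0,
            ]
        )

        def to_global(pts: np.ndarray) -> np.ndarray:
            return (pts @ rot_p.T) @ wobble_p.T + ring

        # local segment coordinates, keyed by residue number
        local: dict[int, np.ndarray] = {}

        # N-terminal helix: axis along +x, parked below the bundle
        nt_pts = nt_template @ _rot_y(90.0).T + np.array(
            [-params.d13 / 2.0 - 4.0, -4.0, -0.6 * params.rise_per_residue * params.tm_length - 8.0]
        )
        for j, res in enumerate(range(nt_lo, nt_hi + 1)):
            local[res] = nt_pts[j]

        axis_dirs: dict[str, np.ndarray] = {}
        for tm, (lo, hi) in segs.items():
            tilt = params.tilts_per_protomer(tm)[p] if tm != "TM1" else 0.0
            rep_idx = reps[tm] - lo
            pts = -template if antiparallel[tm] else template.copy()
            shift = rep_targets[tm] - pts[rep_idx]
            pts = pts + shift
            if tilt != 0.0:
                rx = _rot_x(tilt)
                pivot = pts[rep_idx].copy()
                pts = (pts - pivot) @ rx.T + pivot
                nominal = rx @ np.array([0.0, 0.0, 1.0])
            else:
                nominal = np.array([0.0, 0.0, 1.0])
            if antiparallel[tm]:
                nominal = -nominal
            axis_dirs[tm] = wobble_p @ (rot_p @ nominal)
            for j, res in enumerate(range(lo, hi + 1)):
                local[res] = pts[j]

        # manifest: exact as-built representative distances & inclinations
        manifest_dist[chain] = {
            "TM1-TM3": float(np.linalg.norm(local[reps["TM1"]] - local[reps["TM3"]])),
            "TM2-TM4": float(np.linalg.norm(local[reps["TM2"]] - local[reps["TM4"]])),
        }
        incl = {}
        for tm in ("TM2", "TM3", "TM4"):
            tilt = params.tilts_per_protomer(tm)[p]
            incl[f"TM1-{tm}"] = 180.0 - tilt if antiparallel[tm] else float(tilt)
        manifest_incl[chain] = incl
        manifest_axes[chain] = {tm: axis_dirs[tm].tolist() for tm in segs}

        # emit Cα atoms in residue order, with moiety atoms after the Cα of
        # planted residues
        for res in sorted(local):
            names.append("CA")
            resnames.append(_residue_name(res))
            chain_ids.append(chain)
            resnums.append(res)
            het.append(False)
            base.append(to_global(local[res][None])[0])
            if res in planted_residues:
                ip = planted_residues[res]
                resname = _residue_name(res)
                atom_names, _, _ = _moiety_cluster(resname)
                key = (ip, chain, res)
                plant_atoms[key] = []
                for an in atom_names:
                    plant_atoms[key].append(len(names))
                    names.append(an)
                    resnames.append(resname)
                    chain_ids.append(chain)
                    resnums.append(res)
                    het.append(False)
                    base.append(np.zeros(3))  # filled per frame below

    protein_count = len(names)
    base_arr = np.array(base)

    # --- pocket centroids (pre-jitter) for water placement ------------------
    centroids = []
    for chain in chains:
        idx = [
            i
            for i in range(protein_count)
            if chain_ids[i] == chain
            and names[i] == "CA"
            and resnums[i] in DEFAULT_POCKET_RESIDUES
        ]
        centroids.append(base_arr[idx].mean(axis=0))
    centroids = np.array(centroids)

    water_cutoff = 6.0
    inner_radius = water_cutoff - 1.5
    margin = water_cutoff + 1.5

    water_xyz: list[np.ndarray] = []
    for p, n_in in enumerate(params.pocket_waters_per_protomer()):
        placed = 0
        while placed < n_in:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = inner_radius * rng.random() ** (1.0 / 3.0)
            pos = centroids[p] + r * u
            other = np.delete(centroids, p, axis=0)
            if np.all(np.linalg.norm(other - pos, axis=1) > margin):
                water_xyz.append(pos)
                placed += 1
    lo_corner = base_arr.min(axis=0) - 8.0
    hi_corner = base_arr.max(axis=0) + 8.0
    placed = 0
    while placed < params.n_bulk_waters:
        pos = lo_corner + rng.random(3) * (hi_corner - lo_corner)
        if np.all(np.linalg.norm(centroids - pos, axis=1) > margin):
            water_xyz.append(pos)
            placed += 1

    for w, pos in enumerate(water_xyz, start=1):
        names.append("O")
        resnames.append("HOH")
        chain_ids.append("W")
        resnums.append(w)
        het.append(True)
        base.append(pos)
    base_arr = np.array(base)
    n_atoms = len(names)

    elements = [infer_element(a) for a in names]
    masses = np.array([atomic_mass(e) for e in elements])
    topology = Topology(
        serial=np.arange(1, n_atoms + 1),
        atom_name=np.array(names, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        chain_id=np.array(chain_ids, dtype=object),
        residue_number=np.array(resnums, dtype=np.int64),
        element=np.array(elements, dtype=object),
        mass=masses,
        het=np.array(het, dtype=bool),
    )

    # --- frames: base + jitter, then planted moiety clusters ----------------
    F = params.n_frames
    coords = np.broadcast_to(base_arr, (F, n_atoms, 3)).copy()
    if params.jitter_sigma > 0:
        coords += rng.normal(0.0, params.jitter_sigma, size=(F, n_atoms, 3))

    bridges_manifest = []
    bridge_cutoff = 4.0
    for ip, plant in enumerate(params.bridge_plants):
        dwell = plant.dwell_per_protomer(params.n_protomers)
        name_a = _residue_name(plant.residue_a)
        name_b = _residue_name(plant.residue_b)
        _, off_a, m_a = _moiety_cluster(name_a)
        _, off_b, m_b = _moiety_cluster(name_b)
        for p, chain in enumerate(chains):
            ca_a = topology_index(topology, chain, plant.residue_a, "CA")
            ca_b = topology_index(topology, chain, plant.residue_b, "CA")
            pa, pb = base_arr[ca_a], base_arr[ca_b]
            mid = 0.5 * (pa + pb)
            u = pb - pa
            u = u / np.linalg.norm(u)
            n_bridged = math.ceil(dwell[p] * F)
            sep = np.full(F, plant.far_distance)
            sep[:n_bridged] = plant.distance
            com_a = mid[None, :] - 0.5 * sep[:, None] * u[None, :]
            com_b = mid[None, :] + 0.5 * sep[:, None] * u[None, :]
            for com, off, m, key_res in (
                (com_a, off_a, m_a, plant.residue_a),
                (com_b, off_b, m_b, plant.residue_b),
            ):
                idx = plant_atoms[(ip, chain, key_res)]
                pos = com[:, None, :] + off[None, :, :]
                if params.jitter_sigma > 0 and len(idx) > 1:
                    j = rng.normal(0.0, params.jitter_sigma, size=(F, len(idx), 3))
                    j -= (j * m[None, :, None]).sum(axis=1, keepdims=True) / m.sum()
                    pos = pos + j
                coords[:, idx, :] = pos
            occ_bridged = 1.0 if plant.distance <= bridge_cutoff else 0.0
            occ_far = 1.0 if plant.far_distance <= bridge_cutoff else 0.0
            occupancy = (n_bridged * occ_bridged + (F - n_bridged) * occ_far) / F
            bridges_manifest.append(
                {
                    "chain": chain,
                    "pair": [plant.residue_a, plant.residue_b],
                    "distance": plant.distance,
                    "far_distance": plant.far_distance,
                    "dwell_nominal": dwell[p],
                    "n_bridged_frames": n_bridged,
                    "occupancy": occupancy,
                    "bridged": occupancy >= 0.5,
                }
            )

    pocket_counts = {
        chain: int(n) for chain, n in zip(chains, params.pocket_waters_per_protomer())
    }

    manifest = GroundTruthManifest(
        seed=params.seed,
        jitter_sigma=params.jitter_sigma,
        n_frames=F,
        dt_ps=params.dt_ps,
        tm_segments={k: list(v) for k, v in segs.items()},
        tm_distances=manifest_dist,
        inclinations=manifest_incl,
        axis_directions=manifest_axes,
        bridges=bridges_manifest,
        pocket_counts=pocket_counts,
    )
    traj = Trajectory(topology, coords, dt_ps=params.dt_ps, source=f"synthetic(seed={params.seed})")
    return traj, manifest


def topology_index(top: Topology, chain: str, residue: int, atom_name: str) -> int:
    """Index of a single named atom; raises if absent or ambiguous."""
    hits = np.nonzero(
        (top.chain_id == chain)
        & (top.residue_number == residue)
        & (top.atom_name == atom_name)
    )[0]
    if hits.size != 1:
        raise ConfigError(f"atom {chain}:{residue}:{atom_name} not uniquely present")
    return int(hits[0])


def perturb_protomer(
    traj: Trajectory,
    protomer: str,
    tilt_deg: float,
    axis: str = "x",
    tm: Optional[str] = None,
    chanl: Optional[ChannelDefinition] = None,
) -> Trajectory:
    """Rigidly rotate one protomer (or one of its TM segments) in every frame.

    The rotation is about the chosen membrane-plane axis (``'x'`` or ``'y'``)
    through the centroid of the rotated atom set (frame 0).  Rotating a whole
    protomer leaves all intra-protomer metrics unchanged; to perturb an
    inclination, pass ``tm`` (with the matching ``chanl``) so that only that
    segment rotates.
    """
    mask = np.array([c == protomer for c in traj.topology.chain_id])
    if not mask.any():
        raise ConfigError(f"unknown protomer chain {protomer!r}")
    if tm is not None:
        if chanl is None:
            raise ConfigError("a ChannelDefinition is required to locate a TM segment")
        lo, hi = chanl.tm_segments[tm]
        mask &= (traj.topology.residue_number >= lo) & (traj.topology.residue_number <= hi)
        if not mask.any():
            raise ConfigError(f"no atoms of {tm} in chain {protomer}")
    rot = {"x": _rot_x, "y": _rot_y}[axis](tilt_deg)
    idx = np.nonzero(mask)[0]
    pivot = traj.coords[0, idx].mean(axis=0)
    coords = traj.coords.copy()
    coords[:, idx, :] = (coords[:, idx, :] - pivot) @ rot.T + pivot
    return Trajectory(traj.topology, coords, dt_ps=traj.dt_ps, source=traj.source)
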