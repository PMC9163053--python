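"""Coarse-grain solvent-accessible surface area and the ζ excess-exposure
metrics.

SASA is computed on Cα beads by a Shrake–Rupley sphere-point algorithm with
residue-specific radii. The default radii are proportional to the cube root of
standard amino-acid volumes, normalized so that glycine has radius 3.4 Å;
every ζ metric is a ratio against a reference ensemble computed with identical
settings, so the verdicts are robust to the absolute radius calibration.

The ζ metrics report the percent excess of aggregate SASA of a residue set
relative to the native-state ensemble mean::

    ζ_set(t) = (A_set(t) / ⟨A_set⟩_NS − 1) · 100 %

with set ∈ {hydrophobic, DnaK-binding sites, aggregation-prone, peptide
fragment}. A trajectory whose tail average ⟨ζ⟩ (final 100 ns) stays at or
below 10 % is called native-like for that property (chaperone evasion, no
excess aggregation, no excess degradation).

The co-translational variant compares the exposed hydrophobic SASA of a
nascent chain of length l at time t against the folded population of synthesis
trajectories, only counting residues outside the ribosome exit tunnel
(default: x ≥ 100 Å in the simulation frame), and only for nascent lengths
l ≥ 100 — shorter proteins are considered not to interact with trigger factor
at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .struct_io import (CAStructure, ReferenceEnsembleStats, ResidueSet,
                        Trajectory)

__all__ = [
    "SASAResult",
    "TrajectorySASA",
    "ZetaSeries",
    "CotranslationalZeta",
    "DEFAULT_RESIDUE_RADII",
    "residue_radii",
    "sasa",
    "sasa_trajectory",
    "zeta_series",
    "build_cotrans_reference",
    "cotrans_zeta",
]

DEFAULT_PROBE = 1.4  # Å
DEFAULT_N_POINTS = 960
ZETA_THRESHOLD = 10.0  # percent, boundary inclusive
DEFAULT_TAIL_NS = 100.0
MIN_TF_LENGTH = 100  # residues; shorter nascent chains do not engage TF

# Amino-acid volumes in Å³ (Zamyatnin-style consensus values); bead radii are
# 3.4 Å · (V / V_Gly)^(1/3).
_AA_VOLUMES = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}
_GLY_RADIUS = 3.4

DEFAULT_RESIDUE_RADII = {
    name: _GLY_RADIUS * (vol / _AA_VOLUMES["GLY"]) ** (1.0 / 3.0)
    for name, vol in _AA_VOLUMES.items()
}


def residue_radii(structure: CAStructure, radii: dict = None) -> np.ndarray:
    """Per-bead radii (Å) for a structure; unknown residue types are an error."""
    table = DEFAULT_RESIDUE_RADII if radii is None else radii
    out = np.empty(structure.n_residues)
    for k, name in enumerate(structure.residue_names):
        if name not in table:
            raise KeyError(f"no radius for residue type {name!r}")
        out[k] = table[name]
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


@dataclass
class SASAResult:
    """Per-residue SASA (Å²) of one conformation."""

    per_residue: np.ndarray  # (N,)
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_residue.sum())

    def aggregate(self, residue_set: ResidueSet) -> float:
        """Aggregate SASA of a residue set (sum over members)."""
        idx = residue_set.indices()
        idx = idx[idx <= self.per_residue.size]
        return float(self.per_residue[idx - 1].sum())


@dataclass
class TrajectorySASA:
    """Per-frame per-residue SASA of a trajectory."""

    times: np.ndarray  # (F,)
    per_residue: np.ndarray  # (F, N)
    probe: float
    n_points: int

    def aggregate(self, residue_set: ResidueSet) -> np.ndarray:
        idx = residue_set.indices()
        idx = idx[idx <= self.per_residue.shape[1]]
        return self.per_residue[:, idx - 1].sum(axis=1)


def sasa(frame: CAStructure, radii=None, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> SASAResult:
    """Shrake–Rupley sphere-point SASA over Cα beads.

    ``radii`` may be a residue-type → radius mapping or a per-bead array;
    omitted, the default volume-derived radii apply. The probe radius is
    added to every bead radius; a test point on bead i is accessible when it
    lies outside every other expanded sphere.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if isinstance(radii, dict) or radii is None:
        r = residue_radii(frame, radii)
    else:
        r = np.asarray(radii, dtype=float)
        if r.shape != (frame.n_residues,):
            raise ValueError("per-bead radii length mismatch")
    coords = frame.coords
    n = coords.shape[0]
    expanded = r + probe
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    # Neighbour cull: only spheres that can overlap bead i matter.
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        near = np.where((d_centers < expanded[i] + expanded) &
                        (np.arange(n) != i))[0]
        if near.size:
            d = np.linalg.norm(pts[:, None, :] - coords[near][None, :, :], axis=2)
            buried = (d < expanded[near][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SASAResult(areas, probe, n_points)


def sasa_trajectory(traj: Trajectory, radii=None, probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS) -> TrajectorySASA:
    """Per-frame SASA of a trajectory (same settings for every frame)."""
    per_frame = np.stack([
        sasa(traj.frame(k), radii=radii, probe=probe, n_points=n_points).per_residue
        for k in range(traj.n_frames)
    ])
    return TrajectorySASA(traj.times.copy(), per_frame, probe, n_points)


@dataclass
class ZetaSeries:
    """ζ(t) for one residue set, its tail mean, and the 10 % verdict."""

    name: str
    times: np.ndarray
    zeta: np.ndarray  # percent
    tail_mean: float
    threshold: float = ZETA_THRESHOLD

    @property
    def native_like(self) -> bool:
        """True iff ⟨ζ⟩ over the tail is ≤ the threshold (boundary inclusive)."""
        return bool(self.tail_mean <= self.threshold)


def zeta_series(traj: Trajectory, residue_set: ResidueSet,
                ref: ReferenceEnsembleStats = None, *, ref_mean: float = None,
                tail_ns: float = DEFAULT_TAIL_NS, radii=None,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS,
                sasa_result: TrajectorySASA = None) -> ZetaSeries:
    """ζ_set(t) = (A_set(t)/⟨A_set⟩_NS − 1)·100 % and its tail average.

    The reference mean comes from ``ref.mean_sasa[residue_set.name]`` or an
    explicit ``ref_mean``. A precomputed ``sasa_result`` avoids recomputing
    the surface for several sets of the same trajectory.
    """
    if ref_mean is None:
        if ref is None or residue_set.name not in ref.mean_sasa:
            raise ValueError(f"no reference SASA mean for set {residue_set.name!r}")
        ref_mean = ref.mean_sasa[residue_set.name]
    if ref_mean <= 0:
        raise ValueError("reference SASA mean must be positive")
    if sasa_result is None:
        sasa_result = sasa_trajectory(traj, radii=radii, probe=probe,
                                      n_points=n_points)
    a = sasa_result.aggregate(residue_set)
    zeta = (a / ref_mean - 1.0) * 100.0
    tail = traj.tail_mask(tail_ns)
    return ZetaSeries(residue_set.name, traj.times.copy(), zeta,
                      float(zeta[tail].mean()))


@dataclass
class CotranslationalZeta:
    """Co-translational ζ over nascent lengths l ≥ 100 and its grand mean."""

    zeta: np.ndarray  # percent, one entry per qualifying frame
    times: np.ndarray
    lengths: np.ndarray
    grand_mean: float
    no_tf_interaction: bool = False
    exposure: tuple = ("x", 100.0)

    @property
    def evades_tf(self) -> bool:
        """No TF engagement: too short, or ⟨ζ^co-t⟩ ≤ 10 %."""
        return self.no_tf_interaction or self.grand_mean <= ZETA_THRESHOLD


_AXES = {"x": 0, "y": 1, "z": 2}


def _exposed_hydrophobic_area(coords, names, hydrophobic: ResidueSet,
                              exposure, radii, probe, n_points) -> float:
    axis, threshold = exposure
    sub = CAStructure(coords, names[:coords.shape[0]], synthetic_stretched=True)
    res = sasa(sub, radii=radii, probe=probe, n_points=n_points)
    members = hydrophobic.indices()
    members = members[members <= coords.shape[0]]
    exposed = coords[members - 1, _AXES[axis]] >= threshold
    return float(res.per_residue[members - 1][exposed].sum())


def build_cotrans_reference(folded_runs, hydrophobic: ResidueSet,
                            exposure=("x", 100.0), radii=None,
                            probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_N_POINTS) -> dict:
    """Folded-population reference ⟨A_hydrophobic(t, l)⟩_F.

    Binned by nascent length l with per-length time averaging over all frames
    of the folded synthesis trajectories: maps l → mean exposed-hydrophobic
    SASA (Å²).
    """
    acc: dict = {}
    for run in folded_runs:
        names = run.topology.residue_names
        for k in range(run.n_frames):
            l = int(run.nascent_lengths[k])
            a = _exposed_hydrophobic_area(run.coords[k, :l], names, hydrophobic,
                                          exposure, radii, probe, n_points)
            acc.setdefault(l, []).append(a)
    return {l: float(np.mean(vals)) for l, vals in acc.items()}


def cotrans_zeta(synthesis_traj: Trajectory, folded_reference: dict,
                 hydrophobic: ResidueSet, exposure=("x", 100.0), radii=None,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> CotranslationalZeta:
    """Co-translational hydrophobic-exposure excess against the folded
    population.

    ζ^co-t(t, l) = (A(t, l)/⟨A(t, l)⟩_F − 1)·100 % over synthesis frames with
    nascent length l ≥ 100; proteins shorter than 100 residues are flagged as
    not interacting with TF and the metric is left undefined. A missing
    (l) reference bin is an error.
    """
    n = synthesis_traj.n_residues
    if n < MIN_TF_LENGTH:
        return CotranslationalZeta(np.array([]), np.array([]), np.array([]),
                                   np.nan, no_tf_interaction=True,
                                   exposure=tuple(exposure))
    names = synthesis_traj.topology.residue_names
    zetas, times, lengths = [], [], []
    for k in range(synthesis_traj.n_frames):
        l = int(synthesis_traj.nascent_lengths[k])
        if l < MIN_TF_LENGTH:
            continue
        if l not in folded_reference:
            raise KeyError(f"no folded-population reference bin for length {l}")
        ref = folded_reference[l]
        if ref <= 0:
            raise ValueError(f"non-positive reference mean at length {l}")
        a = _exposed_hydrophobic_area(synthesis_traj.coords[k, :l], names,
                                      hydrophobic, exposure, radii, probe,
                                      n_points)
        zetas.append((a / ref - 1.0) * 100.0)
        times.append(synthesis_traj.times[k])
        lengths.append(l)
    zetas = np.asarray(zetas)
    return CotranslationalZeta(zetas, np.asarray(times), np.asarray(lengths),
                               float(zetas.mean()) if zetas.size else np.nan,
                               exposure=tuple(exposure))
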