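"""Synthetic inputs with known ground truth.

Everything the analysis consumes can be generated here with its truth planted
and recorded: idealized Cα structures (helix, β-hairpin, loop-plus-thread
topologies with a chosen linking number), fluctuating trajectories
(native-like jitter, persistently entangled, or folding at a prescribed
time), folding-event times drawn from a two-exponential mixture, structures
with controlled SASA excess, and LiP-MS peptide tables with planted log-ratios
and missing-data patterns.

Every generator is seed-deterministic and returns a machine-readable truth
record alongside its output. The jitter model is isotropic Gaussian
displacement per bead — not physically realistic, but adequate because every
downstream metric is purely geometric.

The loop-plus-thread recipe builds a planar contact-closed loop of Cα beads
and routes the C-terminal segment through it: each planted |g| unit is one
full passage of the thread through the loop near its center (returns between
passes stay outside the loop's disk, contributing no net linking). The sign
of g is set by the passage direction relative to the loop's orientation;
mirroring the structure (z → −z) flips it. Geometric clearance between
thread and loop beads stays above 1 Å so the discretized Gauss kernel is
never singular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .struct_io import CAStructure, NativeContactMap, Trajectory

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "make_entangled_structure",
    "make_trajectory",
    "sample_folding_times",
    "make_peptide_table",
]

BOND = 3.8  # Å, Cα virtual bond
_MAX_STEP = 3.4  # Å, subdivision target for polyline paths


@dataclass
class SyntheticSpec:
    """Recipe card for one synthetic system.

    ``recipe`` is one of ``helix``, ``hairpin``, ``loop_thread``. For
    loop-thread structures ``planted_g`` is the target total linking number
    (−2..+2) and ``n_residues`` must be at least 20. Trajectory and kinetics
    fields feed :func:`make_trajectory` and :func:`sample_folding_times`.
    """

    seed: int = 0
    n_residues: int = 50
    recipe: str = "helix"
    planted_g: int = 1
    loop_size: int = 12
    jitter_amplitude: float = 0.3  # Å
    n_frames: int = 40
    dt_ns: float = 5.0  # trajectory stride
    f1: float = 0.7
    tau1_ns: float = 10.0
    tau2_ns: float = 1000.0
    sasa_inflation: float = 0.0  # fractional radial expansion

    def __post_init__(self) -> None:
        if self.recipe == "loop_thread" and self.n_residues < 20:
            raise ValueError("loop+thread recipes need at least 20 residues")
        if self.recipe not in ("helix", "hairpin", "loop_thread"):
            raise ValueError(f"unknown recipe {self.recipe!r}")
        if abs(self.planted_g) > 2:
            raise ValueError("planted linking numbers are limited to |g| ≤ 2")


# ---------------------------------------------------------------------------
# Structure builders
# ---------------------------------------------------------------------------

def _helix_coords(n: int) -> np.ndarray:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å, 100° per residue."""
    k = np.arange(n)
    phi = np.deg2rad(100.0) * k
    return np.column_stack([2.3 * np.cos(phi), 2.3 * np.sin(phi), 1.5 * k])


def _hairpin_coords(n: int) -> np.ndarray:
    """Two antiparallel strands 4.8 Å apart joined by a two-residue turn."""
    n1 = (n - 2) // 2
    n2 = n - 2 - n1
    top = 3.8 * n1
    s1 = np.column_stack([np.zeros(n1), 3.8 * np.arange(n1), np.zeros(n1)])
    turn = np.array([[1.1, top - 3.8 + 3.2, 0.0], [3.7, top - 3.8 + 3.2, 0.0]])
    s2 = np.column_stack([np.full(n2, 4.8),
                          top - 3.8 - 3.8 * np.arange(n2) + 3.8,
                          np.zeros(n2)])
    return np.vstack([s1, turn, s2])


def _subdivide(waypoints) -> np.ndarray:
    """Polyline through waypoints with every bond in the physical range."""
    pts = [np.asarray(waypoints[0], dtype=float)]
    for nxt in waypoints[1:]:
        nxt = np.asarray(nxt, dtype=float)
        prev = pts[-1]
        d = float(np.linalg.norm(nxt - prev))
        steps = max(1, math.ceil(d / BOND))
        if steps > 1 and d / steps <= 2.05 and d / (steps - 1) < 4.45:
            steps -= 1
        for s in range(1, steps + 1):
            pts.append(prev + (nxt - prev) * (s / steps))
    return np.array(pts)


def _loop_thread_coords(spec: SyntheticSpec, threaded: bool) -> tuple:
    """Loop-plus-thread Cα trace.

    Returns (coords, contact) where ``contact`` is the 1-based (i, j) pair
    closing the loop. With ``threaded`` the C-terminal segment makes
    |planted_g| passages through the loop (direction set by the sign);
    otherwise it climbs outside the loop's disk and the structure is
    unentangled (g = 0).
    """
    n_loop = spec.loop_size
    radius = BOND / (2.0 * math.sin(math.pi / n_loop))
    h = radius + 6.0  # passage half-height, clear of the loop beads

    # N-terminal tail: radial approach in the loop plane from +x (outside the
    # disk, so it never threads).  6 beads upstream of the loop.
    tail_way = [np.array([radius + 6 * BOND, 0.0, 0.0]),
                np.array([radius + BOND, 0.0, 0.0])]
    n_tail = _subdivide(tail_way)

    # Loop: counterclockwise circle in the z = 0 plane (viewed from +z),
    # starting at angle 0.  The closing contact is (first, last) loop bead.
    ang = 2.0 * math.pi * np.arange(n_loop) / n_loop
    loop = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n_loop)])

    exit_pt = loop[-1]  # angle −Δ, just below the +x axis
    out_dir = exit_pt / np.linalg.norm(exit_pt)
    g = spec.planted_g if threaded else 0
    n_pass = abs(g)
    z_sign = 1.0 if g >= 0 else -1.0  # +z passage through a CCW loop: g > 0

    way = [exit_pt, exit_pt + out_dir * 5.0]
    if threaded and n_pass > 0:
        # descend outside the disk, then slide under the center
        way.append(exit_pt + out_dir * 5.0 + np.array([0, 0, -z_sign * h]))
        for p in range(n_pass):
            off = 0.9 * np.array([math.cos(2.2 * p), math.sin(2.2 * p), 0.0])
            way.append(off + np.array([0, 0, -z_sign * h]))
            way.append(off + np.array([0, 0, z_sign * h]))  # the passage
            if p < n_pass - 1:
                # return outside the disk without crossing it
                way.append(np.array([radius + 7.0, 0.0, z_sign * h]))
                way.append(np.array([radius + 7.0, 0.0, -z_sign * h]))
        # C-pad: straight continuation away from the plane
        top = way[-1]
        way.append(top + np.array([0, 0, z_sign * 8 * BOND]))
    else:
        # unthreaded: climb outside the disk
        base = exit_pt + out_dir * 5.0
        way.append(base + np.array([0, 0, 10.0]))
        way.append(base + np.array([0, 0, 10.0 + 8 * BOND]))
    path = _subdivide(way)[1:]  # drop the duplicate of the loop exit bead

    coords = np.vstack([n_tail, loop, path])
    i = n_tail.shape[0] + 1  # first loop bead, 1-based
    j = n_tail.shape[0] + n_loop  # last loop bead
    if coords.shape[0] < spec.n_residues:
        # extend the C-pad to the requested chain length
        tail_dir = coords[-1] - coords[-2]
        tail_dir /= np.linalg.norm(tail_dir)
        extra = spec.n_residues - coords.shape[0]
        pad = coords[-1] + tail_dir * BOND * np.arange(1, extra + 1)[:, None]
        coords = np.vstack([coords, pad])
    return coords, (i, j)


def make_structure(spec: SyntheticSpec):
    """Deterministic Cα structure plus its native contact map.

    For ``loop_thread`` the returned structure is the *unentangled* reference
    conformation (the thread outside the loop, g = 0) and the contact map
    holds the loop-closing contact; :func:`make_entangled_structure` builds
    the threaded conformation of the same chain. For ``helix``/``hairpin``
    the contact map is the standard geometric one (8 Å, separation ≥ 4,
    all-residue secondary-structure mask).
    """
    from .struct_io import build_native_contacts

    if spec.recipe == "helix":
        coords = _helix_coords(spec.n_residues)
        struct = CAStructure(coords)
        contacts = build_native_contacts(struct, np.ones(spec.n_residues, bool))
    elif spec.recipe == "hairpin":
        coords = _hairpin_coords(spec.n_residues)
        struct = CAStructure(coords, synthetic_stretched=True)
        contacts = build_native_contacts(struct, np.ones(spec.n_residues, bool))
    else:
        coords, (i, j) = _loop_thread_coords(spec, threaded=False)
        struct = CAStructure(coords)
        d = np.linalg.norm(coords[i - 1] - coords[j - 1])
        contacts = NativeContactMap(np.array([[i, j]]), np.array([d]),
                                    np.ones(coords.shape[0], bool))
    return struct, contacts


def make_entangled_structure(spec: SyntheticSpec) -> CAStructure:
    """Threaded loop-plus-thread conformation achieving the planted g."""
    if spec.recipe != "loop_thread":
        raise ValueError("entangled conformations exist only for loop_thread")
    coords, _ = _loop_thread_coords(spec, threaded=True)
    return CAStructure(coords)


# ---------------------------------------------------------------------------
# Trajectory builders
# ---------------------------------------------------------------------------

def _jitter(rng, coords, amplitude):
    return coords + rng.normal(0.0, amplitude, coords.shape)


def make_trajectory(native: CAStructure, kind: str, spec: SyntheticSpec,
                    entangled: CAStructure = None, fold_at_ns: float = None,
                    expand_factor: float = 1.0):
    """Synthetic trajectory with a truth record.

    Kinds: ``native_like`` (Gaussian jitter about the native conformation),
    ``misfold_entangled`` (every frame at the entangled/expanded conformation
    plus jitter), ``fold_at`` (entangled frames before ``fold_at_ns``, native
    frames from then on, so the folding time is recovered by construction).
    ``expand_factor`` scales the misfolded conformation about its centroid,
    breaking native contacts (drives the Q arm of the misfold call and plants
    SASA excess).
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.dt_ns * np.arange(spec.n_frames)
    base_mis = None
    if kind in ("misfold_entangled", "fold_at"):
        src = entangled.coords if entangled is not None else native.coords
        centroid = src.mean(axis=0)
        base_mis = centroid + (src - centroid) * expand_factor

    frames = np.empty((spec.n_frames, native.n_residues, 3))
    for k in range(spec.n_frames):
        if kind == "native_like":
            base = native.coords
        elif kind == "misfold_entangled":
            base = base_mis
        elif kind == "fold_at":
            base = base_mis if times[k] < fold_at_ns else native.coords
        else:
            raise ValueError(f"unknown trajectory kind {kind!r}")
        frames[k] = _jitter(rng, base, spec.jitter_amplitude)

    traj = Trajectory(frames, times, native)
    truth = {"kind": kind, "seed": spec.seed,
             "jitter_amplitude": spec.jitter_amplitude,
             "expand_factor": expand_factor,
             "planted_g": spec.planted_g if entangled is not None else 0,
             "fold_at_ns": fold_at_ns}
    return traj, truth


def sample_folding_times(f1: float, tau1_ns: float, tau2_ns: float, n: int,
                         seed: int = 0) -> np.ndarray:
    """Event times from the two-exponential mixture
    S_U(t) = f1·e^{−t/τ1} + (1−f1)·e^{−t/τ2}."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must lie in [0, 1]")
    if tau1_ns <= 0 or tau2_ns <= 0:
        raise ValueError("time constants must be positive")
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < f1
    return np.where(fast, rng.exponential(tau1_ns, n),
                    rng.exponential(tau2_ns, n))


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

def make_peptide_table(n_null: int = 20, n_hits: int = 5, effect: float = 3.0,
                       cv: float = 0.1, seed: int = 0, timepoint: str = "1 min",
                       n_all_or_nothing: int = 2, n_one_missing: int = 2,
                       n_discarded: int = 2, n_multi_feature: int = 3,
                       baseline: float = 1e6):
    """LiP-MS feature table with planted effects and missingness patterns.

    ``n_hits`` groups carry a planted |log2(R/N)| = ``effect`` (alternating
    sign); ``n_null`` groups have no effect. The three missingness blocks are
    drawn from the null groups and cover the all-or-nothing, one-dropped, and
    discarded statuses. ``n_multi_feature`` of the hit groups get a second
    consistent feature (exercising Fisher's-method combining). Intensities
    are lognormal around ``baseline`` with within-group coefficient of
    variation ``cv``. Returns ``(DataFrame, truth)`` where truth maps group →
    planted effect / expected status / hit flag.
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], {}

    def draw(mean):
        sigma = math.sqrt(math.log(1.0 + cv**2))
        return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, 3))

    def add(group, log2_effect, feat, pattern=None):
        r = draw(baseline * 2.0**log2_effect)
        n_ = draw(baseline)
        r, n_ = list(r), list(n_)
        if pattern == "all_or_nothing":
            n_ = [np.nan] * 3
        elif pattern == "one_missing":
            r[rng.integers(3)] = np.nan
        elif pattern == "discarded":
            r[0] = np.nan
            n_[1] = np.nan
        rows.append({"peptide_group": group, "feature_id": f"{group}.f{feat}",
                     "timepoint": timepoint,
                     "R1": r[0], "R2": r[1], "R3": r[2],
                     "N1": n_[0], "N2": n_[1], "N3": n_[2],
                     "half_tryptic": False, "pk_site": ""})

    for h in range(n_hits):
        name = f"hit{h:02d}"
        sign = 1.0 if h % 2 == 0 else -1.0
        add(name, sign * effect, 1)
        if h < n_multi_feature:
            add(name, sign * effect, 2)
        truth[name] = {"effect": sign * effect, "status": "quantified",
                       "hit": True}
    for k in range(n_null):
        name = f"null{k:02d}"
        if k < n_all_or_nothing:
            add(name, 0.0, 1, pattern="all_or_nothing")
            truth[name] = {"effect": 0.0, "status": "all_or_nothing",
                           "hit": False}
        elif k < n_all_or_nothing + n_one_missing:
            add(name, 0.0, 1, pattern="one_missing")
            truth[name] = {"effect": 0.0, "status": "quantified", "hit": False}
        elif k < n_all_or_nothing + n_one_missing + n_discarded:
            add(name, 0.0, 1, pattern="discarded")
            truth[name] = {"effect": 0.0, "status": "discarded", "hit": False}
        else:
            add(name, 0.0, 1)
            truth[name] = {"effect": 0.0, "status": "quantified", "hit": False}
    return pd.DataFrame(rows), truth
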