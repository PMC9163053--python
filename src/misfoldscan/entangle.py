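"""Non-covalent lasso entanglement detection via Gauss linking numbers.

A native contact (i, j) pseudo-closes the backbone loop running from residue i
to residue j. The N-terminal tail (residues 1..i−1) and C-terminal tail
(residues j+1..N) may thread through that loop; the threading is quantified by
partial Gauss linking numbers g_N(i, j) and g_C(i, j), computed as discretized
Gauss double integrals over segment midpoints::

    R_l  = (r_l + r_{l+1}) / 2
    dR_l = r_{l+1} − r_l

    g_N(i,j) = (1/4π) Σ_{m=6..i−5} Σ_{n=i..j−1}   K(m, n)
    g_C(i,j) = (1/4π) Σ_{m=i..j−1} Σ_{n=j+4..N−6} K(m, n)

    K(m,n)   = (R_m − R_n) / |R_m − R_n|³ · (dR_m × dR_n)

The first 5 residues of the N-terminal curve, the last 5 of the C-terminal
curve, and 4 residues on either side of the contact are excluded to suppress
noise from flexible termini and trivial local structure. Empty summation
ranges contribute 0. The total linking number is

    g(i,j) = round(g_N) + round(g_C)

with rounding half-away-from-zero (symmetric in chirality). |g| counts
threading events; the sign encodes chirality and flips under mirror
reflection.

Changes in linking between a frame and the native reference fall into six
cases k ∈ {0..5}; the per-trajectory case distribution P(G_k) = N_k / N_E,
corrected against the native-state-run reference distribution,
f_c(G_k) = |P_pt(G_k) − P_ref(G_k)| for the non-trivial cases k ∈ {0..4},
drives the entanglement arm of the misfolding criterion: a trajectory is
misfolded/entangled when any tail-averaged f_c reaches 0.1.

G(t), the fraction of currently-formed native contacts whose linking number
differs from the native reference, is the time-resolved entanglement order
parameter used for folding-time determination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .struct_io import CAStructure, NativeContactMap, Trajectory

__all__ = [
    "LinkingResult",
    "EntanglementChangeProfile",
    "linking_kernel",
    "gauss_linking",
    "native_linking",
    "classify_change",
    "change_profile",
    "g_timeseries",
    "entangle_misfold_flag",
    "CASE_GAIN",
    "CASE_LOSS",
    "CASE_GAIN_SWITCH",
    "CASE_LOSS_SWITCH",
    "CASE_PURE_SWITCH",
    "CASE_NO_CHANGE",
]

# Change-in-linking case taxonomy (k indices into P(G_k)).
CASE_GAIN = 0         # |g| increases, chirality preserved
CASE_LOSS = 1         # |g| decreases, chirality preserved
CASE_GAIN_SWITCH = 2  # |g| increases with chirality switch
CASE_LOSS_SWITCH = 3  # |g| decreases with chirality switch
CASE_PURE_SWITCH = 4  # |g| equal, sign flipped
CASE_NO_CHANGE = 5

# Exclusion margins of the discretized Gauss sums (residues).
_TERMINAL_EXCLUDE = 5
_CONTACT_EXCLUDE = 4

#: Midpoint pairs closer than this (Å) are skipped as singular kernel terms.
SINGULAR_TOL = 1e-6

DEFAULT_THRESHOLD = 0.1
DEFAULT_TAIL_NS = 100.0


@dataclass(frozen=True)
class LinkingResult:
    """Partial and total Gauss linking numbers for one native contact."""

    contact: tuple
    g_n_raw: float
    g_c_raw: float
    g_n: int
    g_c: int

    @property
    def g(self) -> int:
        return self.g_n + self.g_c


@dataclass
class EntanglementChangeProfile:
    """Per-trajectory change-in-linking profile and the G(t) order parameter."""

    times: np.ndarray  # (F,) ns
    case_labels: np.ndarray  # (F, M) int in 0..5
    case_counts: np.ndarray  # (6,) instance counts over all (frame, contact)
    p: np.ndarray  # (6,) P(G_k) = N_k / N_E
    g_t: np.ndarray  # (F,) G(t)
    frame_fractions: np.ndarray  # (F, 6) per-frame case fractions
    ref_profile: np.ndarray = None  # (6,) P_ref(G_k)
    f_c: np.ndarray = None  # (5,) |P_pt − P_ref| for k in 0..4
    entangled: bool = False

    @property
    def n_instances(self) -> int:
        return int(self.case_counts.sum())


def _round_half_away(x: float) -> int:
    """Round half away from zero (symmetric in chirality)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def linking_kernel(coords: np.ndarray) -> np.ndarray:
    """Pairwise Gauss kernel matrix K[m, n] over segment midpoints.

    ``coords`` is an (N, 3) Cα array; the result is (N−1, N−1) with
    K[m, n] = (R_m − R_n)/|R_m − R_n|³ · (dR_m × dR_n) (0-based segment
    indices). Near-coincident midpoints are skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    r = 0.5 * (coords[:-1] + coords[1:])
    dr = np.diff(coords, axis=0)
    sep = r[:, None, :] - r[None, :, :]
    dist = np.linalg.norm(sep, axis=2)
    cross = np.cross(dr[:, None, :], dr[None, :, :])
    num = np.einsum("mnk,mnk->mn", sep, cross)
    np.fill_diagonal(dist, np.inf)
    singular = dist < SINGULAR_TOL
    if singular.any():
        warnings.warn(
            f"{int(singular.sum())} near-coincident midpoint pairs skipped "
            "in Gauss kernel", RuntimeWarning, stacklevel=2)
        dist[singular] = np.inf
    return num / dist**3


def _partial(kernel: np.ndarray, m_lo: int, m_hi: int, n_lo: int, n_hi: int) -> float:
    """Sum K over 1-based inclusive segment ranges; empty ranges give 0."""
    if m_hi < m_lo or n_hi < n_lo:
        return 0.0
    m_lo = max(m_lo, 1)
    n_lo = max(n_lo, 1)
    nseg = kernel.shape[0]
    m_hi = min(m_hi, nseg)
    n_hi = min(n_hi, nseg)
    if m_hi < m_lo or n_hi < n_lo:
        return 0.0
    return float(kernel[m_lo - 1:m_hi, n_lo - 1:n_hi].sum()) / (4.0 * np.pi)


def gauss_linking(structure, contact, kernel: np.ndarray = None) -> LinkingResult:
    """Partial and total linking numbers of a native contact in one frame.

    ``structure`` may be a :class:`CAStructure` or a raw (N, 3) array.
    Passing a precomputed ``kernel`` (from :func:`linking_kernel`) amortizes
    the O(N²) pairwise work across contacts of the same frame.
    """
    coords = structure.coords if isinstance(structure, CAStructure) else np.asarray(structure, dtype=float)
    n = coords.shape[0]
    i, j = int(contact[0]), int(contact[1])
    if not (1 <= i < j <= n):
        raise ValueError(f"invalid contact ({i}, {j}) for chain of length {n}")
    if kernel is None:
        kernel = linking_kernel(coords)
    g_n_raw = _partial(kernel, _TERMINAL_EXCLUDE + 1, i - _TERMINAL_EXCLUDE,
                       i, j - 1)
    g_c_raw = _partial(kernel, i, j - 1,
                       j + _CONTACT_EXCLUDE, n - _TERMINAL_EXCLUDE - 1)
    return LinkingResult((i, j), g_n_raw, g_c_raw,
                         _round_half_away(g_n_raw), _round_half_away(g_c_raw))


def native_linking(native: CAStructure, contacts: NativeContactMap) -> np.ndarray:
    """Total linking number g(i, j) of every native contact in the reference
    structure, as an (M,) integer array aligned with ``contacts.pairs``."""
    kernel = linking_kernel(native.coords)
    return np.array([gauss_linking(native, pair, kernel).g
                     for pair in contacts.pairs], dtype=int)


def classify_change(g_native: int, g_frame: int) -> int:
    """Six-case change-in-linking taxonomy.

    Compares (|g|, sign) between the native reference and the frame:
    k=0 gain in |g| with chirality preserved, k=1 loss with chirality
    preserved, k=2 gain with chirality switch, k=3 loss with chirality
    switch, k=4 pure chirality switch (equal |g|, flipped sign), k=5 no
    change. A transition to or from g = 0 never counts as a chirality switch.
    """
    gn = int(getattr(g_native, "g", g_native))
    gf = int(getattr(g_frame, "g", g_frame))
    if gf == gn:
        return CASE_NO_CHANGE
    switched = gn != 0 and gf != 0 and np.sign(gn) != np.sign(gf)
    if abs(gf) > abs(gn):
        return CASE_GAIN_SWITCH if switched else CASE_GAIN
    if abs(gf) < abs(gn):
        return CASE_LOSS_SWITCH if switched else CASE_LOSS
    return CASE_PURE_SWITCH


def _frame_linking(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    kernel = linking_kernel(coords)
    return np.array([gauss_linking(coords, pair, kernel).g for pair in pairs],
                    dtype=int)


def change_profile(traj: Trajectory, contacts: NativeContactMap,
                   g_native: np.ndarray, ref_profile: np.ndarray = None,
                   formation_factor: float = 1.2,
                   tail_ns: float = DEFAULT_TAIL_NS,
                   threshold: float = DEFAULT_THRESHOLD) -> EntanglementChangeProfile:
    """Change-in-linking profile of a trajectory against the native reference.

    Every (frame, contact) pair is one instance: the case distribution is
    P(G_k) = N_k / N_E with N_E the total instance count, so P sums to 1 over
    k ∈ {0..5}. With a reference profile the corrected values
    f_c(G_k) = |P(G_k) − P_ref(G_k)| are reported for the non-trivial cases
    k ∈ {0..4}, and the trajectory-level ``entangled`` flag applies the
    tail-averaged criterion of :func:`entangle_misfold_flag`.

    G(t) is computed alongside: the fraction of all native contacts that are
    both formed at t (r ≤ formation_factor · r⁰) and have g(i,j,t) ≠ g_native.
    """
    g_native = np.asarray(g_native, dtype=int)
    if g_native.shape[0] != contacts.n_contacts:
        raise ValueError("g_native must align with the contact map")
    n_frames = traj.n_frames
    m = contacts.n_contacts
    labels = np.empty((n_frames, m), dtype=int)
    g_t = np.empty(n_frames, dtype=float)
    idx = contacts.pairs - 1
    for k in range(n_frames):
        coords = traj.coords[k]
        g_frame = _frame_linking(coords, contacts.pairs)
        labels[k] = [classify_change(gn, gf) for gn, gf in zip(g_native, g_frame)]
        d = np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)
        formed = d <= formation_factor * contacts.native_distances
        g_t[k] = np.mean(formed & (g_frame != g_native)) if m else 0.0

    counts = np.zeros(6, dtype=float)
    for c in range(6):
        counts[c] = np.sum(labels == c)
    n_e = counts.sum()
    p = counts / n_e if n_e > 0 else np.zeros(6)
    fractions = np.stack([(labels == c).mean(axis=1) for c in range(6)], axis=1)

    profile = EntanglementChangeProfile(
        times=traj.times.copy(), case_labels=labels, case_counts=counts,
        p=p, g_t=g_t, frame_fractions=fractions)
    if ref_profile is not None:
        profile.ref_profile = np.asarray(ref_profile, dtype=float)
        profile.f_c = np.abs(p[:5] - profile.ref_profile[:5])
        profile.entangled = entangle_misfold_flag(profile, tail_ns=tail_ns,
                                                  threshold=threshold)
    return profile


def g_timeseries(traj: Trajectory, contacts: NativeContactMap,
                 g_native: np.ndarray,
                 formation_factor: float = 1.2) -> np.ndarray:
    """G(t): fraction of formed native contacts whose linking number differs
    from the native reference, per frame."""
    profile = change_profile(traj, contacts, g_native,
                             formation_factor=formation_factor)
    return profile.g_t


def entangle_misfold_flag(profile: EntanglementChangeProfile,
                          tail_ns: float = DEFAULT_TAIL_NS,
                          threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Entanglement arm of the misfolding criterion.

    True iff, for any non-trivial case k ∈ {0..4}, the corrected value
    f_c(t, k) = |P_k(t) − P_ref(G_k)| averaged over the final ``tail_ns`` ns
    reaches the threshold (boundary inclusive, default 0.1).
    """
    if profile.ref_profile is None:
        raise ValueError("a reference profile is required")
    t = profile.times
    tail = t >= t[-1] - tail_ns
    f_c_t = np.abs(profile.frame_fractions[tail, :5] - profile.ref_profile[:5])
    return bool(f_c_t.mean(axis=0).max() >= threshold)
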