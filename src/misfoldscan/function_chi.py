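"""Structural overlap of functional residues and the reduced-function call.

χ(t) is the fraction of pairwise distances among the functional residues
{Func} that remain at native-like values::

    χ(t) = (1/N) Σ_{i ∈ Func} Σ_{j ≥ i+2, j ∈ Func} θ(ε − |r_ij(t) − r_ij⁰|)

with θ the unit step (θ(x) = 1 for x ≥ 0), N the number of unordered
functional pairs with sequence separation j ≥ i + 2, and tolerance
ε = 0.2 · 3.81 Å (a fifth of the Cα virtual bond length). Because χ uses
internal distances only, it is invariant under rigid-body motion with no
superposition step.

The relative perturbation against the native ensemble is::

    χ_func(t) = (1 − χ(t)/⟨χ⟩_NS) · 100 %

zero when the frame matches the native mean, negative when it is *more*
native-like than average. A trajectory whose tail average ⟨χ_func⟩ (final
100 ns) reaches 10 % is called less functional than the native state.

Functional residue sets are inputs; the standard harvesting convention is
residues with heavy atoms within 4.5 Å of ligand heteroatoms or of another
chain, plus database-annotated catalytic sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .struct_io import (CAStructure, ReferenceEnsembleStats, ResidueSet,
                        Trajectory)

__all__ = ["ChiResult", "DEFAULT_EPSILON", "functional_pairs", "chi",
           "chi_func_series"]

#: Distance tolerance ε = 0.2 · r_Cα with r_Cα = 3.81 Å.
DEFAULT_EPSILON = 0.2 * 3.81
DEFAULT_TAIL_NS = 100.0
CHI_FUNC_THRESHOLD = 10.0  # percent, boundary inclusive


@dataclass
class ChiResult:
    """χ(t), χ_func(t), tail mean, and the reduced-function verdict."""

    times: np.ndarray
    chi_t: np.ndarray  # (F,) in [0, 1]
    chi_func: np.ndarray  # (F,) percent
    tail_mean: float  # ⟨χ_func⟩ over the tail, percent
    native_mean: float  # ⟨χ⟩_NS
    epsilon: float
    n_pairs: int
    threshold: float = CHI_FUNC_THRESHOLD

    @property
    def reduced_function(self) -> bool:
        """True iff ⟨χ_func⟩ ≥ threshold (boundary inclusive)."""
        return bool(self.tail_mean >= self.threshold)


def functional_pairs(func: ResidueSet, n_residues: int = None) -> np.ndarray:
    """Unordered functional pairs (i, j) with j ≥ i + 2, both in {Func}.

    The sequence-separation rule applies to residue indices in the full
    sequence; pairs with either residue outside {Func} are excluded.
    """
    members = func.indices()
    if n_residues is not None and members.size and members[-1] > n_residues:
        raise ValueError("functional residues beyond chain length")
    pairs = [(i, j) for a, i in enumerate(members) for j in members[a + 1:]
             if j >= i + 2]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def chi(frame: CAStructure, func: ResidueSet, native: CAStructure,
        epsilon: float = None) -> float:
    """Structural overlap of the functional residues in one conformation."""
    if epsilon is None:
        epsilon = DEFAULT_EPSILON
    if len(func.members) < 3:
        raise ValueError("at least 3 functional residues are required")
    pairs = functional_pairs(func, native.n_residues)
    if pairs.shape[0] < 1:
        raise ValueError("fewer than one valid functional pair")
    d_t = frame.distances(pairs)
    d_0 = native.distances(pairs)
    return float(np.mean(epsilon - np.abs(d_t - d_0) >= 0.0))


def chi_func_series(traj: Trajectory, func: ResidueSet, native: CAStructure,
                    ref: ReferenceEnsembleStats = None, *,
                    native_mean: float = None, epsilon: float = None,
                    tail_ns: float = DEFAULT_TAIL_NS) -> ChiResult:
    """χ_func(t) = (1 − χ(t)/⟨χ⟩_NS)·100 % with its tail average and verdict.

    The native mean comes from ``ref.mean_chi`` or an explicit
    ``native_mean``; zero or missing native means are an error.
    """
    if epsilon is None:
        epsilon = DEFAULT_EPSILON
    if native_mean is None:
        if ref is None or not np.isfinite(ref.mean_chi):
            raise ValueError("native mean ⟨χ⟩_NS is required")
        native_mean = ref.mean_chi
    if native_mean <= 0:
        raise ValueError("native mean ⟨χ⟩_NS must be positive")

    pairs = functional_pairs(func, native.n_residues)
    if pairs.shape[0] < 1:
        raise ValueError("fewer than one valid functional pair")
    idx = pairs - 1
    d_0 = native.distances(pairs)
    diffs = traj.coords[:, idx[:, 0], :] - traj.coords[:, idx[:, 1], :]
    d_t = np.linalg.norm(diffs, axis=2)  # (F, P)
    chi_t = np.mean(epsilon - np.abs(d_t - d_0) >= 0.0, axis=1)
    chi_func = (1.0 - chi_t / native_mean) * 100.0
    tail = traj.tail_mask(tail_ns)
    return ChiResult(traj.times.copy(), chi_t, chi_func,
                     float(chi_func[tail].mean()), float(native_mean),
                     float(epsilon), int(pairs.shape[0]))
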