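"""Per-trajectory verdicts, per-protein summaries, Fisher exact tests, and
bootstrap confidence intervals.

A trajectory is *misfolded* when either arm fires: the Q arm (tail-mean
Q_mode below ⟨Q_mode^NS⟩ − 3σ in any domain/interface) or the entanglement
arm (any tail-mean corrected change-in-linking value f_c ≥ 0.1). A misfolded
trajectory bypasses the proteostasis network and remains soluble but
non-functional when all of the following hold (10 % thresholds boundary
inclusive):

* evades trigger factor — protein shorter than 100 residues, or
  ⟨ζ^co-t_hydrophobic⟩ ≤ 10 %;
* evades GroEL/GroES — not a known client, or ⟨ζ_hydrophobic⟩ ≤ 10 %;
* evades DnaK — not a known client, or ⟨ζ_DnaK⟩ ≤ 10 %;
* does not aggregate — ⟨ζ_agg⟩ ≤ 10 %;
* is not degraded in excess — ⟨ζ_hydrophobic⟩ ≤ 10 % (shares the GroEL
  metric value);
* has reduced function — ⟨χ_func⟩ ≥ 10 %.

Cohort statistics use two-sided Fisher exact tests on 2×2 contingency tables
and percentile-bootstrap confidence intervals of proportions (10⁶ resamples).
A protein is called entangled when at least 50 % of its misfolded
trajectories are entangled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "TrajectoryMetrics",
    "TrajectoryVerdict",
    "ProteinSummary",
    "verdict",
    "fisher_exact",
    "bootstrap_ci",
    "summarize_protein",
    "protein_entangled",
    "contingency_table",
]

ZETA_THRESHOLD = 10.0
CHI_THRESHOLD = 10.0
MIN_TF_LENGTH = 100
ENTANGLED_PROTEIN_FRACTION = 0.5
DEFAULT_BOOTSTRAP = 1_000_000


@dataclass
class TrajectoryMetrics:
    """Inputs to the verdict: per-trajectory tail-averaged metrics and flags.

    ``zeta_cotrans`` may be nan for proteins shorter than 100 residues (the
    no-TF-interaction case). ``groel_client``/``dnak_client`` come from the
    chaperone client lists.
    """

    q_misfold: bool
    entangle_misfold: bool
    entangled: bool
    n_residues: int
    zeta_cotrans: float  # ⟨ζ^co-t_hydrophobic⟩, percent
    zeta_hydrophobic: float  # ⟨ζ_hydrophobic⟩, percent
    zeta_dnak: float  # ⟨ζ_DnaK⟩, percent
    zeta_agg: float  # ⟨ζ_agg⟩, percent
    chi_func: float  # ⟨χ_func⟩, percent
    groel_client: bool = False
    dnak_client: bool = False


@dataclass(frozen=True)
class TrajectoryVerdict:
    """All per-trajectory calls; ``soluble_nonfunctional`` is the conjunction
    of misfolding, the five evasion/solubility flags, and reduced function."""

    misfolded_q: bool
    misfolded_entangle: bool
    entangled: bool
    evades_tf: bool
    evades_groel: bool
    evades_dnak: bool
    no_aggregation: bool
    no_degradation: bool
    reduced_function: bool

    @property
    def misfolded(self) -> bool:
        return self.misfolded_q or self.misfolded_entangle

    @property
    def bypasses_proteostasis(self) -> bool:
        return (self.misfolded and self.evades_tf and self.evades_groel
                and self.evades_dnak and self.no_aggregation
                and self.no_degradation)

    @property
    def soluble_nonfunctional(self) -> bool:
        return self.bypasses_proteostasis and self.reduced_function


def verdict(m: TrajectoryMetrics) -> TrajectoryVerdict:
    """Apply the decision logic to one trajectory's metrics.

    Raises ``ValueError`` (verdict withheld) when a required metric is
    missing: every ζ/χ value must be finite, except the co-translational ζ
    for proteins below the 100-residue TF length rule.
    """
    needs_cotrans = m.n_residues >= MIN_TF_LENGTH
    required = {
        "zeta_hydrophobic": m.zeta_hydrophobic,
        "zeta_dnak": m.zeta_dnak,
        "zeta_agg": m.zeta_agg,
        "chi_func": m.chi_func,
    }
    if needs_cotrans:
        required["zeta_cotrans"] = m.zeta_cotrans
    missing = [k for k, v in required.items() if not np.isfinite(v)]
    if missing:
        raise ValueError(f"verdict withheld; missing metrics: {missing}")

    evades_tf = (not needs_cotrans) or m.zeta_cotrans <= ZETA_THRESHOLD
    hydro_ok = m.zeta_hydrophobic <= ZETA_THRESHOLD
    return TrajectoryVerdict(
        misfolded_q=m.q_misfold,
        misfolded_entangle=m.entangle_misfold,
        entangled=m.entangled,
        evades_tf=evades_tf,
        evades_groel=(not m.groel_client) or hydro_ok,
        evades_dnak=(not m.dnak_client) or m.zeta_dnak <= ZETA_THRESHOLD,
        no_aggregation=m.zeta_agg <= ZETA_THRESHOLD,
        no_degradation=hydro_ok,
        reduced_function=m.chi_func >= CHI_THRESHOLD,
    )


def fisher_exact(table) -> tuple:
    """Two-sided Fisher exact test on a 2×2 count table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio ad/bc (∞ when
    bc = 0) and the two-sided p-value from summing hypergeometric
    probabilities at or below the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("a 2×2 table of non-negative counts is required")
    if table.sum() == 0:
        raise ValueError("table has all-zero margins")
    (a, b), (c, d) = table
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = np.nan
    result = _scipy_stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(result.pvalue)


def bootstrap_ci(successes: int, n: int, b: int = DEFAULT_BOOTSTRAP,
                 seed: int = 0, level: float = 0.95) -> tuple:
    """Percentile-bootstrap confidence interval of a proportion.

    Resamples the n-trial binary outcome vector with replacement ``b`` times
    (vectorised as Binomial(n, successes/n) draws, which is distributionally
    identical) and takes the percentile interval of the resampled proportion,
    reported as integer-rounded percentages.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if b < 10_000:
        raise ValueError("at least 10^4 resamples are required")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, successes / n, size=b) / n
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return int(round(lo * 100.0)), int(round(hi * 100.0))


@dataclass
class ProteinSummary:
    """Per-protein counts over its trajectories, with a bootstrap CI on the
    misfolding probability."""

    name: str
    n_traj: int
    n_misfolded: int
    n_entangled_misfolded: int
    n_soluble_nonfunctional: int
    counts: dict = field(default_factory=dict)
    misfold_ci: tuple = None

    @property
    def p_misfold(self) -> float:
        return self.n_misfolded / self.n_traj

    @property
    def entangled(self) -> bool:
        """Protein-level entanglement: ≥ 50 % of misfolded trajectories
        entangled."""
        if self.n_misfolded == 0:
            return False
        return (self.n_entangled_misfolded / self.n_misfolded
                >= ENTANGLED_PROTEIN_FRACTION)


def protein_entangled(verdicts) -> bool:
    """≥ 50 % of the misfolded trajectories of a protein are entangled."""
    mis = [v for v in verdicts if v.misfolded]
    if not mis:
        return False
    return sum(v.entangled for v in mis) / len(mis) >= ENTANGLED_PROTEIN_FRACTION


def summarize_protein(name: str, verdicts, b: int = DEFAULT_BOOTSTRAP,
                      seed: int = 0) -> ProteinSummary:
    """Aggregate trajectory verdicts into per-protein counts and the
    misfolding-probability bootstrap CI."""
    verdicts = list(verdicts)
    n = len(verdicts)
    if n == 0:
        raise ValueError("at least one trajectory verdict is required")
    n_mis = sum(v.misfolded for v in verdicts)
    flags = ["evades_tf", "evades_groel", "evades_dnak", "no_aggregation",
             "no_degradation", "reduced_function", "soluble_nonfunctional",
             "entangled"]
    counts = {f: sum(getattr(v, f) for v in verdicts) for f in flags}
    return ProteinSummary(
        name=name, n_traj=n, n_misfolded=n_mis,
        n_entangled_misfolded=sum(v.entangled for v in verdicts if v.misfolded),
        n_soluble_nonfunctional=counts["soluble_nonfunctional"],
        counts=counts,
        misfold_ci=bootstrap_ci(n_mis, n, b=b, seed=seed),
    )


def contingency_table(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """2×2 table of two boolean vectors: rows (True, False) × cols
    (True, False)."""
    rows = np.asarray(rows, dtype=bool)
    cols = np.asarray(cols, dtype=bool)
    if rows.shape != cols.shape:
        raise ValueError("row and column flags must align")
    return np.array([
        [int(np.sum(rows & cols)), int(np.sum(rows & ~cols))],
        [int(np.sum(~rows & cols)), int(np.sum(~rows & ~cols))],
    ])
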