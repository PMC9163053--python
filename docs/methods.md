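# Methods

This note documents the models, conventions, defaults, and deliberate design
choices behind misfoldscan, and what the synthetic-data tests do and do not
demonstrate about real trajectories.

## Scope and the shape of the problem

The package analyzes Cα-resolution trajectories of protein synthesis,
ejection, and post-translational dynamics. It does **not** run dynamics: the
coarse-grain force field is implemented only as a static energy evaluator
(for validating synthetic conformations), and trajectory generation is the
job of an external MD engine or of the in-package synthetic generators.
Secondary-structure masks, DnaK-site lists, aggregation-prone regions,
functional-residue sets, and chaperone client lists are inputs — the
external predictors and database harvesting that produce them are out of
scope. Functional residues follow the standard harvesting convention
(heavy atoms within 4.5 Å of ligand heteroatoms or of another chain, plus
database-annotated catalytic residues), documented here because the set
semantics matter even though the harvesting itself is not performed.

Units: Å, ns, kcal/mol. Residues are 1-based and contiguous after reading.
All windowed logic is half-open `[t, t + w)` on timestamps, never frame
counts, so variable-stride trajectories behave correctly.

## Native contacts and Q

The contact map is geometric: Cα–Cα ≤ 8 Å, sequence separation ≥ 4, both
residues inside secondary-structure elements. Cutoff and separation are
configuration parameters, since the exact definition belongs to the force
field's parameterization pipeline rather than to this analysis.

A contact is *formed* at time t when `r_ij(t) ≤ 1.2·r_ij⁰` (the common
Gō-analysis convention; the factor is configurable). `Q_mode` takes the mode
of Q over a 15 ns sliding window advanced one frame at a time; because Q is
effectively continuous, values are rounded to 3 decimals before frequency
counting, and ties break toward the larger Q — a deliberate bias *against*
false misfolding calls. The misfold threshold `⟨Q_mode^NS⟩ − 3σ` uses the
mean and SD over all windows of all native-state reference runs; with a
per-domain reference table the flag is evaluated per domain/interface and
OR-ed to the trajectory level.

## Linking numbers and the entanglement arm

The partial Gauss linking numbers follow the discretized double integral
over bond midpoints with the exclusion margins stated in the README (first 5
N-terminal residues, last 5 C-terminal residues, 4 on either side of the
contact). Implementation notes:

* The (N−1)² kernel matrix is computed once per frame and reused by every
  contact (block summation), making per-frame cost O(N²) + O(contacts).
* Rounding is half-away-from-zero, which is symmetric in chirality;
  `round` semantics are the one place where a ±0.5 raw partial can flip, so
  the synthetic generators keep planted raw partials well away from ±0.5.
* Midpoint pairs closer than 10⁻⁶ Å are skipped with a warning rather than
  poisoning the sum with a singular kernel term.

The six change-in-linking cases are: 0 gain in |g| (chirality preserved),
1 loss (preserved), 2 gain with chirality switch, 3 loss with switch,
4 pure switch (equal |g|, flipped sign), 5 no change. A transition to or
from g = 0 never counts as a chirality switch. The classification lives in
one function and can be swapped wholesale if a different case table is
preferred.

P(G_k) counts **per-contact-per-frame instances** (so ΣP = 1 including the
no-change case), and f_c(G_k) = |P − P_ref| is reported for the non-trivial
cases k ∈ {0..4}. Because the misfold rule averages corrected values *over
the final 100 ns*, the implementation also keeps per-frame case fractions
P_k(t); the flag fires when any tail-averaged |P_k(t) − P_ref(k)| reaches
0.1 (boundary inclusive). The whole-trajectory distribution is reported
alongside for cohort-level summaries. The per-frame reading is the only one
compatible with a tail average; its per-event alternative is noted as a
sensitivity concern.

## SASA and the ζ metrics

SASA on Cα beads is a Shrake–Rupley sphere-point algorithm with a
deterministic Fibonacci point set (default 960 points, probe 1.4 Å).
Residue radii default to cube-root-of-volume scaling normalized to
Gly = 3.4 Å. These are calibration choices, not physical truths — but every
ζ is a *ratio* against a reference computed with identical settings, and a
regression test confirms that scaling all radii by a common factor moves
tail-mean ζ by under 2 points on jittered ensembles.

All 10 % thresholds are boundary inclusive (`≤ 10 %` native-like,
`≥ 10 %` reduced function). The co-translational reference
`⟨A(t, l)⟩_F` is binned by nascent length l with per-length time averaging —
the simplest binning consistent with variable-duration synthesis phases —
and the exit-tunnel exposure rule is a generalized (axis, threshold) pair
with default x ≥ 100 Å; a bulk analysis simply sets the threshold to −∞.
Proteins shorter than 100 residues are flagged "no TF interaction" without
computing the metric.

## χ_func

χ uses internal pairwise distances only (no superposition), over unordered
functional pairs with sequence separation j ≥ i + 2, tolerance
ε = 0.2·3.81 Å, with the step function boundary-inclusive
(θ(0) = 1). Whether pairs are counted ordered or unordered cancels in
χ_func, which normalizes by the native mean. Negative χ_func (more
native-like than the reference average) is preserved, not clipped.

## Kinetics

Folding time is the first window time where `Q_mode ≥ ⟨Q_mode^NS⟩ − 3σ` and
`G ≤ G_xs` hold *simultaneously*; G is sampled at window times by nearest
neighbour, with misalignment beyond one series spacing treated as an error.
G_xs is not prescribed anywhere authoritative, so the default is
`⟨G⟩_NS + 3·sd` from the native runs, overridable in configuration.

Survival curves count censored (never-folded) trajectories as unfolded over
their observed span, and the fitting grid truncates at the shortest span so
every trajectory informs every grid point; no external convention pins down
how censored runs should enter such fits, so this conservative scheme is the
package's own choice. The double exponential is fit as decaying phases (the printed
`exp(k t)` form only makes sense with decaying rates; τ = 1/|k|), with f1
constrained to [0, 1], 20 seeded multi-start initializations drawn
log-uniformly in τ, best SSE kept, components canonically ordered τ1 ≤ τ2.
Reliability is Pearson R² > 0.90 between fit and data; a constant curve is
degenerate and flagged unreliable. Protein-level times take the longest slow
phase over domains/interfaces, and any unreliable component voids the
protein's estimate. Extrapolation multiplies by α = 3,967,486 and converts
ns → s (and days).

## Verdicts and cohort statistics

The verdict is a pure function of tail-averaged metrics and client flags:
TF evasion (short chain or ⟨ζ^co-t⟩ ≤ 10 %), GroEL/DnaK evasion (non-client
or ζ ≤ 10 %), no aggregation (ζ_agg ≤ 10 %), no excess degradation (shares
the hydrophobic-ζ value with the GroEL rule), reduced function
(⟨χ_func⟩ ≥ 10 %); soluble-but-nonfunctional is the full conjunction with
misfolding. Missing metrics withhold the verdict with a reason rather than
defaulting.

Fisher exact tests are two-sided with the sample odds ratio ad/bc (∞ when
bc = 0); the test suite checks them against exhaustive hypergeometric
enumeration. Bootstrap CIs use the percentile method (validated against both
worked-example intervals in the test suite), vectorised as Binomial(n, p̂)
draws — exactly the distribution of a with-replacement resample count — with
10⁶ resamples.
A protein is "entangled" when ≥ 50 % of its misfolded trajectories are.

## LiP-MS statistics

Effects are ratios of arithmetic means of raw intensities, reported in log2;
p-values from Welch's unequal-variance t-test. The missing-data policy is
exactly three-way: all-3-vs-0 missing → fill with the 1000-count detection
floor ("all-or-nothing"), exactly 1 of 6 missing → drop it, anything else →
discard. Features of one peptide group combine only when effect signs agree:
the median-effect feature's quantification is kept (even counts take the
candidate nearer the mean effect) and p-values merge via Fisher's method
(natural log, 2m degrees of freedom); sign disagreement forces p = 1. CV is
sd/mean of the refolded replicates. Filters are strict inequalities:
|log2(R/N)| > 1.8 with p < 0.01 is the stringent preset (3.5-fold), and
|log2| > 1 the general preset (2-fold).

## Synthetic generators: what they emulate, and what they don't

Generators are seed-deterministic and emit truth sidecars. The loop-thread
recipe builds a planar contact-closed loop and routes the C-tail through it
once per planted |g| unit, with inter-pass returns outside the loop's disk
and ≥ 1 Å clearance from loop beads; +z passage through a counterclockwise
loop gives g > 0, and mirroring flips the sign. Jitter is isotropic Gaussian
per bead (default 0.3 Å) — not a physical ensemble, but sufficient because
every downstream metric is geometric. Trajectory kinds plant native-like
fluctuation, persistent entanglement (optionally expanded about the centroid
to break contacts and inflate SASA), or a folding event at a prescribed
time.

Consequently, green tests demonstrate that the *measurement machinery* is
correct on curves and ensembles with known truth; they do not demonstrate
that real proteins misfold, nor calibrate the thresholds against real
native-state fluctuations. Test problem sizes (chains of 25–110 residues,
tens of frames, cohorts of ~10 trajectories, 500–2000 simulated folding
events) were chosen as the smallest sizes at which each planted truth is
statistically unambiguous.

## Known limitations

* Only amyloid-type aggregation propensity is proxied (the ζ_agg input list
  comes from an amyloid predictor); other aggregate forms are invisible.
* Knot-type identification and crossing localization are out of scope; the
  linking number reports *that* and *how often* threading changed, not where.
* The six-case taxonomy spans all (|g|, sign) transitions, but its case
  numbering is a convention; comparisons against other implementations must
  align tables first.
* The double-exponential model assumes irreversible parallel folding with no
  unfolded↔misfolded interconversion; strongly non-two-phase survival curves
  simply fail the R² gate.
* SASA radii on Cα beads are a coarse proxy; absolute areas should not be
  interpreted, only the ζ ratios.
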