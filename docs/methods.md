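# Methods

## Overview

`neurograph` implements a four-step graph-theoretical analysis of brain
networks: (1) nodes are the 90 regions of the AAL parcellation (78
cortical, 12 subcortical); (2) a continuous association is estimated
between every pair of regions; (3) the 90 × 90 association matrix is
thresholded by sparsity into a binary adjacency matrix; (4) topological
parameters of the binary graph are computed and compared with the same
parameters of a population of degree-preserving random networks.  On top
of the topology layer sit covariate-adjusted group statistics and a
kernel-regression model that predicts cognitive (MoCA) scores from
network features.

Because no patient MRI data ship with the package, a synthetic-cohort
module generates inputs with the statistical structure the analysis
assumes; every stage is exercised end to end on those cohorts.

## Network construction

**Gray-matter structural covariance (group level).**  For each diffusion
kurtosis channel (MK, AK, RK, KA) and each group, edge (i, j) is the
Pearson correlation of region-i and region-j regional kurtosis values
*across the subjects of that group*.  One matrix per channel per group.

**Functional connectivity (subject level).**  Edge (i, j) is the Pearson
correlation of the two regional BOLD time courses (T = 230 samples by
default), optionally Fisher-z transformed, z = atanh(r).  Because atanh
diverges at |r| = 1 (e.g. duplicated signals), r is clipped to
1 − 1e−7 before the transform and a warning is emitted.  The z transform
is strictly increasing, so the binarized network is identical whether
thresholding is applied to r or z; the package asserts this invariance in
its tests rather than taking a side.

**Binarization.**  At sparsity s the top ⌊s · 4005⌋ weights become edges
(4005 = 90·89/2 node pairs).  Negative correlations are excluded from
edge candidacy by default — binary small-world metrics presuppose positive
connectivity — with absolute-value ranking available behind a flag.
Ranking ties at the cutoff are broken by ascending (i, j) node order and
recorded in a `tie_note`, making the result bit-reproducible across
platforms.  Sparsity grids: 0.06–0.40 step 0.01 for structural networks
(35 thresholds), 0.10–0.40 step 0.01 for functional networks (31
thresholds).

## Graph topology

For a binary undirected graph: clustering coefficient
C_i = 2t_i / (k_i(k_i−1)) (0 when k_i < 2) and Cp = mean C_i;
characteristic path length Lp = mean shortest-path length; global
efficiency Eg = mean of 1/d(i,j) over ordered pairs (1/∞ = 0); local
efficiency Eloc = mean over nodes of the global efficiency of each node's
neighbor-induced subgraph; nodal efficiency Ne_i = mean_j 1/d(i,j);
degree centrality Dc_i = k_i.  Distances are breadth-first-search hops.

**Disconnected graphs.**  Lp is defined as the mean over *finite* pairs,
with the finite fraction (`connected_fraction`) always reported alongside.
This is a convention, not a fact of nature; the efficiency metrics, which
handle disconnection natively, are computed in parallel so that no
conclusion needs to rest on it.

**Null models.**  Normalized metrics use Maslov–Sneppen double-edge
swaps: repeatedly pick two edges (a,b), (c,d), rewire to (a,d), (c,b)
unless a self-loop or multi-edge would result.  Defaults: 100 nulls, 10
attempted swaps per edge — standard practice for this family of null
models; both are configurable and every ensemble is seeded.  Then
γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ; σ > 1 indicates small-world
organization.  The swap kernel is compiled with numba so that full-grid,
100-null ensembles run in seconds.

**AUC.**  Each metric curve is integrated over its sparsity grid by the
trapezoidal rule, giving threshold-free scalars (units: metric ×
sparsity).  Note that a per-threshold γ > 1 is compatible with a γ AUC
well below 1, because the integration window has width 0.3–0.34; the
package therefore never compares AUC values against 1.

## Group inference

Per-subject measures (functional AUCs) are compared between groups by OLS
on [intercept, group, age, sex, education]; the group coefficient's t and
two-sided p are reported.  Group-level structural curves admit no
per-subject distribution, so the default comparison is a two-sample t
across per-threshold values (mean ± SD over thresholds), with a
permutation mode — shuffle subject labels, rebuild covariance networks,
compare AUC differences against ≥1000 permutations — as the statistically
principled alternative; its p-values are empirical, bounded below by
1/(n_perm+1), and shown to be uniform under the null in the tests.

Multiplicity is controlled by Benjamini–Hochberg FDR at q = 0.05.  The
family is defined per metric and scope: the 90 nodes of one nodal metric
form one family; the global measures form their own.  Brain–behavior
association uses partial correlation (residualize metric and MoCA on the
covariates, correlate residuals; p from
t = r√((n−k−2)/(1−r²))).

Demographic-table statistics: pooled-variance two-sample t from summary
statistics, Pearson chi-square (2×2, continuity correction off by
default), Mann–Whitney U with tie-corrected normal approximation.

## MoCA prediction

**LSSVRM.**  The least-squares SVR solves the equality-constrained
saddle-point system [[0, 1ᵀ], [1, K + I/C]] · [b; α] = [0; y] with RBF
kernel K_ij = exp(−‖x_i−x_j‖²/(2σ²)) (or linear), predicting
f(x) = Σ α_i K(x, x_i) + b.  Leave-one-out residuals have the closed form
e_i = α_i / (M⁻¹)_{ii} (M the full saddle matrix), verified in the tests
against explicit refits to 1e−8 and used as the fast inner objective; an
explicit-refit fallback covers ill-conditioned inverses.

**WOA.**  Hyperparameters (log10 C, log10 σ) are searched over the box
[−3, 6] × [−3, 3] — log scale is the natural parameterization for scale
parameters and the box comfortably brackets useful values — by the whale
optimization algorithm: population 20, 50 iterations, spiral constant
b = 1, encircling coefficient a decaying linearly 2 → 0, per-dimension
random draws, positions clipped to the box, non-finite objective values
treated as +∞.  Seeded and bit-reproducible.

**Evaluation.**  Outer leave-one-out over patients.  Default (nested):
features are z-scored on the n−1 training rows and hyperparameters tuned
by minimizing the training fold's closed-form LOO MSE, so the held-out
subject never leaks into model selection.  A single-level mode (tune once
on all subjects, then LOO) is available behind a flag and warns about its
optimistic bias; with n = 45 the two protocols can differ noticeably, and
published single-number accuracies rarely state which was used.  Pooled
predictions are scored by MSE, RMSE = √MSE, MAE, MAPE (%) — undefined and
reported as such if any actual score is 0 — and R² = 1 − SS_res/SS_tot on
the pooled LOO predictions.

**Feature selection** keeps measures whose partial correlation with MoCA
survives FDR, in two modes: global measures only, or global plus nodal.
If nothing survives (common at small n), the strict behavior is an error;
an optional top-|r| fallback exists for pipeline robustness and stamps
`FALLBACK` into the selection-rule audit field so it can never be
mistaken for the FDR rule.

## Synthetic cohorts

Defaults mirror the study conditions: 45 patients, 37 controls, 90
regions, 230 timepoints, ages 30–65 (normal with the reported group
moments, truncated), education uniform 6–18 years, sex Bernoulli(0.5),
MoCA intercepts 22 (patients) and 27.5 (controls) around the 26-point
clinical cutoff.

*Structural*: per group, subjects × 90 kurtosis values are multivariate
normal with a block-modular correlation target — 5 modules,
within-module r = 0.6 (controls) vs 0.3 (patients), between-module
r = 0.1 — so the patient covariance network has lower clustering by
construction.  Channel levels (mean ± SD): MK 0.94 ± 0.10, AK 0.71 ± 0.08,
RK 1.12 ± 0.14, KA 0.34 ± 0.05, in the range typical of adult gray
matter.  A non-positive-definite target is repaired by eigenvalue
clipping (renormalized to unit diagonal) and flagged.

*Functional*: a one-factor-per-module model — region i in module m reads
loading·f_m(t) + noise — chosen because only the pairwise Pearson
structure matters downstream and the implied correlation,
loading²/(loading²+noise²), is available analytically for tests.
Defaults: loading 0.7, unit noise (within-module r ≈ 0.33), patient
loadings × 0.7 (r ≈ 0.19).

*MoCA coupling*: score = round(clip(intercept + features·β + N(0, σ), 0,
30)), enabling parameter-recovery tests of the predictor.

What the generator does **not** emulate: spatial autocorrelation and
hemodynamic smoothness of BOLD, heavy-tailed or site-dependent kurtosis
distributions, motion artifacts, age/sex effects on connectivity, and
any realistic coupling between the structural and functional channels of
the same subject.  Passing tests therefore demonstrate that the
machinery is correct and calibrated under its stated assumptions — not
that the biological effect sizes of any real cohort are reproduced.  No
published effect sizes exist for the underlying raw data, so generator
defaults are chosen for plausibility, not calibrated to the reported
group differences.

## Numerical choices

- Edge counts use floor; tie-breaks are lexicographic and logged.
- Fisher z clipped at |r| = 1 − 1e−7.
- Null ensembles seeded per threshold (seed + threshold index) so curves
  are reproducible independently of evaluation order.
- KKT systems solved by dense inversion (n ≤ 100 here); singularity
  raises with a hint that smaller C adds jitter I/C.
- Matrices are written as `%.17g` text and read with round-trip float
  parsing, so write→read is bit-exact.
- The a-schedule uses a = 2 − 2t/(T−1), hitting exactly 2 and 0 at the
  endpoints.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desk scale: 100-null
ensembles on full sparsity grids for a handful of networks (two group
structural networks; 4–6 functional subjects — the group-mean γ is stable
to well under the assertion margins beyond a few subjects), 25-seed
parameter-recovery sweeps for the predictor, and 50 × 1000-permutation
calibration runs on a thinned grid (the calibration property is
grid-independent).  All are the package's own choices of problem size and
are configurable upward.

## Known limitations

- The structural permutation mode permutes the Cp AUC only; normalized
  metrics inside a permutation loop are computationally prohibitive and
  statistically redundant for calibration checks.
- Lp on disconnected graphs depends on the stated finite-pairs
  convention; compare `connected_fraction` before interpreting Lp at low
  sparsity.
- MAPE is scale-dependent and undefined at zero scores; it is reported
  only because it is conventional alongside MSE/RMSE/MAE.
- The WOA is a metaheuristic: seeded runs are reproducible, but there is
  no optimality guarantee beyond the benchmarked behavior.
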