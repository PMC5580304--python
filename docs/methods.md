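# Methods

`mcda_hh` implements the two multi-criteria decision-analysis (MCDA)
procedures used to decide which of two hand-hygiene methods — washing
with antimicrobial soap and water, or rubbing with an alcohol-based
antiseptic solution (ABAS) — a panel of infectious-disease and clinical
microbiology specialists prefers, judged against seven criteria (short
application time, glove usage, dry and cracked skin, staff workload,
ease of use, intervention type, efficiency).

## Entropy-weighted MAUT

The panel's 1–5 Likert ratings are averaged per (alternative, criterion)
cell into a decision matrix `X` (m alternatives × n criteria, all
benefit-type). The pipeline is:

1. **Column normalization** — `r_ij = x_ij / Σ_p x_pj`, so each column is
   a share vector.
2. **Shannon entropy per criterion** — `e_j = −(1/ln m) Σ_i r_ij ln r_ij`,
   with the convention `0·ln 0 = 0`. `e_j = 1` exactly when the column is
   uniform (the criterion does not discriminate), `e_j = 0` for a
   degenerate column.
3. **Entropy weights** — `w_j = (1 − e_j) / Σ_p (1 − e_p)`; criteria that
   discriminate more get more weight, and `Σ w_j = 1` by construction.
4. **Utilities** — `u_ij = (x_ij − min_i x_ij) / (max_i x_ij − min_i x_ij)`;
   with two alternatives this is exactly the 1/0 assignment to the
   better/worse alternative per criterion.
5. **Total utility** — `U_i = Σ_j w_j u_ij`; the alternative with the
   highest `U_i` wins.

Numerical choices:

* All internal computation is full double precision; only display output
  is rounded to 2 decimals (the convention of the study's tables).
* A tied criterion column (`max = min`) makes step 4 a 0/0; every
  alternative then receives the neutral utility 0.5 and a
  `TiedCriterionWarning` is emitted, so a tie can never silently favour
  one side.
* If *every* criterion column is uniform, entropy weights are undefined;
  this is an error ("no discriminating criteria"), not a silent fallback
  to equal weights — such data are almost certainly wrong.
* With m = 2 and no ties, `U_A + U_B = 1` for any weight vector; this is
  asserted as an invariant.

## Group AHP

Each expert fills a positive reciprocal pairwise matrix `A` on the
Saaty scale (`a_ij ∈ {1/9 … 1/2, 1, 2 … 9}`, `a_ji = 1/a_ij`,
`a_ii = 1`): `n(n−1)/2` judgments for n items.

* **Validation** parses decimal and rational (`"1/5"`) entries; rational
  entries are kept as exact fractions so reciprocity is checked without
  float slack (tolerance 1e-6 otherwise, 1e-9 on the diagonal). Raw
  expert matrices must stay on the discrete scale; aggregated matrices
  may legitimately fall between scale values and skip that check.
* **Priorities** come from the principal right eigenvector, computed by
  power iteration from the uniform vector with L1 tolerance 1e-12 and a
  10,000-iteration guard (Perron–Frobenius guarantees convergence for
  positive matrices; the guard only catches programming errors).
  `λ_max` is the mean of the component-wise Rayleigh ratios
  `(Ap)_i / p_i`, which is exact at the fixed point. The row geometric
  mean (`p_i ∝ (Π_j a_ij)^{1/n}`) is kept as a second, independent
  derivation; the two agree within L1 0.05 whenever CR < 0.05 (property-
  tested), but can differ more for badly inconsistent matrices.
* **Consistency** — `CI = (λ_max − n)/(n − 1)`, `CR = CI / RI` with the
  standard random-index table `{3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
  7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}`; CR < 0.10 is acceptable
  (threshold configurable). Orders 1–2 are always consistent, so CR is
  defined as 0 there; orders above 10 require a user-supplied extended
  RI table.
* **Group aggregation** is the entry-wise geometric mean with equal
  expert weights — the only separable aggregation rule that maps
  reciprocal matrices to reciprocal matrices.
* **Synthesis** is distributive only: `global_i = Σ_j w_j p_ij` over a
  goal → criteria → alternatives hierarchy. Ideal-mode synthesis is out
  of scope.

## Reliability

`cronbach_alpha` implements
`α = k/(k−1) · (1 − Σ var(item) / var(total score))` with sample (n−1)
variances. Missing responses are rejected rather than imputed (the
motivating study states no missing-data policy). The study's published
α values (0.74 for the Likert form, 0.77 for the pairwise form) cannot
be recomputed because the raw responses are unpublished; they are
carried in the reproduce report as reference metadata only.

## Synthetic expert panels

The raw 15-expert questionnaire is unpublished, so the simulator
(`mcda_hh.synthetic`) generates panels with the statistical structure the
analysis assumes, making every stage testable without any download.

* **Likert channel**: rating = `round(clamp(Normal(latent mean, σ_L), 1, 5))`
  — a discretized truncated Gaussian, the simplest mechanism with a
  single dispersion knob. Default σ_L = 0.7 Likert points (roughly one
  scale step of disagreement between experts).
* **Pairwise channel**: for each unordered pair, the judged ratio is
  `w_i/w_j · exp(ε)`, `ε ~ Normal(0, σ_P²)` drawn once per pair, snapped
  to the Saaty scale, then mirrored exactly (`a_ji = 1/a_ij`), so every
  simulated matrix is scale-legal and exactly reciprocal. Snapping uses
  the **geometrically nearest** scale value (nearest in log space): the
  noise is multiplicative, so log distance is the natural metric.
  Default σ_P = 0.25, i.e. moderate judgment noise; at that level the
  simulated per-expert CRs fall around 0.01–0.05 — consistent experts,
  somewhat cleaner than the published per-participant CRs (0.07–0.09).
* **Defaults reproduce the study's shape**: 15 experts, 7 criteria,
  2 alternatives. Latent cell means are anchored at the four published
  cell means (soap/glove-usage 4.27, soap/easy-to-use 2.85, ABAS/short-
  time 4.23, ABAS/dry-skin 3.00) with plausible mid-scale fills
  elsewhere, keeping ABAS ahead on 5 of 7 criteria as published. Latent
  criterion weights are the four published AHP weights (efficiency 0.35,
  intervention type 0.19, easy to use 0.12, dry skin 0.07) with the
  unpublished remainder 0.27 split equally over the other three.

What the simulator does **not** model: inter-expert correlation (e.g.
experts from the same institution judging alike), response styles
(acquiescence, central tendency), or any criterion being cost-type.
Passing recovery tests therefore show the pipelines are correct and
well-conditioned under independent, unbiased expert noise — not that
the published study's field data meet those assumptions.

### The snap-bias dithering effect

`recovery_experiment` measures the L1 distance between the latent weight
vector and the eigenvector of the aggregated simulated panel. Because
judgments are quantized to the Saaty scale, σ_P = 0 does **not** give
zero error: every expert then emits the *identical* snapped matrix, and
the deterministic snap bias (~0.03 L1 for the default weights) survives
aggregation unchanged. A little noise (σ_P ≈ 0.1) acts as dither — the
snap errors vary across experts and pairs and partially cancel in the
geometric mean — giving a *lower* median error (~0.019) than the
noiseless limit. Median error is therefore monotone in σ_P only on
grids away from 0 (e.g. {0.1, 0.25, 0.5}); the sweep in
`analysis/03_panel_simulation.py` shows the full curve, and the
monotonicity test uses paired seeds across noise levels (common random
numbers) because the 0.1-vs-0.25 difference is smaller than the
Monte Carlo spread of 20 independent panels.

## The published combined matrix

The bundled 7×7 combined pairwise matrix (transcribed exactly, including
the fractional entries) is a valid reciprocal matrix, but recomputing
from it contradicts the study's own summary: the principal eigenvector
ranks *dry and cracked skin* highest (0.234) with *efficiency* second
(0.194), and λ_max = 8.453 gives CR = 0.18 — far above the 0.10
threshold — whereas the study reports efficiency 0.35 on top, dry skin
0.07 at the bottom, and a combined CR of 0.01. The study's discussion
itself notes the tension between the pairwise table and the reported
ranking. This package computes and reports what the printed matrix
implies and attaches the discrepancy note; the published summary
figures are shipped as reference metadata and are never asserted as
expected outputs. The per-criterion alternative-level matrices behind
the published global priorities (0.69 ABAS / 0.31 soap) were never
printed, so hierarchical synthesis is exercised on synthetic
hierarchies only.

## Problem sizes

All analyses run at desk scale: the study's own 2×7/7×7 fixtures, 1,000
random 2×7 matrices for the pipeline-vs-brute-force equivalence check,
500 consistent matrices of orders 3–10 for eigenvector recovery, 200
random reciprocal panels for aggregation reciprocity, and 20 simulated
panels per noise level for the recovery sweep. The whole test suite and
all analysis drivers complete in well under a minute on one CPU.
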