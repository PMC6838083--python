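# Methods

## Data model and assumptions

Input are quantification-cycle (Cq) values from two-group RT-qPCR
experiments, one technical triplicate per (sample, gene). Cq is treated as
log2-scale expression at 100 % amplification efficiency, so a Cq difference
of δ corresponds to a 2^δ fold change and the log ratio of two genes is
simply the difference of their Cq values. Because the RNA input per sample
is fixed, any per-sample quantity common to all genes (a "loading" shift)
cancels in these differences; every statistic in the package operates on
pairwise differences and is therefore invariant to such shifts. Cq values
are modelled as Gaussian with equal variances across groups; departures
(heavy tails, outliers) inflate the estimated spread, which makes the
equivalence test conservative rather than anti-conservative.

## Triplicate quality control

Two rules are applied, in this order, before any analysis:

1. **Failure rule** — a triplicate is *failed* when any replicate is
   undetected or detected after `max_cq` cycles (default 32). A failed
   triplicate yields a missing cell; a late replicate is never "rescued" by
   the outlier rule below. The strict inequality is used (exactly 32.0
   does not fail).
2. **Outlier rule** — when the sample SD (n − 1 denominator) of a non-failed
   triplicate exceeds `sd_threshold` (default 0.5 cycles), the single
   replicate with the largest absolute deviation from the triplicate mean
   is removed and the mean of the remainder is emitted. The rule is applied
   exactly once, never iterated; deviation ties are broken by dropping the
   replicate with the larger replicate index (deterministic and independent
   of row order).

All SDs in the package use the n − 1 denominator. Undetected markers
accepted on input (case-insensitive): empty cell, `NA`, `ND`,
`Undetermined`. A group contributing fewer than two values to a summary SD
reports that SD as undefined (NaN), never as zero.

## The pairwise equivalence test

For genes (a, b), d_s = Cq_a − Cq_b per sample (samples missing either gene
are excluded pair-wise). The between-group effect is
estimate = mean(d | group 2) − mean(d | group 1), where the group order is
the first-seen order of the labels. With pooled variance
(df = n₁ + n₂ − 2) the TOST p-value is

    p_tost = max[ P(T_df > (estimate + Δ)/se),  P(T_df < (estimate − Δ)/se) ],

the exact dual of requiring the (1 − 2α)-level confidence interval inside
[−Δ, +Δ]. Degenerate cases: zero pooled variance gives p = 0 when
|estimate| < Δ and p = 1 otherwise; a pair with fewer than two usable
samples in either group is *untestable* and reported distinctly from
p = 1 — untestable pairs can never create a graph edge. A Welch variant
(`variance_mode="welch"`) exists but the pooled test is the default, per
the equal-variance model. Only two-group designs are supported; more
groups are rejected with an explicit error rather than silently pooled.

## Graph construction and selection

Edges require `p_tost < cutoff` (strict). Maximal cliques are enumerated
with networkx's pivoting Bron–Kerbosch implementation (the contract is the
output set, verified in the tests against exhaustive subset search);
cliques are reported sorted by size then lexicographically, so reports are
reproducible. The selected set is the intersection of all
maximum-cardinality cliques; when several disjoint maximum cliques make
that intersection empty, the selection is returned empty and flagged
*ambiguous* instead of inventing a fallback. Selections whose maximum
clique is smaller than `min_reliable_clique` (default 4) are flagged
unreliable: small cliques arise too easily from chance edges, since a
clique of N nodes needs only N(N−1)/2 simultaneous rejections. The
`delta_profile` helper re-runs the pipeline across a margin grid and
annotates each gene with the smallest Δ at which it enters the selection —
a partial stability ranking induced by the margin.

## Cutoff calibration

The per-pair cutoff is chosen by Monte-Carlo simulation so that, under a
null where **no** pair is equivalent, the probability of any ≥ 3-node
clique stays at or below `target_fwer` (default 0.05). The built-in null is
the **fence**: gene g receives a between-group shift of g·Δ, so every
adjacent pair sits exactly on the equivalence margin — the least
favourable chain for false edges — and every pair differs by a non-zero
multiple of Δ. Residual noise is i.i.d. Gaussian per cell with SD
`residual_sd`/√2, so that pairwise differences have within-group SD
`residual_sd`.

Implementation: each simulated dataset is reduced to its *critical cutoff*,
the minimum over gene triples of the largest of the three pairwise
p-values; the spurious-clique probability at cutoff c is then the fraction
of critical cutoffs strictly below c. This uses common random numbers
across candidate cutoffs, making the search exactly monotone, and a fixed
seed yields a bit-identical result. The calibrated cutoff is the largest
value on a 0.001-resolution grid meeting the target; if even the smallest
grid value fails, the result is flagged unsuccessful with the achieved
probability. The Monte-Carlo SE of the achieved probability is reported so
"≤ 0.05" statements are interpretable.

Defaults and caveats:

* `residual_sd` defaults to 1.0 cycle, i.e. a per-gene inter-individual SD
  of ≈ 0.7 cycles, mid-range for human cell-line panels; when real data are
  available the estimator `estimate_residual_sd` (pooled within-group SD of
  all pairwise differences) should be used instead, as the
  `cutoff="calibrate"` mode of `EquivalenceCliqueSelector` does. The
  calibrated cutoff is quite sensitive to this scale (measured at G = 30,
  n = (14, 26), Δ = 0.5, 4,000 simulations: cutoff 0.38 / 0.21 / 0.16 /
  0.18 for residual_sd 0.6 / 0.8 / 1.0 / 1.3 — non-monotone because the
  noise both creates and destroys the triangle-closing cross edges).
* Under this fence null the calibrated cutoff **decreases** as the number
  of candidate genes grows (more triples, more opportunities for a spurious
  clique): measured 0.34 / 0.24 / 0.17 / 0.16 for G = 5 / 10 / 20 / 30 at
  residual_sd 1.0. Folklore in the field sometimes states the opposite
  direction; that presumably reflects a differently-constructed null, and
  no such claim is asserted here.
* The spurious-clique probability is exactly non-decreasing in the cutoff,
  but *not* monotone in Δ, because the fence spacing scales with Δ.
* On very clean data (residual noise far below Δ) the fence null produces
  almost no spurious cliques at any cutoff, and the calibrated cutoff
  drifts towards 1 — family-wise control becomes vacuous and stops being a
  useful way to pick an operating point. The explicit-cutoff mode exists
  for exactly this situation, and the synthetic-recovery checks in this
  repository run at an explicit cutoff of 0.3.

## Comparison rankers

**geNorm.** M_j is the mean over partner genes k of the across-sample SD of
(Cq_j − Cq_k), computed pairwise-complete over samples. The gene with the
largest M is removed (ties: the lexicographically last gene) and M is
recomputed until two genes remain; those share the M of the two-gene set
and are reported as an unordered best pair, both with rank 1. A strict mode
refuses missing cells.

**NormFinder** (grouped, two-group variant). Each sample is centred across
genes (removing the compositional loading), then per gene i and group g the
group mean ȳ and naive variance s² are computed. Because centring across n
genes correlates the residuals, the per-gene variances are de-biased as
σ̂²_ig = (s²_ig − Σ_i' s²_i'g / (n(n−1))) · n/(n−2), clipped at zero. The
inter-group bias d_ig = ȳ_ig − mean_g(ȳ_ig) is shrunk towards zero in
proportion to its sampling variance, with the between-gene bias variance
γ̂² = Σ d²/((n−1)(k−1)) − mean(σ̂²/n_g), clipped at zero, and the stability
value is the group-average of |shrunken bias| plus its posterior SD. Lower
is more stable; the ranking is deterministic with lexicographic
tie-breaking. Missing cells are imputed with the (gene, group) mean —
casewise deletion is not viable at realistic failure rates, where almost
every sample misses at least one of 30 genes — and a strict mode refuses
missing data; a gene with no usable value at all in some group is rejected
with an explicit error.

Both rankers treat Cq directly as log2 expression, so geNorm's log-ratio SD
is the SD of Cq differences.

## Synthetic data generator

Cq(s, g, r) = baseline_g + effect_g·1[s ∈ group 2] + loading_s +
individual_(s,g) + analytical_(s,g,r), with planted genes sharing one
common effect and decoys receiving effects that pairwise differ (and differ
from the planted effect) by at least the design spacing. Defaults:
loading SD 0.5, inter-individual SD 0.2, analytical SD 0.1 cycles —
decomposing an observed per-gene Cq SD of ≈ 0.54 (√(0.5² + 0.2²)) into a
common-mode part that cancels in ratios and a gene-specific part, with
technical replicate noise around 0.1. Outliers add a fixed magnitude
(default 5 cycles) to single replicates; failures turn single replicates
into late (32.5–40 cycles) or undetected measurements, half and half. All
randomness flows from one seed; the truth record (baselines, effects,
loadings, individual noise, outlier and failure positions) is emitted
beside the data so downstream checks never re-derive the ground truth.

Presets: the study-scale preset uses 30 genes, groups of 14 + 26,
triplicates, 7 planted genes, decoy spacing 0.6 cycles, outlier rate 1 %,
failure rate 0.5 %; the recovery preset plants 6 of 15 genes with
1.0-cycle decoy spacing. Preset baselines are drawn from 14–24 cycles so
that differential shifts do not push genes past the 32-cycle failure rule;
genes amplifying near the detection limit are represented through the
failure rate instead.

What the generator does **not** emulate: amplification-efficiency
heterogeneity between genes, non-Gaussian biological variation, correlated
expression between decoy genes, plate/batch effects, or Cq-dependent
technical noise. Passing the synthetic checks therefore demonstrates the
statistical machinery (QC, TOST, clique selection, calibration) under the
stated model, not robustness to those real-data features.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's standard verification settings: TOST/CI duality on
1,000 random configurations; clique enumeration against exhaustive subset
search on 500 random graphs of ≤ 12 nodes; family-wise control verified
with a 2,000-simulation calibration at G = 10, n = (14, 26), Δ = 0.5 and
2,000 fresh null draws (tolerance 0.05 + 3 Monte-Carlo SEs); planted-set
recovery over 200 simulated studies (threshold 95 % exact recovery);
cutoff calibration reported at 10,000 simulations for the 30-gene design.

## Known limitations

* Two-group designs only; no paired or multi-factor layouts.
* Only the Gaussian TOST ships; the equivalence test is a small pluggable
  surface (any function producing a p-value per pair can replace it), but
  no non-parametric variant is included.
* The calibration null is the fence configuration; other least-favourable
  configurations (e.g. clustered decoys) are not explored, and the
  calibrated cutoff should be read as specific to this null and to the
  supplied residual SD.
* Efficiency is assumed to be 100 %; no standard-curve correction.
* Checks against the original 30-gene laboratory dataset require that
  dataset to be supplied locally; it is not redistributed here.
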