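# Methods

This note documents the models, parameter choices and numerical conventions
behind `hexasense`, and what the synthetic validation does and does not show.

## The AICAP pipeline

**Model.** Treating cells with 1,6-hexanediol dissolves hydrophobic-
interaction-dependent condensates; chromatin-associated proteins that depend
on them are released and recovered at lower abundance in the treated
chromatin fraction. The index is a ratio of normalized abundances,

AICAP_p = mean_r FOT̃_p(treated, r) / mean_r FOT̃_p(control, r),

where FOT̃ is the fraction-of-total abundance (iBAQ / sample total × 10⁶)
after per-sample minimum imputation and quantile normalization. Replicates
are averaged, not paired; significance is a two-sided Welch t-test per
protein (the variant is unstated upstream; Welch is the conservative
default for unequal variances).

**Order of operations and their consequences.**

* FOT makes the index compositional: only relative abundances survive. The
  pipeline is therefore exactly invariant to rescaling any input sample by a
  positive constant (tested).
* Minimum imputation presumes left-censoring — a missing value means "below
  detection", and the smallest observed value in that sample approximates
  the detection floor. The minimum is taken **per sample** (column), because
  detection floors are run-specific. A protein missing in some replicates of
  one condition is pulled toward the floor there, which preserves the
  direction of strong depletion but adds noise near the detection limit.
* Quantile normalization forces every sample onto the common order-statistic
  distribution, which makes the index effectively rank-based. Ties (created
  en masse by imputation) receive the average of the reference values over
  the tied block; consequently the "all sorted columns identical" invariant
  is exact only on tie-free tables, which is how it is tested.

**Grouping.** Six sensitivity groups on left-closed bins
[0, 0.3), [0.3, 0.5), [0.5, 0.7), [0.7, 0.9), [0.9, 1.1), [1.1, ∞). Only the
lowest bin's label is fixed by the source material; the remaining edges are
0.2-wide steps placed symmetrically around 1.0 — a package convention.

**Preranked enrichment.** Proteins are ranked ascending by AICAP (most
sensitive first), metric = max(1 − AICAP, 0), weight exponent 1. Hit steps
are metric-proportional (normalized to 1 over hits), miss steps are
−1/(N − N_hits), ES is the signed maximum deviation of the running sum. The
permutation p-value shuffles set-membership labels,
p = (1 + #{|ES_perm| > |ES|}) / (n_perm + 1); ties do not count as
exceedances so a maximal observed ES attains the minimal attainable p. With
every protein in the set the statistic is defined as 0.

**Residue composition.** For proteins with AICAP < 1, the fraction of each
of the 20 residues is computed in four region classes — whole sequence,
whole minus IDR, IDR, PLD — and Spearman-correlated (average ranks) against
AICAP. Proteins with an empty region class are excluded for that class;
residues absent everywhere yield an undefined (NaN) correlation.

## Synthetic proteomics generator

The generator emulates a label-free experiment with 3 control and 3 treated
replicates over 500 proteins (defaults; all overridable):

* abundance: log-normal, sdlog 2.5 (≈5 orders of magnitude dynamic range,
  typical for label-free iBAQ);
* depletion field: 25 % of proteins are exactly unchanged (d = 1, the
  histone-like bulk); the rest model treatment as a balanced redistribution —
  released condensate proteins (d < 1) and cytoplasmic proteins gaining
  access (d > 1). Log-factors are drawn antithetically (each x paired with
  −x, sdlog 1.0) on abundance-adjacent proteins, so the field has median 1
  in every abundance stratum. This matters because the quantile-normalized
  index is rank-based: a log-skewed field would systematically shift the
  measured AICAP of unchanged proteins away from 1;
* noise: log-normal with CV 0.2 per replicate;
* missingness: left-censoring — a cell is missing with probability
  sigmoid(−(log λ − μ)/s), censoring width s = 0.3 natural-log units
  (sharp, detector-like), with μ solved by bisection so 20 % of all cells
  are censored. Proteins detected in **no** sample are dropped from the
  table, as in a real search-engine output; the truth object keeps them
  flagged. Recovery statistics are computed over detected proteins — the
  only proteins for which an index exists in a real experiment.

What passing recovery tests show: the pipeline identifies the planted
depletion order (Spearman ≈ 0.91–0.94 across seeds) and keeps unchanged
proteins calibrated (mean AICAP within ≈0.05 of 1). What they do not show:
robustness to batch effects, peptide-level noise structure, shared-peptide
protein inference, or interference — none of which the generator emulates.

## Hi-C model and analysis

**Generator.** Expected counts for one chromosome,

λ_ij = depth-scale · b_i b_j · (|i−j|+1)^(−α) · (1 + c_i c_j √(δ_i δ_j)) · T_ij · L_ij · S_ij,

with per-bin biases b (log-normal, sdlog 0.2, mean-normalized), decay
exponent α = 1, compartment signs c_i = ±1 in alternating blocks and per-bin
strengths δ_i < 1, a within-TAD factor T (default 2–2.5), loop factors with
Gaussian spill (σ = 0.5 bins, so APA sees a peak rather than a delta), and
stripe factors along anchor lines. Counts are Poisson; both conditions are
drawn with a common random-number stream so identical truths give identical
matrices and paired comparisons are low-variance. Overdispersion (negative
binomial) is not modelled.

**Balancing.** Knight–Ruiz iteration (inner–outer Newton with CG inner
solves) targeting unmasked row sums of 1, with a plain Sinkhorn fallback;
tol 10⁻⁶ on the row-sum deviation, max 3000 iterations, bins with < 10
non-zero pixels masked. An independent Sinkhorn implementation serves as the
test oracle. A practical consequence verified here: balancing absorbs part
of any enrichment concentrated on a single row — a planted stripe of factor
3 reads as ≈2.1 after balancing because the anchor-row weight shrinks;
single-pixel loops lose only ≈5–10 %. Stripe statistics are therefore
validated as strong detection against a null, not as exact factor recovery.

**Expected model and transforms.** Expected(s) is the plain per-distance
mean of balanced values over unmasked pixels (no smoothing); O/E divides by
it; the Pearson matrix correlates O/E rows pairwise-complete. Compartments
are the leading eigenvector (unit norm) of the Pearson matrix, negated if it
anticorrelates with a gene-density reference; A = PC1 > 0. Known
limitations: only the first eigenvector is used (no arm-tracking fallback),
and the Pearson transform saturates — correlations encode the sign pattern,
not per-bin amplitude, so the per-bin PC1 ratio responds only weakly to a
planted strength change at high depth. The change classification (ratio
within ±20 % inclusive = stable; beyond = weakened/strengthened; opposite
signs = flipped) therefore recovers direction in aggregate (A bins weaken
more than B bins when only A is perturbed) but not bin-by-bin majorities;
eigenvectors are rescaled to unit standard deviation over shared bins before
ratios are formed, since their natural scale is arbitrary.

**TADs.** Insulation is the mean balanced value in a w×w square upstream ×
downstream of each bin (w = window/resolution, canonical 1 Mb at 40 kb,
i.e. 25 bins; the square must be smaller than a TAD to resolve it), log2-
normalized to the chromosome mean. The delta vector is right-flank mean
minus left-flank mean over d bins (canonical 200 kb = 5 bins); boundaries
sit at negative-to-positive zero crossings (the lower-insulation bin of the
crossing pair), with strength = max(delta over [i, i+d]) − min(delta over
[i−d, i]) and a 0.1 floor. Cross-condition matching is greedy closest-pair
within ±80 kb, ties to the leftmost; swapping inputs swaps lost and gained.
Intra/inter-TAD change ratios pool subcompartments as A1 / A2+B1 / B2+B3
(configurable), skip pairs joining different groups, and cap inter-TAD
separation at 10 Mb to keep the ratio distance-comparable.

**Loops and stripes.** Anchors map to bins by midpoint. Loop signal change is
the ratio of contact probabilities (balanced value over total balanced
signal — depth-independent) at the loop pixel; zero or masked before-values
are flagged undefined and excluded from summaries. APA averages
(2h+1)×(2h+1) O/E windows (h = 10) over loops whose windows stay on-matrix
and off-diagonal; center enrichment is the center over the mean of the h×h
far-from-diagonal corner block; grouped APA divides each group by its own
loop count. Differential loops use slopped (±10 kb) both-anchor interval
overlap, order-preserving. Stripe aggregation reads O/E along the stripe
line and compares with the same profile offset perpendicular by ±5 bins (the
background construction is this package's choice; the upstream geometry is
not fully specified).

## FRAP

Double normalization: background subtraction, bleached/control ratio, then
division by the pre-bleach mean (3 baseline frames), making the trace a
proportion of pre-bleach intensity and cancelling acquisition
photobleaching. The recovery model A(1 − e^(−t/τ)) + y0 is fitted by
bounded nonlinear least squares (A ∈ [0, 2], τ ∈ (0, 10·span],
y0 ∈ [0, 1.5]) with data-driven initialization (A₀ = last − first, τ₀ =
first half-recovery crossing, fallback span/3). Time is anchored at the
first post-bleach frame so y0 is that frame's intensity; t₁/₂ = τ·ln 2 by
the model's closed form. Flat traces return A = 0 with a wide-τ flag rather
than an arbitrary time constant. The mobile-fraction-versus-AICAP relation
is ordinary least squares with the Pearson r and the two-sided slope test.

## Problem sizes and determinism

All validation runs use desk-scale problems chosen to expose each effect
cleanly: 500 proteins × 6 samples; 200 bins at 100 kb (compartments,
depth 10⁶); 200 bins at 40 kb (TADs, depth 5×10⁵); 300 bins at 5 kb
(loops/stripes, depth 2×10⁶); 100-frame FRAP traces. Every stochastic step
is a pure function of (parameters, seed); the acceptance script derives all
sub-seeds from its `--seed` argument. The full test suite runs in a few
seconds on one CPU.
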