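# Methods

## The inference problem

NK cells from a donor panel are cultured under numbered cytokine regimens,
each a priming cocktail (0–16 h) followed by a post-priming-I cocktail
(16 h–day 3) and a maintenance phase that the model ignores.  Cell counts
relative to day 0 ("fold expansion") are recorded on days 2, 4, 7 and 9
(later days exist in the data model but do not enter the analysis).  The
question the framework answers: which STAT/NF-κB activation pattern, and
which form of interaction between the priming and post-priming phases,
best explains and predicts the cohort-level day-9 response — and which
factor pairs act synergistically or antagonistically.

## Donor weighting

Cross-donor averaging uses weights inversely proportional to the distance
of a donor's cross-condition variance from a robust center,
`medme = 0.1·mean + 0.9·median` of the group's variances.  The deviance
`d_i = |σ²_i − medme|` is floored at `1e-9 · median(σ²)` so a donor sitting
exactly on the center gets a large but finite weight; weights are
normalized to sum to one within each donor group.  Two conventions are
selectable: sample (n−1, default) or population variance, and absolute
(default) or squared deviance.  Two degenerate cases are handled
explicitly: a single donor receives weight 1 with a warning, and
all-equal deviances fall back to uniform weights.  Note a limiting quirk:
as one donor's variance diverges, its weight tends not to zero but to a
small constant (≈ q/(N−1+q·(N−2)) with q = 0.1/(N·0.9) scale coupling,
numerically ~0.008 at N = 4), because the 0.1·mean term in medme grows
with the outlier; the damping is still roughly an order of magnitude below
uniform.

## Imputation maps and activation matrices

The 64 maps arise from the fixed primary assignments and the secondary
pools (IL-2: subsets of {STAT1, STAT3, STAT4, NF-κB}; IL-18: {STAT3};
IL-21: {STAT1}; IL-12/IL-15: none).  Canonical map order is lexicographic
over (IL-2 secondary bitmask, IL-18 bit, IL-21 bit); because any such
numbering is an artifact of that order, all reporting keys on an
index-independent content signature, and the map found optimal for the
study data (IL-2 → STAT5/STAT4/STAT1, IL-18 → NF-κB/STAT3,
IL-21 → STAT3/STAT1) is exposed by content as `reference_optimal_map()`.
Activation is binary by construction: a factor is "on" in a phase iff any
cytokine present in that phase activates it under the map — magnitudes are
deliberately not modeled.

## RReliefF and the constraint filter

The regression Relief variant scores each of the 10 features in [−1, 1]
from k-nearest-neighbor contrasts (Manhattan distance, ties broken by
instance order, uniform neighbor influence — no distance decay; response
differences normalized by the response range; binary feature difference =
inequality indicator).  Constant features score exactly 0, which has a
structural consequence: a feature that never varies across the condition
panel can never satisfy a positivity constraint, so the condition panel
must toggle STAT3 and NF-κB in both phases for the filter to be
satisfiable at all.  The filter itself imposes (1) condition 2 induces
STAT3 (checked structurally, either phase) and (2) positive weights for
STAT3 and NF-κB in both phases across neighbor counts k = 2…10.  Two
aggregation rules over k are exposed: `all` (strict) and `majority`.  The
strict rule proved brittle on a 12-point response — single k values
occasionally flip sign from local neighbor geometry — so the synthetic
validation protocol uses `majority`; both remain available.

## Regression families, fitting and selection

Eight design families combine per-phase linear terms (5 columns) and
within-phase pairwise products (+10): single-phase (5/15), additive
concatenation (10/30) and multiplicative cross-phase products (25/225).
Multiplicative families are fit as free linear models over the product
columns, not rank-1 constrained, so the stated predictor counts are exact.
Fits minimize ½‖Y − Xβ − b‖² + λ·penalty with a free intercept and
unstandardized binary predictors; LASSO via scikit-learn coordinate
descent (tolerance 1e-12), Ridge in closed form, and λ = 0 falling back to
minimum-norm least squares.

Model selection runs leave-one-condition-out CV for every (feasible map ×
family) pair and ranks by out-of-fold RSS; ties break toward higher R²,
then canonical order, with the tie recorded.  R² is defined as the squared
Pearson correlation between predictions and observations, which is
invariant to affine rescaling of the predictions and would also score
anticorrelated predictions as 1 — the signed ρ is therefore carried in the
result.  Selection defaults to Ridge with fixed λ = 0.1: with 12
observations and up to 225 predictors the folds are badly underdetermined,
and LASSO's held-out extrapolations proved unstable enough to prefer a
wrong map even on noise-free planted data, while Ridge separated the true
map at every λ tested.  Coefficient interpretation and the bootstrap use
LASSO (λ = 0.01 default) so that exact zeros define the retained predictor
set (|β| > 1e-10).  An inner-LOOCV λ search over a 25-point log grid
(1e-4…10) is available (`lam="cv"`) but is not the default, trading the
spec of an adaptive rule for exact reproducibility and runtime.

## Bootstrap and synergy calls

Uncertainty on β comes from resampling donors with replacement within
their groups (sizes 10/4/3), recomputing deviance weights and per-group
weighted averages, and refitting the restricted design per replicate
(1000 by default).  Replicates that draw a single unique donor in any
group are redrawn with the count reported.  A predictor is a synergy if
|⟨β⟩/σ_β| > 2 with ⟨β⟩ > 0, an antagonism with ⟨β⟩ < 0, else inconclusive.
In-silico inhibition zeroes a factor's activation in the priming phase
only by default (inhibitors were applied during priming and washed out);
zeroing both phases is selectable since the original construction is not
pinned down.

## Day-8 statistics

Day 8 is the (day 7 + day 9)/2 midpoint.  Viability weights follow three
rules on the day-2/day-4 values (rising and > 1: day-4 value; > 1 but not
rising: the average — the day4 = day2 tie falls here since the rules'
inequalities are strict; otherwise: the minimum).  Variability weights are
inverse squared distances to the leave-one-out median of the day-8 values;
the floor is additive (`d + 1e-9·mean(d)`), so exact-median donors receive
large finite weight and an all-identical panel degrades to uniform.  The
net weight is the renormalized sum of both.  Condition distributions come
from a 10 000-replicate donor bootstrap with all weights recomputed per
replicate.  The omnibus test is the ANOVA F stage of Fisher's LSD on
donor-level day-8 values; applying it to bootstrap distributions would
inflate the sample size ~1000-fold, so that variant exists for description
only.  The pairwise comparison is a paired label-swap permutation test:
each donor's two condition trajectories are exchanged with probability ½,
the net-weighted day-8 means are recomputed from scratch for every
permuted dataset, and the one-sided p-value is (1 + #{≥ observed})/(n+1),
or the exact enumeration fraction over all 2^n patterns when requested
(n ≤ 20).  Because the outlier-damping weights make the statistic robust
to single-donor swaps, a strongly shifted alternative saturates near — not
exactly at — the resolution floor.

## Synthetic data: what it emulates, and what it does not

`generate_dataset` produces the cohort structure the analysis assumes:
three groups (10/4/3 donors), day-9 responses
`s_i · (Xβ_true)_α · exp(ε)` with log-normal donor scales (σ_log = 0.35
default, spanning over an order of magnitude in cross-condition variances)
and multiplicative log-normal observation noise (σ = 0.1 default; the
response is a positive ratio, so additive Gaussian noise would be
mis-specified — no error model is given for the real data, and this choice
is a stand-in).  One super-responder (donor 7, condition 3, ×3.5,
reaching ~70-fold against a ~20-fold base) is planted by default.  Days
2–7 follow a deterministic monotone interpolation pinned to the day-9
value; only days 7 and 9 matter downstream, the shape is cosmetic, but it
does mean rule-2/rule-3 viability cases arise only from sub-unit
responses, not from non-monotone noise.

Only five condition regimens are documented exactly (1, 2, 3, 12, 13);
the synthetic registry fills 4–11 with clearly labelled stand-in cocktails
chosen as a contrast ladder — near-neighbor condition pairs that toggle
STAT3 or NF-κB in one phase while the complementary phase stays strong.
This is an identifiability requirement, not a convenience: without such
contrasts the constraint filter is structurally unsatisfiable and the map
is not recoverable from 12 points.  The planted β_true is all-positive
with dominant STAT3/NF-κB means (0.5/2.2 pattern per phase, cv 0.15),
encoding the same biology the inhibitor constraints assert.  Passing the
synthetic validation therefore demonstrates internal consistency of the
machinery under a favorable, identifiable design; it does not certify
performance on real panels whose regimens, noise law and donor structure
differ.

## Validation protocol and problem sizes

The planted-truth check generates Y_GT = Xβ_true for the reference map and
multiplicative family, verifies the map survives noise-free filtering
(5 fresh β draws), then runs 50 noisy replicates (multiplicative σ = 0.03
on the 12-condition response — ~10% donor-level noise shrunk by averaging
over ten donors; a power analysis showed map identity degrades above
σ ≈ 0.05–0.07) through filter + full grid selection, scoring the fraction
in which the planted pair attains minimum RSS (measured: 92–100% across
seeds).  Permutation calibration uses 10-donor null panels, 199
permutations, 1000–2000 replicates (measured type-I 3.6–5.9% at nominal
5%).  These sizes keep the whole validation in a few minutes while holding
Monte-Carlo error on the reported rates to a few percent.

## Known limitations

- Conditions 4–11 of the original design are not machine-readable; with
  user-supplied regimens the builtin registry replaces the stand-ins, but
  results on the stand-ins do not transfer.
- Activation is binary; dose effects and partial activation are out of
  scope, as is the maintenance (PP-II) phase.
- The 12-condition response leaves every multiplicative design
  underdetermined; conclusions about individual coefficients lean on the
  regularizer, and the map/family identity is trustworthy only to the
  extent the LOOCV margin exceeds the response noise.
- The deviance-weighting limit quirk above means extreme super-responders
  retain a small constant influence rather than vanishing.
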