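# Methods

## The instrument model

The engine implements the DMRS-Q, a forced-distribution Q-sort over 150
observer-rated item statements, five per defense mechanism. The hierarchy
is fixed: 30 defenses partition into seven levels
(L1 action = {D1 acting out, D2 help-rejecting complaining, D3 passive
aggression}; L2 major image-distorting = {D4 splitting of other's image,
D5 splitting of self-image, D6 projective identification}; L3 disavowal =
{D7 autistic fantasy, D8 projection, D9 rationalization, D10 denial};
L4 minor image-distorting = {D11–D15}; L5 neurotic = {D16 displacement,
D17 reaction formation, D18 dissociation, D19 repression}; L6 obsessional
= {D20–D22}; L7 high adaptive = {D23–D30}), and the levels into three
categories (C1 immature = L1–L4, C2 neurotic = L5–L6, C3 mature = L7).
Two finer splits are carried: L5a hysterical = {D18, D19} vs L5b other
neurotic = {D16, D17}, and the depressive subset C1a = {D1–D6, D8, D14,
D15} vs C1b other immature = {D7, D9–D13}. The psychotic level (level 0)
is outside the instrument and the package.

The item bank is packaged as a denormalized CSV (one row per item with
explicit defense/level/category codes) and validated eagerly on load:
150 items, 30 defenses, exactly five items per defense, the per-defense
item lists forming a bijection onto 1..150, and every declared
level/category code consistent with the hierarchy constants. The
hierarchy is never inferred from item ordering. Item 79 (altruism) has no
recoverable statement text in the published item tables; it carries a
clearly-labelled synthetic placeholder, is flagged
`text_missing_in_paper`, and scores normally — only narrative output is
affected, and only when that item reaches ranks 6–7.

## Scoring

A sort is a total map item → rank obeying the capacities
(60, 30, 20, 16, 10, 8, 6). Validation is total and returns violations
as data (missing/duplicate items, per-rank count deltas); scoring
refuses invalid sorts and attaches the validation report to the error.

Scores follow the published formulas literally. Every valid sort has rank
mass Σ rank(i) = 60·1 + 30·2 + 20·3 + 16·4 + 10·5 + 8·6 + 6·7 = 384, so
subtracting the floor (one rank unit per item) leaves 234 units of
discretionary mass; a defense's score is its share of that mass in
percent. Conservation (defenses, levels, categories each summing to 100)
is therefore an algebraic identity, which the test suite confirms on
1,000 seeded random sorts at 1e−9. Aggregation is done at full floating
precision; reports round to two decimals only at rendering. The constant
234 is not hard-coded into arithmetic: it is the `normalizer` property of
the distribution (total rank mass − item count), so research variants
with other capacities score with the analogous constant, accompanied by a
warning that non-default distributions have no published interpretation.

ODF is the level-weighted mean of defensive mass on the 1–7 scale. An
equivalent single-pass accumulation, ODF = (Σᵢ level(i)·rank(i) − 675)/234
with 675 = 5·Σ_d level(d), is implemented as a separate code path
(`odf_from_items`) purely so the identity can be cross-checked. Over
valid sorts ODF is bounded by the rearrangement inequality: the maximum
1513/234 ≈ 6.466 is attained by filing items in descending level order
into descending ranks, the minimum 553/234 ≈ 2.363 by the mirror image.
The acceptance script re-derives the maximum through the scoring pipeline
and validates it against an LP solution of the 7×7 level-by-rank
transportation polytope (whose vertices are integral, so the LP bound is
attained by an actual sort). A single advisory flag is exposed for
ODF < 4; no further interpretive banding is invented.

## Narrative

The DPN comprises the 14 items at ranks 6–7 (8 + 6 by the capacities),
each entry carrying the verbatim bank statement plus defense and level
labels. Published example narratives do not fix an ordering, so the
engine orders deterministically: rank 7 first (the "almost always used"
pile), then rank 6, ascending item id within rank. Statements are
concatenated as printed, without pronoun harmonization. Reports render as
structured JSON (round-trips losslessly), a 45-row delimited scale table
(30 defenses + 9 level scales + 5 category scales + ODF; plot-ready, no
chart rendering in the core), or markdown.

## Synthetic raters

The simulator exists so the full pipeline — including the reliability
methodology — is exercisable without clinical data. A subject is a latent
profile: nonnegative weights over the 30 defenses summing to 1 (the share
of defensive mass the instrument should attribute to each). A rater
perceives item i with salience w(defense(i)) + ε, ε ~ N(0, noise_sd)
i.i.d., and files items into the forced distribution in descending
salience, ties broken by ascending item id. Gaussian perturbation is the
simplest exchangeable rater model; nothing in the published methodology
constrains the noise law, so noise_sd is a free parameter. Consequences
used as test oracles: noise 0 makes the sort a deterministic function of
the profile (score order matches weight order up to capacity ties, and a
profile concentrated on one defense drives its five items into rank 7,
score 30·100/234 ≈ 12.82, the per-defense maximum); as noise_sd → ∞ the
sorts converge to uniform random sorts, under which each defense's mean
score is 100/30 by item exchangeability.

Every stochastic operation takes an explicit seed (numpy Generator); a
panel cell (subject s, rater r) uses `default_rng([rater_seed, s])`, so
identical rater models reproduce identical sorts per subject and panels
are order-independent.

Study conditions for the packaged experiments, chosen once: subject
profiles drawn from a symmetric Dirichlet(1) over the 30 defenses
(heterogeneous subjects on the natural weight scale ~1/30, per-weight
sd ≈ 0.03); panels of 8 subjects × 3 raters; a five-point rater-noise
grid {0.01, 0.02, 0.04, 0.08, 0.16} spanning noise weak relative to the
profile signal through noise that dominates it; 20 replicates per grid
point. What the simulator does **not** emulate: systematic rater bias
(leniency/severity), item-specific difficulty, halo effects across items
of one defense, or within-subject change over sessions — so passing
recovery tests demonstrates the engine's statistical machinery, not
field reliability of human raters.

## Agreement statistics

ICC uses the two-way random-effects, absolute-agreement decomposition.
With n subjects, k raters, and mean squares MSR (subjects), MSC (raters),
MSE (residual):

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Both single-rater and k-rater forms are reported explicitly because
validation reports in this literature typically say "ICC" without naming
the form; treating raters as random is the defensible choice when raters
are a sample of trained/untrained coders. The mean squares are computed
directly (and are cross-checked in tests against both a brute-force
double-loop ANOVA and pingouin's ICC(A,1)/ICC(A,k)). Numerical policy:
a matrix with total variance ≤ 1e−12 is degenerate — agreement is
returned as 1 with a `degenerate` flag rather than 0/0; negative
estimates are reported as computed (clipped to [−1, 1]) with a
`negative` flag, not truncated to 0; confidence intervals are out of
scope but the variance components are exposed on the result. Q-correlation
between two complete sorts is Pearson (or Spearman) across the 150 paired
ranks; both sorts must be valid and cover the same items.

## Problem sizes and numerical tolerances

Identity-type checks (conservation, dual-path ODF, oracle equivalence)
use 1e−9; pure floating identities typically hold to 1e−12 and are
asserted there when exact algebra guarantees it. Simulation-backed
assertions use sizes that make the statistics stable without waste:
1,000 sorts for conservation, 10,000 for ODF bounds, 8×3 panels × 20
replicates for the noise-decay experiment, 2,000 random sorts in the
acceptance script's bound search. Monotonicity of mean ICC across the
noise grid uses paired subject profiles across grid points to cut
replicate variance.

## Known limitations

* The engine scores completed sorts; partial-sort workflows are limited
  to validation diagnostics (remaining capacity is visible in the
  violation list), since the scoring formulas presuppose a full forced
  distribution.
* No population norms are packaged (none are published); scores are
  ipsative and should not be compared across subjects as absolute
  frequencies.
* The rank-6 vs rank-7 split of the published example narrative is not
  recoverable, so the narrative fixture checks content, not ordering.
* Fitting latent profiles to observed sorts (the inverse problem) is out
  of scope.
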