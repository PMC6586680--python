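# Methods

This note documents the models and procedures implemented in `agrosdm`,
the defaults and why they were chosen, what the synthetic test bed does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## The consensus suitability model

For one species, training data are presence cells (label 1) and
pseudo-absence cells (label 0) with the retained bioclimatic predictors
as features. Each learner in the registry exposes `fit`/`predict_proba`
and returns a suitability probability p_m(x) ∈ [0, 1]. Calibration:

1. **Stratified 4-fold cross-validation.** Rows are permuted within each
   class and dealt round-robin over k = 4 folds, so per-class fold sizes
   differ by at most one and every fold contains both classes (each class
   must have ≥ k rows). Each learner is fit on three folds and scored on
   the held-out fold by AUC, computed with the rank-sum identity
   (probability that a random presence outscores a random absence, ties
   counted ½).
2. **AUC weighting.** Per-learner AUCs are averaged over folds (the
   per-fold AUCs are also retained in the calibration record); raw
   weights are w_m = AUC_m / Σ AUC. Learners with w_m > 0.05 — at least
   a 5% contribution to consensus predictivity — are selected and their
   weights renormalised to sum to one. If no learner clears the cutoff
   the calibration fails loudly rather than producing a vacuous model.
   A learner that raises during cross-validation is assigned AUC 0.5
   (no discrimination, hence typically deselected) and the failure is
   logged; one broken algorithm should not abort a species.
3. **Refit and threshold.** Selected learners are refit on all rows
   (maximising data use for projection), the consensus
   S(x) = Σ w_m p_m(x) is evaluated on the training rows, and the
   presence threshold t* is the smallest observed score maximising
   sensitivity + specificity. The comparison is done in exact integer
   counts, so ties resolve deterministically to the smallest maximiser,
   which maximises mapped presence area. Binarisation uses
   presence ⇔ S(x) ≥ t*.

The default registry holds six learner types: a linear logistic model, a
degree-2 polynomial logistic model, a random forest, gradient boosting,
k-nearest-neighbours (k = 15, standardised features), and a
distance-to-niche-centroid scorer (exp(−d²/2) on standardised distance to
the presence centroid — a deliberately simple climatic-envelope-style
scorer). Any object satisfying the contract can be registered; at least
two learners are required.

## Occurrence processing

Cleaning applies, in order: incomplete coordinates; coordinates outside
[−180, 180] × [−90, 90]; outside the study grid; on a masked
(no-data/ocean) cell; year ≤ 1959 under the default baseline start of
1960. Records with a *missing* year are retained — presence archives
commonly omit dates, and an undated record is not evidence of a
pre-baseline location. The mask check subsumes validation against
external administrative boundaries: its intent (removing implausible
locations) is met by the grid's own validity mask.

Thinning retains one presence per cell of a lattice anchored at the study
grid's north-west origin (cell size defaults to the grid resolution;
2.5 arc-min for realistic configurations), choosing uniformly at random
among co-located records with a fixed seed. The operation is idempotent
and seed-reproducible. Pseudo-absences are drawn uniformly *without
replacement at cell level* from valid cells, by default excluding
presence cells to avoid label contamination (a flag restores the literal
"anywhere in the study area" behaviour); requesting more than the
eligible cell count is an explicit error naming both numbers.

## VIF screening

VIF_j = 1/(1 − R²_j) with R²_j from an intercept-included least-squares
regression of predictor j on all others, computed on a seeded random
subsample of at most 10,000 valid cells (full-grid computation is
available; on the smooth synthetic fields the subsample estimate is
indistinguishable in practice). One predictor — the highest VIF, ties
broken lexicographically for reproducibility — is removed per iteration
while that VIF exceeds the threshold (default 10). Perfect collinearity
reports +inf; a constant predictor is an error naming the variable. The
retained set always audits to all-VIF ≤ threshold (or a single survivor).

## Scenario projection and agreement voting

Futures are modelled as one predictor stack per GCM. The calibrated
consensus is projected onto each stack and binarised with the *baseline*
threshold t* (one derived suitability model; no per-GCM re-thresholding).
Per-cell presence votes v over g maps are integrated with the
likelihood-scale rule: presence if v ≥ ⌈0.66·g⌉, absence if
g − v ≥ ⌈0.66·g⌉ (12 of 17 at the default ensemble size). Cells reaching
neither consensus are conservatively counted as not suitable downstream
but flagged in a separate uncertainty raster so the information is
preserved. The ceiling uses a 10⁻⁹ slack so exact products
(e.g. 0.66 × 50 = 33) are not inflated by float representation.

## Change, replacement and portfolio analysis

Baseline/future binary maps partition cells into remain (1→1), loss
(1→0), gain (0→1) and never (0→0); loss/gain/remain percentages are
relative to the baseline area (cell counts by default; cos-latitude
weighting available — percentages are nearly invariant between the two on
small extents). Altitudinal profiles use half-open 100 m bins plus the
named bands 0–300 m, 400–700 m and >1800 m; band edges are configurable,
and the gap between 300 and 400 m is deliberate (no interpolation is
attempted between named bands). Replacement overlays classify crop A's
loss cells by crop B's future suitability (replaceable vs no
alternative) and A's future cells by B's (both suitable vs A only).
Portfolio richness counts, per cell of the crop area (baseline ∪ future
presence — "remaining and vulnerable"), the tree species projected
suitable, in total and per use group; a cell is high-option when total
richness is strictly greater than 30 *and* every group supplies at least
10 species, low-option when at most 3 species remain (thresholds literal
and configurable). Species-level tables report % change of suitable area
with per-group counts of species losing or gaining more than 15%; species
with an empty baseline get an undefined % change and are excluded from
the tallies.

## The synthetic test bed

Each predictor layer is a unit-variance field: a linear ramp with random
orientation plus white noise smoothed by a fixed 5-cell moving average
(spatial autocorrelation). An elevation layer (0–3000 m) is always
generated; the lowest 5% of the raw elevation field is masked, emulating
ocean/no-data cells. With elevation coupling on, temperature-like layers
(WorldClim bio01–bio11 names, or names containing "temp") have
1.5 × standardised elevation subtracted — since the uncoupled field has
unit variance, this guarantees a negative temperature–elevation
correlation, the property the upslope-shift analyses rely on.

Virtual species have product-of-Gaussians niches
s(x) = Π_j exp(−½((v_j(x)−μ_j)/σ_j)²), the standard virtual-species
construction; the niche centre is placed on a real cell of the landscape
and a common width multiplier is bisected until roughly a target
fraction (default 0.15) of valid cells have s ≥ 0.5. Presences are drawn
with replacement with probability ∝ s(x)·bias(x) and reported at cell
centres (thinning operates at cell granularity, so sub-cell jitter would
add nothing). Pseudo-GCM futures add the scenario mean shift plus a
per-GCM, per-layer *spatially constant* deviation — GCMs are treated as
alternative futures, not spatial error fields, which is sufficient to
exercise agreement voting.

What the test bed does not emulate: the real covariance structure of the
19 bioclimatic variables, land-cover/soil constraints, taxonomic and
georeferencing error beyond the planted defect types, and spatially
structured GCM disagreement. Passing tests therefore demonstrate that the
machinery is correct and that the workflow recovers known niches under
realistic-but-idealised sampling; they do not certify predictive skill on
real archives.

## Validation studies and problem sizes

Two studies quantify end-to-end behaviour (both in
`agrosdm.validation`, reported by `scripts/acceptance.py`):

- **Parameter recovery** — 100×100 grid, 5 predictors, 300 presences,
  1,000 pseudo-absences, the full six-learner registry, k = 4, repeated
  over 10 landscape seeds. Reported: median held-out AUC — the
  consensus's discrimination of the species' *true range* (truth ≥ 0.5)
  against outside-range cells, excluding all training cells — and the
  median cellwise Pearson correlation with true suitability. Scoring
  against the true binary range rather than raw background matters:
  probabilistically sampled presences scored against uniform background
  bound AUC well below 1 *even for the true suitability surface*, so
  that design would measure the sampling process, not the model.
- **Directional climate response** — 50×50 elevation-coupled landscape,
  temperature shifts of 0.5 and 1.0 within-landscape SD (roughly the
  contrast between an intermediate and a high-emissions scenario),
  5 pseudo-GCMs, 10 seeds. Reported: fraction of seeds where the
  integrated future range sits at higher mean elevation than baseline,
  and median loss% under each shift.

The demo pipeline (48×48 grid, 3 species, 2 scenarios × 5 pseudo-GCMs)
is sized to run in well under a minute; its portfolio thresholds are
scaled down (rich_total 0, rich_per_group 1, low_cutoff 0) because one
tree species cannot exercise the full-scale 30/10/3 defaults, which
remain the library defaults.

## Reproducibility conventions

Every generator and sampler is a pure function of its inputs and a seed.
The pipeline takes one mandatory global seed and derives per-stage child
seeds by hashing "stage-label|seed" (SHA-256, reduced below 2³¹),
avoiding RNG coupling between stages; stage commands re-run individually
rebuild deterministic state (e.g. fitted learners) from the run
directory plus those child seeds instead of pickling models, keeping all
artifacts plain text. Grid cell membership is half-open
([edge, edge + resolution) on both axes, rows north→south); binarisation
uses ≥; masked cells carry NaN everywhere so no computation can read
them as data. Run directories record a config hash in every log record
and a SHA-256 manifest of all artifacts.

## Known limitations

Spatially structured sampling bias is supported in the generator but not
corrected for beyond thinning; cross-validation is random rather than
spatially blocked, so AUCs on strongly autocorrelated real data would be
optimistic; the learner registry deliberately does not reproduce any
specific legacy SDM algorithm suite; pseudo-absences are drawn once per
species, not per fold; and areas are computed on the lon/lat grid
(cos-latitude weighting approximates true area but ignores ellipsoidal
corrections).
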