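# Methods

This note documents the models implemented in `lysokit`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Turnover kinetics

### Model

After a switch to heavy-lysine medium, pre-existing (light) protein is only
degraded and new (heavy) protein is only synthesized. Assuming first-order
degradation at rate *k* (per day) and steady-state total abundance, the
light fraction at time *t* is e^(−kt) and the heavy-to-light ratio is
Ψ(t) = e^(kt) − 1. Two estimators invert this:

* **single-time-point**: t½ = t_s · ln2 / ln(1 + Ψ), evaluated at one
  sampling time t_s (default 96 h). Exactly consistent in the noiseless
  limit for any (t½, t_s), strictly decreasing in Ψ, and t½ = t_s when
  Ψ = 1.
* **multi-time-point**: nonlinear least squares of the observed light
  fraction L/(L+H) against e^(−kt) over ≥ 3 distinct timepoints (design
  default: 1, 2, 4, 6 days). The rate is initialized from a log-linear
  regression of −ln f on t and refined with `scipy.optimize.curve_fit`
  constrained to k > 0. R² is computed on the fraction scale (not the log
  scale); this choice is recorded because the alternative changes R² for
  noisy fast-turnover peptides.

The model applies **no amino-acid-recycling correction** (recycling of
intrinsic amino acids is minor in culture) and **no division-dilution
correction** (the design targets post-mitotic neurons). Neither code path
exists, which a test asserts.

### Normalization and aggregation choices

* The light fraction is computed per peptide per timepoint as L/(L+H),
  which is self-normalizing and removes the need for a day-0 anchor.
* Peptides with missed cleavages are excluded from ratio computation by
  default: with heavy-lysine labeling and LysC/trypsin digestion,
  multi-lysine peptides carry mixed label states. The exclusion is
  user-overridable (`exclude_missed_cleavages=False`).
* Apparent protein half-lives are the arithmetic mean of finite,
  uncensored, unique-peptide half-lives, computed **per biological
  replicate** so that downstream group tests have replicate-level
  observations.
* Censoring: Ψ = 0 (no heavy signal) is reported as an infinite half-life
  flagged `too_slow`; L = 0 with H > 0, or a half-life below t_s/20, is
  flagged `too_fast` — the single-time-point design carries no information
  that far outside its dynamic range. Censored peptides are excluded from
  protein means; a protein with no usable peptide is missing, never zero.
* Half-lives are handled in days in all reported tables.

## Differential turnover

Per-protein two-sided **Welch** t-tests on replicate half-lives in days —
Welch rather than pooled-variance because group sizes of 4–6 give no basis
for assuming equal variances. A log-scale option exists but the default is
days, matching the |Δt½|-in-days difference heatmaps. Benjamini–Hochberg
correction runs across the proteins tested **within one pairwise
comparison** (not pooled across comparisons); ties are stabilized by a
protein-id sort. No fold-change gate is applied to turnover: half-life
effects are far smaller than abundance effects, so significance is
q < α alone. Proteins with fewer than `min_replicates` (default 3) finite
values in either group are excluded and counted, and the fraction-altered
summary is reported against both denominators (tested, and tested +
excluded).

PCA/clustering of half-life profiles uses complete-case, non-constant
proteins, z-scored per protein across samples, full-SVD PCA (first two
components) and average-linkage hierarchical clustering on Euclidean
distances — deterministic given the input. The gene-set test is a
one-sided hypergeometric tail against a user-supplied background with BH
across sets; it deliberately replaces live pathway-database queries.

## Enrichment workflows

All three probe designs share one statistical core:

1. **Reference normalization**: every sample is divided by its intensity of
   an endogenously biotinylated reference protein (default PCCA, exposed as
   a parameter rather than hard-coding a fallback order of other
   carboxylases). This makes results exactly invariant to per-sample global
   scale factors; the reference missing or non-positive in any sample is an
   error naming the sample.
2. **Testing**: Welch t-tests on log2 normalized intensities (multiplicative
   MS error ⇒ log transform), BH across tested proteins. The reported
   `log2_ratio` is log2 of the ratio of group means on the normalized
   linear scale.
3. **Gates**: q < 0.05 and |log2 ratio| ≥ log2(1.5), the volcano dashed
   lines of the study design. `enriched` and `depleted` are mutually
   exclusive by construction.
4. **Filtering**: retained proteins must be enriched against the no-probe
   control and, when the design has a spatial (cytosolic) control, also
   against it; removals are categorized as nonspecific vs cytosolic. The
   filter uses the same gates as the headline volcanoes.
5. **Translocation**: a protein significantly increased in the lysosome
   probe contrast while significantly decreased in the cytosolic probe
   contrast (or vice versa) is called a translocator; same-direction
   changes are not called. Because a call requires joint significance in
   two independent contrasts, its power is lower than a single volcano's.

Missing values are never imputed; proteins failing the per-group replicate
minimum (default 3) are excluded and counted.

## pH ratiometry

Calibration fits ratio = f(pH) from nigericin-clamped buffer standards at
pH 4–8 with a linear (default), 3rd-order polynomial, or 4-parameter
logistic model; point minimums are n_params + 1 (3 / 5 / 5). The fitted
curve must be strictly monotone on a 1001-point grid over [4, 8]; a
non-monotone cubic is rejected with a pointer to the other models rather
than silently inverted. Inversion solves f(pH) = ratio by bisection
(Brent) to well below 1e−6 pH; ratios outside the curve's range are
clamped to the nearer endpoint and flagged out-of-range, and flagged
objects are excluded from well means.

The **well is the statistical unit** (5–15 culture wells per group), not
the lysosome, to avoid pseudo-replication from thousands of correlated
objects per well; per-object values remain available. Group comparisons
are Welch t-tests on per-well mean pH.

Proton concentration is reported in two conventions, both emitted and
labeled: the mean of per-object 10^(−pH)·10⁶ μM (which exceeds
10^(−mean pH) by Jensen's inequality — e.g. pH 4.31 ± 0.16 gives ≈ 52 μM
vs 49 μM), and 10^(−group-mean pH). Fold changes are likewise given both
as the ratio of per-well-averaged concentrations and as 10^(ΔpH); a
0.5-unit pH difference implies 10^0.5 ≈ 3.16, the "nearly three-fold"
effect size this assay is designed to resolve. If background columns are
supplied in the object table they are subtracted before the ratio;
otherwise raw intensities are used.

## Synthetic data generators

The generators emulate the structure of the three data families with known
ground truth; their defaults are the study conditions.

* **dSILAC** (`generate_dsilac`): 1/2/4/6-day course, log-normal half-life
  distribution with median 4 days and log-SD 0.6, plus explicit tails — 5%
  long-lived (20–40 days, echoing histones/nucleoporins) and 5% fast
  (0.3–2 days). Expected intensities are light = a·e^(−kt),
  heavy = a·(1 − e^(−kt)) per peptide, with fixed per-peptide ionization
  factors (log-SD 0.5) around a shared protein abundance, mean-one
  log-normal measurement noise at 20% CV, and optional MCAR missingness.
  Group effects multiply half-lives per protein. Optional flags mark
  missed-cleavage and shared peptides for exclusion testing.
* **Enrichment** (`generate_spatial`): 2,000 proteins, 150 planted
  lysosomal proteins at 4-fold, 4 + 4 replicates, 20% CV, per-sample global
  scale factors (log-SD 0.3) that the reference protein tracks exactly —
  so reference normalization removes them without adding noise, which is
  the reference's role in the real assay. A paired-probe knockout mode
  plants translocators that move between lysosome and cytosol probes.
* **pH** (`generate_ph`): a linear true curve (0.4·pH − 1.1), buffers at
  pH 4–8 with 1% calibration noise, and per-object pH drawn from the group
  distribution (defaults WT 4.31 ± 0.16, knockout 4.81 ± 0.24; 15 wells ×
  100 objects). The loading-control channel varies 20% between objects but
  cancels exactly in the ratio; 3% ratio noise is added on the 488 channel.
  Object pH is clipped to [4, 8] so all objects are invertible; at the
  default parameters this truncation shifts group means by < 0.002 pH.

What the generators do **not** emulate: peptide-level interference and
co-elution, intensity-dependent (left-censored) missingness beyond an
optional mode, retention-time/charge-state structure, correlated biological
replicate effects (exposed as `replicate_cv`, default 0, because the
source designs do not report inter-replicate half-life variance), or
non-normal well-to-well pH variation. Passing recovery tests on these data
therefore demonstrates correctness of the estimators and statistics under
the stated noise model, not robustness to every artifact of real MS or
imaging data.

Determinism: all randomness flows through one `numpy.random.Generator` per
generator call; identical (parameters, seed) give identical tables, and the
CLI writes tables with fixed float formatting so reruns are byte-identical.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use 500–1,000 proteins for
turnover checks (2–5 replicates, 3–5 peptides/protein), 20-seed null
batteries for calibration of the differential tests, the full 2,000-protein
enrichment design, and the full 15-well pH design. These sizes give
Monte-Carlo error comfortably below the decision margins they feed
(e.g. the null share of datasets with any BH discovery is compared at
α + 3·SE with SE ≈ 0.049 at 20 seeds).

## Known limitations

* The single-time-point estimator is biased for proteins whose turnover
  deviates from first-order kinetics (pools, maturation delays); the
  multi-time-point R² is the diagnostic for that.
* Protein half-lives are unweighted means over peptides; no
  inverse-variance weighting or outlier-peptide rejection is attempted.
* BH controls FDR per comparison; consumers combining many comparisons
  should account for selection across them.
* The hypergeometric gene-set test ignores gene-length/abundance bias and
  inter-gene correlation.
* Calibration inversion assumes one global curve per plate; per-well
  calibration drift is not modeled.
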