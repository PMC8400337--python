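# Methods note

This note documents the statistical procedures, model parametrizations,
default parameters and numerical choices implemented in `weanbiome`.

## Dietary scores (`weanbiome.diary`)

A diary covers an inclusive day span with day 0 the first day of solid
food; days inside the span without records are valid zero-intake days and
count in score denominators. Breast milk and formula records are excluded
from every score and energy total.

- **Food diversity** over a window of `d` days with `i` unique item names
  spanning `g` distinct food groups: `i·g/d`. The seven food groups are
  fruit, vegetables, grains (including beans and legumes), meat, dairy,
  confections/desserts, and oils.
- **Pre-/probiotic diversity**: with `p` unique prebiotic and `q` unique
  probiotic foods, the default reading is `((2p+q)/d)·10`, which yields a
  daily maximum of 100 for five prebiotic foods in one day. The printed
  formula is typographically ambiguous, so the alternative literal reading
  `(2p+q)/(10·d)` is available behind `ScoreConfig(literal_denominator=True)`.
- **Daily scores** are the cumulative formulas applied to a single-day
  window, making the daily/cumulative identity exact by construction.
- **Energy** uses the 4-4-9 rule with fiber at 2 kcal/g: carbohydrate
  contributes 4 kcal/g on its non-fiber part and 2 kcal/g on fiber (fiber
  clamped to total carbohydrate), fat 9 kcal/g, protein 4 kcal/g.
- Item classification (prebiotic / probiotic / food group) comes from a
  bundled lexicon (`data/default_lexicon.csv`) with case- and
  plural-insensitive matching; explicit `is_prebiotic`/`is_probiotic`
  columns in a diary CSV override the lexicon.

## Community metrics (`weanbiome.community`)

The `AsvCountTable` holds integer counts (samples × ASVs), a ranked
taxonomy, and sample metadata; a `period` column is derived as `before`
iff `study_day < 0`. Counts load from TSV (orientation auto-detected) or
from BIOM 1.0 JSON / BIOM 2.1 HDF5. The BIOM readers are deliberately
minimal, hand-rolled on `json` and `h5py`, covering dense and sparse
matrices; they are validated by round-trip tests.

- **Alpha diversity**: observed richness (ASVs with count > 0) and Shannon
  index in nats on relative abundances.
- **Bray–Curtis** on relative abundances, computed as half the L1 distance
  between proportion vectors (equivalent to `Σ|x−y|/Σ(x+y)` since
  proportions sum to one). Distances are returned as a
  `skbio.DistanceMatrix`.
- **PCoA** is classical scaling implemented directly: Gower-center the
  squared distances, eigendecompose with `numpy.linalg.eigh`, order by
  descending eigenvalue. Negative eigenvalues — expected for
  non-Euclidean dissimilarities such as Bray–Curtis — are *reported
  unchanged* (no Lingoes/Cailliez correction); axes with non-positive
  eigenvalues get zero coordinates. A library routine was not used here
  because the common implementations clamp negative eigenvalues to zero,
  hiding exactly the diagnostic this design reports. Correctness is
  checked by round-tripping Euclidean configurations (error < 1e-8).
- **UPGMA** uses `scipy.cluster.hierarchy.linkage(method="average")`;
  node heights are half the merge distance, so trees are ultrametric to
  1e-10 by construction, serialized as newick.
- **Genus summaries** collapse relative abundances by genus and pool,
  per sample, genera below the 5% threshold into `Other`; rows still sum
  to one. **Dominance** calls the genus with the highest mean relative
  abundance across an infant's samples, reported only if that mean is at
  least 0.30, otherwise `mixed`. **Shared features** counts ASVs (or
  genera) present in each cohort and in both, and the fraction of each
  cohort's abundance carried by shared features.
- **Stability series**: for each infant, Bray–Curtis change between
  consecutive samples ordered by study day; each interval's dietary
  covariates are means of daily diary values over the days strictly after
  the earlier sample up to and including the later sample's day.

## Statistics (`weanbiome.stats`)

- **Welch's t** from summary statistics with Welch–Satterthwaite degrees
  of freedom; **chi-squared** without continuity correction. Both are
  backed by scipy and verified against closed-form worked examples.
- **Sequential PERMANOVA.** The Gower-centered matrix `G = −½·J·D²·J` is
  partitioned over the model terms in caller order (Type-I): with
  cumulative hat matrices `H_i` (pseudoinverse-based, rank-safe),
  `SS_i = tr(H_i G) − tr(H_{i−1} G)`, pseudo-F uses rank-based degrees of
  freedom. The permutation test permutes rows/columns of `G`
  (optionally within strata) and reports `p = (1 + #{F* ≥ F}) / (1 + n)`.
  Tie counting uses a relative tolerance of `1e-8·max(|F|,1)` so
  permutations equivalent to the identity are not lost to floating-point
  roundoff; `exact=True` enumerates all `n!` permutations for small `n`
  and returns the exact exceedance fraction. Term order matters: for the
  merged analysis the order is cohort → participant → period, since
  participants are nested in cohorts.
- **Gaussian LMM** (alpha diversity): `statsmodels` `MixedLM` by maximum
  likelihood with a random intercept per infant; Wald p-values.
- **Gamma and negative-binomial GLMMs.** No maintained Python library
  fits non-Gaussian random-intercept GLMMs for these families, so the
  marginal likelihood is maximized directly: the per-group random
  intercept (`b ~ N(0, σ²)`) is integrated with 21-node Gauss–Hermite
  quadrature; parameters are the fixed effects, log dispersion and
  log σ, optimized by BFGS (gradient tolerance 1e-8, 500 iterations max)
  from GLM starting values; standard errors come from the numerical
  Hessian at the optimum. Families: gamma with log link
  (shape-parametrized) and NB2 (variance `μ + αμ²`). The log library-size
  offset is mean-centered internally and the intercept shifted back
  afterwards, so a global rescaling of exposures cannot perturb the
  optimizer path of the slope estimates (offset invariance holds to
  1e-6). Degenerate cases (no real group effect) are cross-checked
  against fixed-effects GLMs.
- **Stability models**: Bray–Curtis change (zeros nudged to half the
  smallest positive value, with the nudge count reported) regressed on
  each dietary variable, univariable and adjusted for total energy from
  solids. A gamma goodness-of-fit (ML fit, location 0, one-sample KS) is
  logged in the manifest.
- **Taxon regressions**: NB2 GLMMs of single-ASV counts with log total
  count offset, in three tiers — unadjusted; + energy; + energy and age
  at introduction — plus a cross-sectional candidate screen on each
  infant's last sample (plain NB regression, ranked by absolute log2
  fold change per diet unit, top 5 by default, ≥ 6 infants required).
  P-values are binned (<0.001, <0.01, <0.05, <0.1, ns) with strict
  inequalities; no multiplicity correction is applied, by design, and
  non-converged cells are reported as `missing` rather than dropped.

## Synthetic cohorts (`weanbiome.simulate`)

The generator emulates the two-cohort design at study scale: cohort A,
15 infants with the full food-group repertoire (new-item rate 1.3/day);
cohort B, 9 infants restricted to fruit/vegetables/grains (rate
0.65/day). Diaries run from 3 days before to 11 days after introduction;
each infant contributes 5–12 stool samples, evenly spaced over the span
(protocol-style sampling) so the first sample always precedes solids.
Even spacing also keeps interval length independent of interval diet;
with irregularly drawn days, long gaps concentrate around the sparse
before-introduction period where diet is lowest, and because consecutive
Bray–Curtis change grows with gap length, that correlation would look
like a diet effect even at zero diet coupling.

Microbiome composition follows a logistic-normal state-space model:

- A per-infant Dirichlet baseline places mass 0.6 on a dominance genus
  drawn per cohort (Bifidobacterium 0.78/0.70, Bacteroides 0.22/0.30).
- Log-ratio coordinates evolve as a mean-reverting (Ornstein–Uhlenbeck
  style) process around the baseline, `x_{t+1} = φ·x_t + σ_t·ε`, with
  reversion φ = 0.9 and daily step scale
  `σ_t = σ₀·exp(−γ·D_t)`, where `D_t` is the day's food diversity
  rescaled by the cohort's configured maximum, σ₀ = 1 and the diet
  coupling γ = 1.2 by default. Mean reversion (rather than a pure random
  walk) is essential for calibration: an unreverted walk concentrates
  compositions over time, creating a spurious downward trend in
  Bray–Curtis change that confounds the γ = 0 null.
- Richness grows by Poisson injection of 0.5 new low-abundance ASVs per
  day; counts are multinomial draws at a lognormal library size
  (~20,000 reads). 66% of the ASV pool is private to one cohort.
- A single global seed expands into counter-keyed per-infant substreams
  (`SeedSequence([seed, cohort, infant, stream])`), so every infant is
  independently reproducible and datasets regenerate byte-identically.
- `SyntheticTruth` records the realized dominance genus, daily diet and
  daily step scales for parameter-recovery tests.

The generator produces study-window data only by default (sparse
follow-up samples to one year are config-gated off) so that every
stability interval has diary coverage. It makes no attempt at read-level
realism (no chimeras, contamination or sequencing error models).

## Pipeline (`weanbiome.pipeline`)

`run_pipeline` executes: scores → cohort comparisons → alpha diversity +
LMMs → Bray–Curtis, PCoA, UPGMA (before/after) → merged and per-cohort
PERMANOVA (seeded from the run seed) → stability series and gamma GLMMs →
genus/dominance/shared-feature summaries → NB association matrices and
candidate screens. Every artifact is TSV/JSON/newick; `manifest.json`
records the seed, resolved configuration (minus the output path, so
identical-seed runs into different directories are byte-identical),
library versions, zero-nudge counts, gamma goodness-of-fit and
convergence warnings. Any stage failure aborts with a stage-named error
and removes partial outputs from a fresh directory. `report_summary`
regenerates a one-page markdown summary deterministically from artifacts.

## Numerical choices and limitations

- Permutation p-values can never be zero (`(1+k)/(1+n)` form); exact
  enumeration is only feasible for n ≲ 8.
- Wald inference in the GLMMs assumes the usual asymptotics; with ~24
  groups the random-intercept SD is estimated imprecisely, and the
  gamma model is an approximation to the true Bray–Curtis change
  distribution (the KS goodness-of-fit in the manifest tracks this).
- The quadrature GLMM integrates a single random intercept; nested or
  crossed random effects are out of scope.
- The dietary lexicon is a fixed list; unrecognized items are scored in
  the food-diversity numerator but carry no group or pre-/probiotic
  information, and trigger a parse warning.
- No multiple-testing correction is applied anywhere; binned p-values
  are reported so readers can apply their own.
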