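# Methods

This note documents the models and procedures implemented in `phytosize`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## The scientific question

Long-term "miniaturization" of phytoplankton can arise at two biological
scales: individual species can shrink (intraspecific size change, as
predicted by the temperature–size rule for ectotherms), or the community
can shift toward a higher share of small species (interspecific
replacement, Bergmann's rule in the broad sense). Size-fractionation
methods cannot separate the two. Given monthly microscopy-based records
of per-species cell abundance (cells/L) and mean cell biovolume
(μm³/cell) at a set of monitoring stations, the package quantifies both
processes and partitions their joint effect on community mean size
exactly.

## Size metrics

- **Community mean size** `C = Σᵢ nᵢvᵢ / Σᵢ nᵢ` for one station-month
  sample — an abundance-weighted mean cell biovolume, hence a convex
  combination of the species biovolumes present.
- **Small species**: species in the bottom quartile when all species are
  ranked ascending by their average biovolume across all samples where
  they occur (unweighted mean over presences). The set has
  `floor(S·q)` members (`q = 0.25`, floor, minimum one; ties at the cut
  broken by species id). The threshold reported is the largest member's
  average biovolume.
- **Small%**: the share of *individuals* (cells) belonging to small
  species in a sample. A richness-based variant (share of *species*
  present that are small) is available behind a flag; the
  abundance-weighted form is the default because composition change is an
  abundance phenomenon. Reports name the variant used.
- **ESD** `= (6v/π)^(1/3)` converts biovolume to equivalent spherical
  diameter (μm).
- Months where a species is absent are missing data, not zeros: a zero
  biovolume is biologically meaningless. Region-scale species series
  average station values without abundance weighting, so bloom stations
  do not dominate.

## Trend estimation

All trends are ordinary least squares of a monthly series against the
*lagged month* (whole months since the first sampling occasion), with a
two-sided t-test on the slope (n−2 df) and slopes reported per month and
per year (×12). Conventions for degenerate inputs: a constant series
gets slope 0 with p = 1 (avoids NaN propagation in screening loops); an
exact non-constant fit gets p = 0 with an `exact_fit` flag.

Families of related tests (e.g. the top-species screen) are corrected
with the Benjamini–Hochberg step-up, applied within one analysis family
rather than globally. The implementation is the literal step-up formula
`q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j` (capped at 1) and is cross-checked in the
tests against both the textbook rejection set (exhaustively for m ≤ 10)
and statsmodels.

Seasonality is removed with an STL decomposition (LOESS-based, period
12, seasonal smoother window 13) via statsmodels. Interior gaps in the
monthly grid are linearly interpolated before decomposition and flagged
afterwards; the de-seasoned trend is the OLS fit to trend + residual at
the originally observed months (fitting the smoothed trend component
alone is available via `on="trend"`). The decomposition reconstructs
the input exactly by construction, which the tests assert. Direct and
de-seasoned trends are always reported side by side. No
autocorrelation-corrected (GLS/Newey–West) inference is attempted; the
de-seasoning cross-check is the guard against spurious seasonal trends.

## Exact partition of community size change

Between two time windows, with `p̄ᵢ(w)` the species' share of total cells
summed over window `w` (not the mean of monthly shares — consistent with
`C` as a cell-weighted mean) and `v̄ᵢ(w)` its cell-weighted mean
biovolume:

```
ΔC        = C(1) − C(0),  C(w) = Σᵢ p̄ᵢ(w) v̄ᵢ(w)
within    = Σᵢ (p̄ᵢ(0)+p̄ᵢ(1))/2 · (v̄ᵢ(1)−v̄ᵢ(0))   (size-shift term)
composition = Σᵢ (v̄ᵢ(0)+v̄ᵢ(1))/2 · (p̄ᵢ(1)−p̄ᵢ(0)) (species-shift term)
```

Mid-point (Bennet) weights make the identity `within + composition = ΔC`
exact, with no cross term, so "which process dominates" is a testable
quantity rather than a narrative. Species present in only one window
enter through `p̄ = 0` in the other window and carry their observed
window's `v̄` (their within term vanishes; they contribute only through
composition). Windows default to the first and last 36 months — three
full annual cycles each, balancing seasonal coverage against trend
contrast.

Scenario classification maps trend classes onto two qualitative
outcomes: scenario i (community miniaturization: species sizes declining
while Small% increases or is stable) and scenario ii (offset/uncertain:
species sizes and Small% both declining, so composition change can
cancel species miniaturization at the community level). The species
summary is the majority class over the tested species.

## Community turnover

Bray–Curtis dissimilarity and ANOSIM are implemented from first
principles. Abundances are untransformed by default (transforms
available by flag). ANOSIM uses Clarke's rank form with mid-ranks for
ties; `R = (r̄_between − r̄_within)/(M/2)`, `M = n(n−1)/2`; the one-sided
permutation p is `(#{R_perm ≥ R_obs}+1)/(n_perm+1)` with 999 seeded
permutations by default (the count is a reproducibility choice, not an
inferential one). An exact enumeration mode over all distinct label
arrangements exists for small n and anchors the permutation p in tests.
Note that the attainable minimum p exceeds `1/(n_perm+1)` whenever
several relabelings are equivalent to the observed grouping. Year,
month, station and zone groupings are tested on the same pooled
sample×species matrix, one factor at a time. A constant dissimilarity
matrix has no rank structure and R is reported missing. For large
sample sets the O(n²) matrix is bounded by seeded subsampling.

## Driver attribution

- **Correlation screen**: Pearson r between each top species' monthly
  biovolume (station-month values) and each environmental factor, with
  support counts; cells with < 3 pairs or zero variance are missing.
- **Response groups**: agglomerative clustering (Euclidean distance on
  correlation rows, average linkage, cut at k = 4). Clusters are
  labelled by the sign of their mean temperature correlation, with a
  nutrient suffix when the mean nutrient-block correlation magnitude
  exceeds 0.1 (a config value — the labels summarize a heatmap, not a
  test). Missing entries are imputed to 0 and flagged.
- **Partial effects**: least squares of the response on the focal factor
  plus all covariates plus one fixed intercept per group (station).
  Grouped fixed intercepts stand in for random intercepts deliberately:
  with hundreds of observations per station the shrinkage of a REML
  mixed model is immaterial, and the fixed-effects fit is exactly
  reproducible and oracle-checkable against the normal equations. The
  temperature–size rule test declares "follows TSR" when the temperature
  coefficient on log biovolume is significantly negative with all other
  measured factors held constant. Rank-deficient designs raise an error
  naming the collinear columns. Per-station effects are the same
  operation scoped to one station without group intercepts.
- **Learner tournament**: five adapters mirroring the usual model
  families — penalized linear (ridge), bagged trees (random forest),
  boosted trees (XGBoost), a small feed-forward network, and a kernel
  regressor (RBF SVR) — behind a minimal fit/predict contract, scored by
  held-out R² on a single seeded 20% split, winner by maximal R² with
  ties broken by registration order. Learner internals are deliberately
  not part of this package's contribution; no hyperparameter search.
- **Shapley attribution** is implemented from first principles. Absent
  features are handled interventionally: `v(S)` is the mean prediction
  over a finite background set with the features in S taken from the
  explained sample. Exact mode enumerates all coalitions (feasible to
  p = 12) and satisfies the efficiency, dummy and symmetry axioms to
  machine precision; Monte-Carlo mode averages marginal contributions
  over random feature permutations (coalition values are cached, so the
  Monte-Carlo error is purely in the permutation weights). The default
  background is 100 rows subsampled with a fixed seed — bounded cost,
  reproducible. Pairwise interactions use the Shapley interaction index
  (second differences over coalitions excluding the pair), which is
  symmetric and vanishes for additively separable predictors. Global
  importance is mean |φ| per feature, descending, ties by name.

Two estimator-design choices matter for attribution on monthly series:

1. **Responses are seasonally adjusted before the learner fit** (STL
   trend + residual per station). The question the analysis asks is
   which factor drives the *annual-scale* variation; on raw monthly data
   any clean co-cyclic factor (salinity, temperature) can soak up purely
   seasonal response variance and distort the ranking.
2. **Models are fit on the full joined table**, not a subsample. With
   collinear seasonal regressors, tree ensembles resolve credit through
   the trend component only when the sample is large enough for the
   trend signal to dominate split selection; subsampled fits produced
   unstable rankings between temperature and salinity.

## The synthetic community generator

The generator emulates the statistical structure of a multi-decadal
subtropical coastal monitoring programme, with every injected effect
recoverable in closed form. On log scales:

- temperature `T(s,t) = T0ₛ + wₛ·t/12 + Aₛ·cos(2π(t−φₛ)/12) + ε`
- phosphate `PO4(s,t) = max(floor, (P0ₛ + mₛ·t/12)·e^ε)`
- cell size `ln v(i,s,t) = ln v0ᵢ + γᵢt + βᵢ(T(s,t) − Tref) + ε`
- abundance `ln n(i,s,t) = ln wᵢ + aᵢcos(2π(t−ψᵢ)/12)
  + 1[i small]·(δt + κ(PO4 − P0ₛ)) + ε`, plus a multiplicative bloom
  spike on one abundance-weighted species in a random small fraction of
  station-months; species below 1 cell/L are absent from the table.

Size responses act multiplicatively (on log biovolume) because
biovolumes span orders of magnitude and reported temperature–size
sensitivities (~2.5%/°C) are proportional. Defaults (the package's
standard study conditions): 5 stations × 240 months × 50 species
(27 diatoms / 18 dinoflagellates / 5 other, the 169-species pool's group
proportions at desk scale); baseline temperature 23 ± 0.5 °C with 5 °C
seasonal amplitude peaking in month 6 and warming 0.03 ± 0.01 °C/yr;
phosphate ~30 μg/L declining 0.5 ± 0.15 μg/L/yr, floored at 0.5 μg/L;
baseline biovolumes lognormal with log₁₀ v0 ~ N(3.5, 1) μm³ (spanning
roughly 10¹–10⁶); temperature–size coefficients β ~ N(−0.02, 0.02) /°C
on log size (centred on the literature's ~2%/°C decline, with a positive
tail because exceptions are real); intrinsic trends
γ ~ N(−3·10⁻⁴, 3·10⁻⁴) per month; composition drift δ = −0.002 log-odds
per month *away* from small species (positive δ favours them, so the
Small% trend sign equals sign(δ)); phosphate–Small% coupling κ = 0.02
log-odds per μg/L of PO4 anomaly, making phosphate a genuine positive
driver of Small%; lognormal noise SDs 0.3 (log size), 1.0 (log
abundance), 0.5 °C (temperature), 0.2 (log nutrients); bloom probability
0.01 per station-month with e³ ≈ 20× median magnitude. Bloom frequency
statistics are not constrained by monitoring literature available to us;
those defaults are placeholders and only add heavy-tailed nuisance
variance. One seed sequence drives the run, with sub-streams per
station, so partial regeneration is reproducible.

`truth_summary` returns the injected per-species log-size slope
`γᵢ + βᵢ·wₛ/12` per month (chain rule through the station's warming
rate), the per-station small-species drift rate `δ + κ·mₛ/12`, and the
partition components of a noise-free regeneration (measurement noise and
blooms off, heterogeneity kept) between the analysis windows.

Two derived scenarios are fixed by their purpose:

- **TSR null scenario** (calibration): β = γ = δ = κ = 0, blooms off,
  2 stations × 48 months × 6 species. γ must be zero in the null
  because an intrinsic time trend is collinear with the warming trend in
  temperature and would register as a temperature effect for reasons
  unrelated to test calibration.
- **Offset scenario**: universal miniaturization (β ~ N(−0.02, 0.005),
  γ ~ N(−8·10⁻⁴, 10⁻⁴)) with drift toward large species (δ = −0.002).
  Every species shrinks, yet the community mean need not decline — the
  configuration the two-scenario framework labels "ii".

What the generator does *not* emulate: picoplankton (the observation
process is microscopy-scale by construction), mechanistic nutrient
uptake or hydrodynamics, species interactions, observation gaps and
detection-limit censoring patterns of real monitoring data, and
spatial correlation between stations beyond shared parameter
distributions. Passing recovery tests therefore demonstrates that the
estimators invert the generator's statistical structure at realistic
noise levels — not that real coastal data satisfy that structure.

## Validation suites and problem sizes

The `validation` module (shared by the test suite and
`scripts/acceptance.py`) runs four families, sized for a single CPU:

1. **Exactness** — partition identity and brute-force recomputation on
   1000 random two-window instances (< 10⁻⁹ relative); Shapley
   efficiency/dummy/symmetry axioms in exact mode (< 10⁻⁸); STL
   reconstruction identity; BH equivalence with the textbook rejection
   set, exhaustive for m ≤ 10.
2. **Oracles** — OLS trends and partial effects vs. normal equations
   (< 10⁻⁸); ANOSIM permutation p vs. full enumeration on ≤ 6-sample
   cases; Monte-Carlo Shapley within 2% relative RMS of exact
   enumeration at p = 5 with 4096 permutations.
3. **Parameter recovery** — 20 realizations of the standard scenario:
   median estimated species log-size slope within 15% of the injected
   median; Small% trend sign matching sign(δ) in ≥ 95% of station
   series; TSR type-I error 0.05 ± 0.03 at β = 0 over 200 null
   realizations; temperature ranked top driver of size and PO4 top-2
   for Small% in ≥ 90% of realizations.
4. **Offset scenario** — community trend non-significant at most
   stations and the region classified as scenario ii.

## Data handling conventions

Dates carry year and month only (sampling is monthly). Below-detection
values (`"<x"`) default to half the detection limit, flagged and
configurable, because monitoring agencies differ and the convention must
be auditable. Duplicate (station, month, species) rows keep the first
occurrence with a warning. N/P is computed on a molar basis
(DIN in mg N/L, phosphate in μg P/L → μmol ratio) so it is comparable to
the Redfield value of 16; a zero phosphate yields a missing ratio, never
infinity. Whether an agency's "PO4" is μg P/L or μg PO₄/L is a unit
switch the user must set (default μg P/L). All outputs are tidy CSV
with stable column order; re-running a pipeline configuration reproduces
the bundle byte-for-byte.

## Known limitations

- Trend inference ignores residual autocorrelation beyond seasonality.
- The quartile ranking that defines small species pools all years;
  a per-window re-ranking is not implemented.
- The Shapley background treats features as independent
  (interventional); strongly correlated factors share credit in ways no
  attribution method can fully resolve.
- The tournament's single split estimates, rather than
  cross-validates, held-out skill; it selects among learners, it does
  not certify absolute performance.
- Scenario classification uses majority classes; it does not propagate
  classification uncertainty.
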