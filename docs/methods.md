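# Methods

## Trend engine

Abundance series are analysed on the log10 scale. Zeros cannot be
log-transformed, so each zero is replaced by 1% of the arithmetic mean of
the series' non-zero abundances, computed from that population's own series
only. Annual rates are λ_t = log10(n_t / n_{t-1}); the per-population trend
λ̄ is their arithmetic mean. A series with T consecutive values yields T−1
annual rates; λ̄ averages over those T−1 transitions (the alternative, a
1/T denominator, makes a constant series' trend depend on its length and
breaks the telescoping identity Σλ_t = log10(n_last/n_first)). λ statistics
are exactly invariant to rescaling a series by a positive constant.

Interior gaps are imputed from a model of log10 abundance on year fitted to
the real observations: an ordinary linear regression when there are fewer
than six of them, otherwise a Gaussian GAM with a penalized regression
spline of year. The spline basis dimension is half the series span in
years, rounded up, floored at 4 (a cubic B-spline needs that many columns)
and capped at n_real − 1 for identifiability. The smoothing penalty is
chosen by generalized cross-validation over a fixed log-spaced grid
(10⁻⁴…10⁴), which is deterministic given the data. Real records are never
altered and no values are produced outside the first-to-last-record range.
Fit quality is the proportion of deviance explained (GAM) or R² (linear);
the quality filter applies only to series that actually required
imputation — complete series pass automatically. A series enters the model
frame if it has ≥ 5 consecutive values inside the analysis window
(default 1992–2018; both endpoints configurable).

A note on capacity: a spline basis of dimension span/2 cannot represent
arbitrarily sharp features. On noise-free unimodal test curves the
imputation recovers withheld values within 5% provided the feature width
is resolvable by that basis (roughly ≥ 3 years at a 12-year span); sharper
bumps are a capacity limit, not a tuning failure, and the test fixtures
draw widths of 3.5–6 years accordingly.

## Environmental change

Temperature: monthly values are averaged to arithmetic annual means (years
missing more than two months are flagged), and the warming rate ΔT is the
OLS slope of annual mean temperature on year restricted to the population's
monitoring window — a regression because inter-annual fluctuations are
strong. Land cover: each class's rate is the arithmetic mean of successive
annual differences of its cover fraction, which telescopes to
(last − first)/(years − 1); no regression, because cover change is
directional. Rates are expressed as fraction-of-area per year (not
percentage points); coefficient magnitudes in the model depend on this
convention, so it is fixed here.

Cover fractions come from categorical rasters via a crosswalk: each pixel
code maps to fractional contributions over 14 simplified classes, the four
tree and four shrub classes are grouped into forest and shrubs (8 final
classes), and fractions are averaged over the pixels whose centers lie
within a 1-km great-circle radius of the population's location (haversine
distance; pixel-center membership is simple and reproducible at ~300-m
resolution). Rasters are read from ESRI ASCII grid text files, or the
pipeline accepts pre-extracted site × year × class fraction tables. The
packaged default crosswalk is a simplified mapping in the spirit of the
published 36-code schemes (single-class codes map 1:1, mosaic codes split
70/30 or 50/50); users supply their own CSV for production use.

Because fractions sum to 1 every year, the per-class rates sum to exactly
zero for every population. This closure makes each cover block of the full
model design rank-deficient by one column. The fitter detects linear
dependencies greedily from left to right in term order and drops the
aliased columns from estimation (reported on the fit, as lme4 does);
in the default term ordering the last cover class (water) is the aliased
one, which pins the compositional identification by treating it as the
reference class.

## Life history

Trait records are keyed to accepted binomials through a local synonym
table (an offline stand-in for live taxonomic services; unmatched names
are reported, never silently dropped). Multiple estimates of a trait for
one species combine by geometric mean (log, average, back-transform).
Natural logarithms are used for all trait transforms; the base cancels in
the downstream residual PCA.

Missing trait values are imputed missForest-style: gaps start at column
medians (log scale); each incomplete trait, in order of increasing
missingness, is refit as a scikit-learn random forest (100 trees) on the
other traits, the first 10 phylogenetic eigenvectors, and one-hot
class/order/family factors; iteration stops when the relative change of
the imputed matrix increases, returning the previous iterate. Observed
values are never altered; a seed fixes the forests. The phylogenetic
eigenvectors are the leading principal coordinates of the patristic
distance matrix (dendropy distances, scikit-bio PCoA, no negative-
eigenvalue correction — only the leading axes are consumed); species
absent from the tree get neutral (zero) eigenvector inputs and rely on the
taxonomy factors.

Mass adjustment fits log(trait) ~ log(body mass) per trait with nested
random intercepts (family within order within class); the conditional
residuals — predicted random intercepts subtracted — are the mass- and
kinship-adjusted traits. If a grouping level makes the fit singular the
model degrades gracefully (drop family, then order, then plain OLS), with
the degradation logged. The PCA runs on the correlation matrix (residual
traits are standardized; they are on incommensurate scales after
residualization) of the four adjusted traits; body mass itself is not a
PCA input, having been regressed out. PC1's sign is fixed so that
offspring (fallback: reproductive events) loads positively — fast species
score high; later axes get a deterministic largest-loading-positive
orientation.

## Trend model

The full fixed structure with N cover classes has N+2 main effects, 2N+1
two-way and N three-way interactions (no cover × cover terms): 35 terms at
N=8. The model uses crossed (not nested) random intercepts for location
and species — multiple species share locations and vice versa — fitted via
variance components on a single grouping envelope (statsmodels MixedLM).
Covariates are not standardized by default, so coefficient magnitudes are
on the raw covariate scales.

AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1), where k counts the estimable
fixed effects plus the variance components including the residual.
Backward selection uses ML fits (REML likelihoods of models differing in
fixed effects are not comparable); at each step the droppable term — one
that is not a parent of a retained interaction — whose removal most
decreases AICc is removed, ties breaking deterministically toward the term
later in spec order; aliased droppable terms are cleaned up at no
likelihood cost; the final structure is refit with REML. Fixed effects are
tested with type-III Wald χ² (b'C⁻¹b on the term's coefficients; the
squared z for single columns) against the large-sample χ² reference.
Pseudo-R² follows the variance-decomposition form: marginal =
var(Xβ)/(var(Xβ) + σ²_location + σ²_species + σ²_residual); conditional
adds the random-intercept variances to the numerator.

A property worth knowing when interpreting selection outcomes: backward
AICc retains any term whose |t| exceeds ≈1.4 at the moment of evaluation,
so on pure-noise responses roughly one in seven candidate terms survives
by chance, and marginality then locks in that term's parents. Selection on
noise therefore typically returns a handful of spurious terms rather than
the intercept-only model; the test suite documents this behaviour
honestly. The planted-signal direction — a strong generating interaction
is retained — is reliable.

## Sensitivity protocols

The R²-threshold scan refilters the imputed populations at 0.3/0.5/0.7/0.9
(raising the threshold can only shrink the retained set), rebuilds the
frame, and refits the baseline-selected model per scenario. The trimming
protocol removes populations below the 2.5th percentile of λ̄, above the
97.5th, or both — quantiles empirical with linear interpolation, computed
on the input frame — and refits. Scenarios refit the *selected* model by
default so term-by-term comparison is well defined; a flag enables full
reselection. Reports flag per-term sign flips and significance changes
(α = 0.05) against the baseline. Trimming is assumed to apply after the R²
filter, on the analysis frame.

## Synthetic data

The generator is the analysis run backwards, with every draw recorded.
Traits: log body mass ~ N(5, 2) (grams, natural log); each log trait is
allometric in log mass plus loading × latent fast–slow value plus Gaussian
noise (default sd 0.1), with longevity/maturity loadings (−0.5) opposing
reproductive-events/offspring loadings (+0.5), scaled by a trade-off
strength knob; the phylogeny is a pure-birth ultrametric tree (only
pairwise distances are consumed downstream). Environment: monthly
temperature = site base + true linear trend (default N(0.02, 0.02²)
degC/yr) + seasonal cosine + noise (sd 0.5 degC); cover = Dirichlet
baseline with a linear transfer between the two largest classes (rate
bounded to keep fractions in [0,1]; true per-class rates sum to zero),
renormalized each year. Populations: each gets a species and site; its
expected trend is the model's linear predictor at the true covariates plus
species and site intercepts (defaults sd 0.01 each); abundance follows
n_t = n_{t-1}·10^(λ+ε) with ε on the log10 scale (sd 0.02); series lengths
are 6–27 years inside 1992–2018. Missingness is MCAR on interior years
(default 15%; first and last records are kept so the span is known), and
zeros (default 3%) are injected only into observed slots. The default
generating coefficients mirror the final-model structure of the study
system (cropland and bare-soil effects and their interactions with the
fast–slow score; a near-zero warming main effect).

What the generator does not emulate: spatial autocorrelation of climate
and land-cover fields, observation-error structure of real monitoring,
non-MCAR missingness, phylogenetic signal in the latent axis, and density
dependence. Passing recovery tests therefore demonstrates the estimators'
correctness under the stated generative model, not robustness to these
real-data features.

## Problem sizes and tolerances

Calibration experiments run at desk scale by design: fixed-effect
bias/coverage uses 40–60 replicates of n = 400 populations (bias
thresholds 10%, pooled CI coverage bounds [0.90, 0.99]); Wald type-I error
pools 300–450 p-values from null fits at n = 300 (accepted band
[0.02, 0.08]); stepwise experiments use two cover classes at n = 250. The
recovery experiment's generating coefficients are sized so each effect is
identifiable at these n (|β| ≳ 5 per-fit SEs); λ-engine checks are exact
to ≤ 2 ulp; closure and telescoping identities to 1e-9 and 1e-12.

## Known limitations

Wald χ² p-values use the large-sample reference, slightly liberal for
site-level covariates when sites are few; no spatial or phylogenetic
residual correlation; the GAM penalty grid trades a small amount of
optimality for determinism; GeoTIFF rasters are not read directly (convert
to ESRI ASCII or pre-extract fractions); the packaged crosswalk is a
simplified default, not the published table.
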