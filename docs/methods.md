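# Methods

`hydrisk` implements a pipeline for mapping hydraulic risk of woody-plant
assemblages and relating it to drought-induced mortality (DIM) occurrence:
sparse species-level hydraulic traits are completed from phylogenetic and
edaphoclimatic features with an iterative random-forest imputer, projected
onto a grid through species ranges, aggregated into per-pixel risk metrics,
and related to mortality with background-resampled GLMs and a hinge-feature
maximum-entropy model. A synthetic-world generator provides data with the
same statistical structure and known ground truth, so every stage is
testable end to end.

## The traits and the safety margin

P_min is the minimum xylem water potential recorded for a species; P50 and
P88 are the potentials at 50% and 88% loss of hydraulic conductivity (all
MPa, negative). The hydraulic safety margin is HSM = P_min − P50; the 50/88
variant uses P50 for gymnosperms and P88 for angiosperms. HSM < 0 means a
species' drought exposure exceeds its embolism resistance.

## Synthetic worlds

The generator draws, from one seed:

- **Phylogeny.** A pure-birth (Yule) genus backbone conditioned on the genus
  count, rescaled so all leaves sit at `tree_depth` (default 100 time
  units). Species attach below their genus as a polytomy at 10% of tree
  depth — the tree is genus-level with shallow species structure, as
  phylogenies assembled from genus backbones are. The two subtrees at the
  root define the angiosperm/gymnosperm split.
- **Environment.** Gaussian random fields: white noise smoothed with a
  Gaussian kernel (scale `env_corr_length`, wrapped boundaries; lag-h
  autocorrelation exp(−h²/4s²)), standardized per layer. Categorical biome
  and plant-functional-type layers come from quantile-binned fields.
- **Niches and ranges.** Each species' niche optimum on environmental layer
  1 mixes a Brownian tree component (weight `niche_signal` = 0.5) with an
  independent deviate; the range is every cell whose layer-1 value lies
  within `niche_breadth` (1 env sd) of the optimum. Empty ranges are widened
  to the nearest cell and flagged.
- **Traits.** P_min and P50 each sum a root state, a Brownian component, a
  linear effect of the species' range-mean environment, and Gaussian noise.
  The Brownian parts share a latent component whose weight equals the
  target trait correlation (0.8). P88 is P50 minus a positive offset
  (mean 1.5 MPa). Negativity of P50/P88 is enforced, if a draw ever
  violates it, by a recorded location shift rather than truncation.
- **Observation.** Each trait cell is retained independently with
  probability `observed_fraction`; taxonomy and clade are never masked.
- **Mortality.** Per woody pixel (richness ≥ 1) an event is Bernoulli with
  logit = intercept + Σ coef × metric over assemblage metrics computed from
  ground-truth HSM. Events are attributed to 1–3 occupying species sampled
  with weight exp(−HSM/τ), τ = 3 MPa (the attribution affects only species
  labels, never pixel events). τ is deliberately large relative to the HSM
  spread (~1.1 MPa): a small τ makes event species labels a near-
  deterministic readout of HSM, whereas species identity of observed
  mortality should be only weakly informative — species-level models are
  then weak predictors while assemblage metrics remain strong, the regime
  the pipeline is designed to detect.

### Default parameters (the simulated study conditions)

100 genera with a shifted negative-binomial species count (mean 5) give
≈500 species on a 40×40 grid with 6 environmental layers. Brownian rates
are 0.02 MPa²/time for both traits (tip sd ≈ 1.4 MPa), the environmental
effect is (2.0, 0.6, 0, …) MPa per env-unit, residual noise 0.25 MPa, root
states −6.5 / −7.5 MPa and observed fraction 0.2. These values were chosen
so that the capturable share of trait variance puts repeated
cross-validation R² in the 0.5–0.8 range at 20% observation, the HSM < 0
share sits around 5–30% across seeds, and both signals (phylogenetic and
environmental) contribute materially — the regime in which predictor-set
comparison is meaningful. The default mortality coefficients
(intercept −4.7, +0.025 per species with HSM < 0, −0.9 per MPa of minimum
HSM) put the event rate near 3–22% of woody pixels across seeds.

Because the trait environmental effect is identical for P_min and P50, it
cancels in HSM: spatial HSM variation is purely phylogenetic-compositional
plus noise, while trait maps themselves remain strongly environmental.

### Separately-sourced climate proxies

Real occurrence models use climate layers (maximum temperature, aridity,
soil texture) that are correlated with — but distinct from — the variables
behind the trait predictions. `proxy_climate_layers` emulates this: each
proxy is corr × the standardized composition-driving layer plus an
independent smooth field (default corr 0.75). The maxent model suite uses
these proxies as its continuous "edaphoclimatic" predictors; handing the
suite the exact composition-driving layer instead would make assemblage
metrics exactly recoverable from climate (ranges are deterministic in that
layer) and erase the contrast the suite is designed to measure.

### What the generator does not emulate

Abundances, dispersal limitation, temporal drought dynamics, intraspecific
trait variation, observation bias correlated with climate, and realistic
biogeography. Passing tests therefore show the pipeline recovers the
structure it assumes, not that the assumptions hold for any real flora.

## Phylogenetic and environmental features

Cophenetic (patristic) distances between genera are double-centered and
eigendecomposed (classical PCoA). Negative-eigenvalue axes are dropped
without correction — ultrametric-tree distances are Euclidean-embeddable so
nothing is lost; each axis's first nonzero loading is made positive for
reproducibility. Species inherit their genus coordinates verbatim. The
dense eigendecomposition is O(n³); fine to a few thousand taxa.

Species × layer range means are transformed toward normality (natural log
when |skew| > 1 and the minimum is positive, square root when the minimum
is zero, identity otherwise; threshold configurable) and compressed by PCA.
The PCA standardizes variables (correlation form) because real layers mix
°C, mm and kPa; a `scale=False` covariance option exists. The first five
components and five phylogenetic axes are the default predictor set.

## Imputation

The imputer is the classic iterative random-forest scheme: initialize
missing numerics at the column mean (categoricals at the mode), then sweep
columns in order of increasing missingness, refitting a 100-tree random
forest (⌊√p⌋ candidate variables per split) of the observed rows on all
other columns and re-predicting the missing rows, until the change
statistic — Σ(new−old)²/Σnew² for numerics, mismatch fraction for
categoricals — first fails to decrease; the previous iterate is returned.
Per-column RF seeds are constant across sweeps so that a sweep with
unchanged inputs is idempotent and the loop can converge exactly. Observed
values are never altered. Both traits are imputed jointly in one table with
clade as a categorical predictor, so trait covariation is used.

Cross-validation hides a fraction of *observed* values, imputes, and scores
R² as the squared Pearson correlation between held-out truth and
imputations (a 1−SSE/SST option exists). The fraction grid 0.1–0.7 is
supported; fraction 0.1 repeated plays the role of tenfold CV. Hold-out
masks depend on (seed, fraction, repetition) but not on the predictor set,
so competing specs are scored on identical cells — a paired comparison.
Ensembles run the imputer n times with sub-seeds seed+i; imputed cells get
the ensemble mean and sd (sd flagged degenerate at n=1). A second
uncertainty tier masks 20% of observed species per repetition and records
the per-species sd of predictions, measuring sensitivity to training-set
identity.

## Assemblage metrics

Ranges rasterize by the cell-center rule (a cell belongs to a polygon that
contains its center; explicit cell lists pass through). Per-pixel
statistics over occupying species: mean, minimum, sample variance (n−1;
missing below two valued species), the count of species with values
strictly below a threshold (HSM < 0), and richness. Species with missing
trait values are excluded per metric, not per pixel. Risk layers are
exported as −HSM so higher means riskier; quantile clamping (5%/95%,
linear-interpolation quantiles) exists for display only.

## Mortality models

Events are thinned to one per grid cell of a stated size (grid anchored at
the data bounding box; first record in file order wins — the retained count
is tie-break invariant). Species-level models balance all species with
recorded mortality against an equal random sample without, fitting binomial
(occurrence) and Poisson (event count) GLMs, repeated and averaged.
Assemblage-level models contrast presence pixels with equal-sized random
background draws from defined-metric, no-mortality pixels, fitting binomial
GLMs of a formula in the metric layers, factors and covariates; term
significance uses sequential likelihood-ratio tests; within-level trends of
a metric × factor interaction come from delta-method contrasts. Evaluation
reports Nagelkerke pseudo-R² (McFadden behind a flag) and repeated 80/20
hold-out AUC (rank statistic with tie correction). Residual spatial
structure is checked by a Mantel permutation test between |residual
difference| and Euclidean distance matrices, p = (1+#{r* ≥ r})/(n_perm+1).

Two calibration caveats. First, averaging p-values across background
resamples is not itself a calibrated test — the per-draw test is; the null
calibration checks run one draw per replicate. Second, the balanced
zero-augmented count design is over-dispersed by construction, so Wald
tests from the species-level Poisson model are anti-conservative; its
coefficients are descriptive, and occurrence-model inference should come
from the binomial fits.

## Maximum entropy

The occurrence model is the Gibbs distribution q_λ(x) ∝ exp(λ·f(x))
normalized over the background sample, with forward hinges
max(0, x−k)/(max−k) and reverse hinges max(0, k−x)/(k−min) on an
equally-spaced knot grid per continuous variable (default 50 knots,
fewer at desk scale) and one-hot factor levels — all features in [0, 1].
The fit maximizes mean presence log-likelihood minus Σβ_j|λ_j| with
β_j = reg_multiplier × 0.5 × s_j/√m (s_j the presence sd of feature j,
floored at 0.05 so features constant over presences cannot escape
regularization; m the presence count). The solver is FISTA with
backtracking, soft-thresholding and adaptive restart; convergence is
certified by the L1 subgradient (KKT) condition at tolerance 1e−6 (looser
in bulk runs). Training gain is the penalized mean presence log-probability
plus log(background size), zero for the uniform model. Outputs: raw
(normalized over the training background) and the cloglog transform
1 − exp(−e^H · raw) with H the background entropy of q — strictly
increasing in raw, hence AUC-equivalent.

Variable screening orders candidates by single-variable training gain and
keeps a variable iff |Pearson r| < 0.75 with everything already kept.
Jackknife contribution normalizes single-variable gains (negatives floored
at 0) to percentages; permutation importance is the normalized drop in
training AUC when one variable is shuffled across pooled presence and
background rows with coefficients fixed. Evaluation splits presences and
backgrounds separately at 80/20, repeated. The model suite fits type a
(factors only), type b (factors + continuous climate) and type c (type b
with its two lowest-contribution continuous variables replaced by the
number of species with HSM < 0 and HSM variance), keeping b and c at equal
predictor counts; backgrounds exclude exact presence pixels. Within the
suite, every repetition draws one stratified split shared by all three
model types, so split noise cancels from the between-type AUC comparison
(a paired design); the standalone evaluator keeps independent splits.

## Numerical choices and degenerate inputs

PCoA/PCA eigenvalues below 1e−10 of the spectrum maximum count as zero.
GLMs converge at relative deviance change 1e−8; aliased design columns are
dropped (reported) and complete separation is flagged, not rejected.
Constant residuals make Mantel r undefined (NaN, warned). Constant
variables are excluded from hinge features (warned). Variance layers clip
tiny negative rounding to 0. The species-level Poisson AUC is computed on
the any-event indicator. Test-scale runs use smaller knot counts (6–15),
looser solver tolerances (1e−3–1e−4) and fewer repetitions than the
defaults; problem sizes per check are in the test suite.

## Known limitations

The imputer refits forests per column per sweep — O(columns × iterations)
forest fits; fine to ~10⁴ species, not 10⁶. Hinge-only features cannot
express interactions between continuous variables (the real tool's product
features are out of scope). The Mantel test permutes labels, assuming
exchangeability under the null. The acceptance-scale AUC margins between
model types are a few hundredths — real-data margins depend on how much
the available climate proxies miss about composition.
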