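# Methods

`airhealth` implements a two-stage Bayesian hierarchical analysis of the
long-term association between ambient air pollution and areal disease
counts, for the common situation where (i) pollution is measured accurately
but sparsely by a monitoring network, (ii) a deterministic dispersion model
supplies complete but biased gridded concentrations, (iii) disease counts
are available only as areal totals, and (iv) two pollutants of interest
(e.g. NO2 and PM10) are strongly correlated.

## Stage 1 — multivariate spatio-temporal fusion model

Monitoring observations are annual means at m sites for q pollutants over T
years, modelled on the natural-log scale (concentrations are positive and
right-skewed).  Writing X_j^(t) for the m-vector of log observations of
pollutant j in year t and Z_j^(t) for its design matrix (intercept,
site-type indicators with urban background as reference, log dispersion-model
concentration at the nearest grid point, annual temperature):

    (X_1^(t), ..., X_q^(t))  ~  N( blockdiag(Z_j^(t)) (beta_1^(t),...,beta_q^(t)),
                                   sigma_t^2 C ⊗ I_m )
    beta_j^(t) | beta_j^(t-1) ~ N( beta_j + kappa (beta_j^(t-1) - beta_j), tau^2 I )
    ln sigma_t^2 | sigma_{t-1}^2 ~ N( ln sigma_{t-1}^2, delta^2 ),  flat on ln sigma_1^2

C is the q x q between-pollutant covariance at a site; the Kronecker
structure with I_m asserts spatial independence of residuals after covariate
adjustment.  That assertion is testable: `residual_semivariogram` bins the
empirical semivariogram of residuals and wraps it in a Monte-Carlo envelope
obtained by permuting residuals over locations (the exact independence
null).  Because the dispersion-model covariate is spatially smooth, it
typically removes the spatial signal, which is why no kriging-type residual
model is offered: for sparse networks with large unmonitored regions a
geostatistical model extrapolates poorly, while the dispersion model
carries the spatial information instead.

Priors: long-run coefficients beta_j ~ N(0, 1000 I); kappa ~ U[0,1];
tau^2, delta^2 ~ inverse-gamma(0.001, 0.001); C ~ inverse-Wishart(df=q,
scale=100 I) — the conjugate family for a Gaussian covariance, kept weakly
informative.

**Sampler.**  Block Gibbs with conjugate draws for beta^(t) (one
(qp)-dimensional Gaussian solve per year, coupling pollutants through
C^{-1}), the long-run means, tau^2, delta^2 and C (inverse-Wishart with the
residual cross-product matrix scaled by 1/sigma_t^2); adaptive random-walk
Metropolis on logit(kappa) and on each ln sigma_t^2 (step sizes tuned to
~44 % acceptance during burn-in, then frozen).  Missing observations —
sites that do not report a pollutant in a year — are treated as unknowns:
each sweep draws them from the conditional Gaussian of N(Z beta, sigma_t^2
C) given the observed components at the same site-year (the marginal when
the site reports nothing).  The posterior draws of a held-out entry are
therefore its predictive distribution, which is what the leave-one-out
validation uses directly.

**Prediction and aggregation.**  At every ceil(n_retained / h)-th retained
iteration (default: h=100 predictions at every 300th of 30 000 retained
draws) the q-vector at each grid point is drawn from N(Z~ beta^(t),
sigma_t^2 C) and exponentiated.  Grid squares are classed urban background
or rural only — a 1-km average is never kerbside.  Including the residual
noise draw gives the full predictive distribution; a mean-only mode
(`include_noise=False`) is provided because the distinction matters for
variance propagated downstream and either convention is defensible.  Areal
exposures are the per-draw spatial mean or maximum over member grid points
(the maximum targets the urban pockets where people actually live); an area
containing no grid point falls back to the closest prediction location.

## Stage 2 — areal Poisson disease model

Counts Y_kt in area k and year t with expected counts E_kt (from external
age-sex standardisation; the exploratory risk measure is the standardised
incidence ratio SIR = Y/E):

    Y_kt ~ Poisson(E_kt R_kt)
    ln R_kt = b_kt' alpha + X_kt1 lambda + eps_kt lambda_r + phi_kt
    phi_t | phi_{t-1} ~ N( gamma phi_{t-1}, nu^2 Q(rho, W)^{-1} ),  phi_1 ~ N(0, nu^2 Q^{-1})
    Q(rho, W) = rho (diag(W 1) - W) + (1 - rho) I

Q is the Leroux conditional autoregressive precision on the binary border
adjacency W, interpolating independence (rho=0) and the intrinsic
autoregression (rho=1); gamma is AR(1) temporal dependence.  Priors:
regression effects N(0, 1000); nu^2 ~ IG(0.001, 0.001); rho, gamma ~ U[0,1].

**Two correlated pollutants.**  Putting both pollutants in the linear
predictor invites collinearity, so pollutant 2 enters through its
year-wise least-squares residuals on pollutant 1:
X_2^(t) = b0^(t) + b1^(t) X_1^(t) + eps^(t).  The residuals are exactly
orthogonal to pollutant 1 within each year and sum to zero, so lambda_r is
the effect of the pollutant-2-specific variation.  The decomposition is
asymmetric; both orderings should be fitted and reported (the CLI exposes
an `--ordering` flag), and the package deliberately does not auto-symmetrise.
Nothing beyond q=2 is supported: with more pollutants the orderings
multiply and the residualisation scheme stops being a sensible device.

**Baseline model (BM).**  Exposures are plugged in as fixed values: the
mean of the h stage-1 draws for pollutant 1, and the mean of the h residual
sets for the residual exposure (means of residuals rather than residuals of
means; OLS is linear so the two differ only through pairing of draws, and
the mean-of-residuals is the quantity defined draw by draw).

**Uncertainty model (UM).**  The h draws per cell are data in a classical
measurement-error model around latent true exposures:

    X_kt1^i ~ N( X_kt1, sigma_p^2 X_kt1^2 )   (error sd proportional to level)
    eps_kt^i ~ N( eps_kt, sigma_r^2 )          (constant error variance)

with weakly informative latent priors X_kt1 ~ N(mu_kt, s_kt^2), where mu_kt
is the empirical mean of the h draws and s_kt^2 = 1000 x their empirical
variance (floored at 1), and the same recipe for eps_kt; sigma_p^2 and
sigma_r^2 get IG(0.001, 0.001) priors and conjugate updates.  The residual
error variance is constant rather than proportional because residuals are
centred near zero, where a multiplicative error law would degenerate.
Latent exposures are constrained positive by proposing on the log scale
(residual exposures can be negative and use a plain random walk).  UM
requires h >= 2; with one draw per cell the error variance is not
identified and `fit_bm` is the appropriate tool.

**Sampler.**  Metropolis-within-Gibbs:

- alpha, lambda, lambda_r: adaptive scalar random walks on the Poisson
  log-posterior (target ~44 %).
- phi: single-site random walks, vectorised over (graph colour x year
  parity) blocks.  Within such a block cells are conditionally independent
  — the Leroux precision couples only graph neighbours (different colour)
  and the AR(1) only adjacent years (different parity) — so an entire block
  is proposed and accepted elementwise at once.
- Ridge (translation) moves: the linear predictor is invariant under
  (lambda + d, alpha_0 - d x_bar, phi - d (x - x_bar)), so the conditional
  law of d involves only the Gaussian priors and is available in closed
  form; it is sampled exactly for the intercept, lambda and lambda_r
  directions every sweep.  Without these moves the random field can
  impersonate any covariate at a prior cost the likelihood never sees, and
  the effects mix at a glacial rate along that ridge.
- nu^2 conjugate inverse-gamma; gamma a conjugate Gaussian truncated to
  [0,1]; rho a logit random walk whose Leroux log-determinant is evaluated
  through the (precomputed) Laplacian eigenvalues: det Q = prod(rho l_i + 1
  - rho).
- UM extras: all latent exposures updated simultaneously (conditionally
  independent given the parameters) from their cell-wise conditionals,
  using only the per-cell sufficient statistics (sum and sum of squares of
  the h draws); sigma_p^2 and sigma_r^2 conjugate.

Dense neighbourhood arithmetic is used up to ~2000 areas (faster than
sparse dispatch at these sizes); sparse beyond.  Adaptation freezes at the
end of burn-in.  Every conditional is verified in the test suite against an
independent oracle: dense multivariate-normal evaluation for the CAR x
AR(1) density, a grid-evaluated two-area posterior for the phi kernel,
numerical differentiation for the ridge-move moments, a grid-evaluated
one-cell posterior for the latent-exposure update, and a Geweke-style
forward/successive-conditional comparison for the joint.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with known truth.

*Fusion inputs* are drawn from the stage-1 model itself over a smooth
positive dispersion-model surface (urban bump + noise) and a north-south
temperature trend, with a monotone missingness schedule (monitoring
networks grow over time; the realised missing count per pollutant-year
matches the schedule exactly, and sites that come online stay online).

*Disease-study inputs* follow the published validation protocol for
comparing BM and UM:

- Relative-risk truths 1.030114 (pollutant 1, per 1 sd = 6.84 units) and
  1.005646 (residual pollutant 2); error-prone draws around the true
  surfaces with covariance sigma1^2 [[X1^2, 0.7 X1 X2], [0.7 X1 X2, X2^2]],
  sigma1^2 in {0.001, 0.005, 0.01, 0.05}; BM receives a single realisation,
  UM h=100 of them.  Nonpositive draws (impossible at the default scales)
  would be redrawn and counted.
- Random-effect truths nu^2=0.06, rho=0.9, gamma=0.83 — realistic posterior
  values for respiratory-admission panels of this kind.
- Exposure surfaces: sd 6.84 (pollutant 1) and 1.872 (pollutant 2), shared
  structure giving areal correlation 0.915, hence a residual-exposure sd of
  ~0.77, the scale on which the residual relative risk is defined.  The
  point-level correlation of measured data is lower (~0.74); it is the
  areal surfaces that the disease stage consumes.  The pollutant-1 mean is
  65: the spatial-maximum metric selects kerbside-level peaks, and at sd
  6.84 this mean/sd ratio is the one under which classical measurement
  error of size sigma1^2 produces the published attenuation pattern via the
  errors-in-variables slope factor 1 / (1 + sigma1^2 (1 + m^2/s^2)).
- Surface texture: a smooth component (Gaussian-filter length scale 0.8
  cells) mixed with 70 % cell-level variation, temporal persistence 0.7.
  The fine-scale weight is essential, not cosmetic: a surface dominated by
  broad smooth structure is statistically indistinguishable from the Leroux
  random field at desk scale, and the exposure effect would not be
  identified by ANY estimator.
- The whole risk surface is fixed across replicates: the random-effect
  field is drawn once per scenario and replicates differ only through
  Poisson noise and fresh error-prone exposure draws.  This mirrors a
  protocol in which all generating quantities come from one fit to real
  data and makes interval coverage interpretable cell by cell.
- The fixed field is orthogonalised against {1, X1, eps} in the inner
  product of its own prior precision (the CAR x AR(1) quadratic form at the
  truth rho, gamma).  A fitted random-effect field has this property
  automatically — it is what remains after the exposure effects are
  estimated.  A raw prior draw does not: its random projection on the
  exposure, measured in the prior metric where that component has prior sd
  ~ nu / ||x||_Q (orders of magnitude tighter than the N(0,1000) effect
  prior), is reattributed wholesale to the effect estimate and would make
  the study a lottery over truth seeds.

What passing the simulation study does **not** show about real data: the
generator has no unmeasured spatially structured confounding aligned with
exposure, no dispersion-model bias shared across space, no population
mobility, and expected counts are independent uniform (50–150 around 100)
rather than demographically structured.  The study isolates one question —
what ignoring versus propagating exposure uncertainty does to health-effect
estimates — under conditions where everything else is correct.

## Validation harnesses

*Leave-one-out cross-validation* (stage 1): each held-out observation is
marked missing, the model refitted, and the imputation draws of that entry
used as its predictive distribution; bias, RMSPE and 95 % coverage are
reported on the log scale per pollutant, for the multivariate fit and for
independent single-pollutant fits.  The multivariate model's advantage
comes from borrowing the co-located measurements of the other pollutant
through C, so it grows with the cross-pollutant correlation.

*Simulation study* (stage 2): per error level and replicate, counts are
generated, BM is fitted to one error-prone realisation (with its own
residualisation) and UM to all h, and the posterior-mean relative risks and
95 % intervals per 1 sd of the TRUE exposure scales are recorded.  The
metrics table reports bias, RMSE, mean interval width and coverage, with
the scale of the run attached as metadata so desk-scale numbers are never
mistaken for full-scale ones.  Replicates whose MCMC fails are dropped,
counted and logged.

## Operational sizes and numerical choices

- Full-scale defaults: 50 000 iterations, 20 000 burn-in, h=100 predictions
  at every 300th retained iteration.
- Desk scale used by the acceptance script and test suite: 10x10 lattice,
  T=5, 20 replicates, 5000 iterations / 1000 burn-in, h=100, error levels
  {0.01, 0.05}.  At this size one BM or UM fit takes a few seconds, and the
  whole study under fifteen minutes on one core.  Smaller areal panels
  (K=100 vs 1207) mean wider intervals and larger replicate scatter, so
  coverage-collapse effects that depend on very tight intervals (notably
  the residual-pollutant coverage at sigma1^2 = 0.01) appear at full scale
  but only partially at desk scale.
- Inverse-gamma draws are clipped to [1e-12, 1e12] (diffuse shapes like
  0.001 can underflow the underlying gamma draw); Leroux Cholesky factors
  receive escalating jitter with a logged warning if a (near-)singular
  rho=1 matrix is requested; exposure fields are floored at 5 % of their
  mean; CSV round trips use 17-significant-digit formatting and
  `float_precision="round_trip"` parsing, making write/read bit-identical.
- Adaptive step sizes target 44 % acceptance for scalar and single-site
  updates and 30 % for the vectorised latent-exposure updates, with a
  Robbins-Monro gain decaying as 10/(n+100), frozen after burn-in.
- Seeds: every public entry point takes either a seed or a
  `numpy.random.Generator`; the study harness derives independent child
  streams per replicate via `SeedSequence.spawn`, so runs are reproducible
  and replicates independent.

## Known limitations

- Two pollutants only; the residualisation device does not generalise
  cleanly to q > 2 and both orderings must be run explicitly.
- The two-stage design cuts feedback: the disease data never inform the
  exposure model.  Whether that induces bias is an open question the
  package does not address.
- The stage-1 model assumes residual spatial independence after covariate
  adjustment; use the semivariogram diagnostic before trusting it on a new
  region.
- The measurement-error model assumes the h stage-1 draws are unbiased,
  independent and Gaussian around the truth with variance proportional to
  X^2 (constant for residuals).  These assumptions hold by construction in
  the simulation study; on real data they should be checked against the
  draw ensembles.
- BM's residual exposure uses the mean of the h residual sets; residuals of
  the mean draws would differ slightly since the per-draw regressions are
  refitted.
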