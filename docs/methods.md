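# Methods

`eeanet` implements a complete analysis chain linking n-back task behavior to
brain-network activation: (1) Bayesian estimation of a diffusion decision
model (DDM) per subject, summarized as the efficiency of evidence
accumulation (EEA); (2) cross-validated principal-components regression (PCR)
predicting EEA from parcel-level activation maps, scored as an out-of-sample
partial correlation; (3) network-level association statistics with clustered
bootstrap inference; and (4) a synthetic cohort generator with known ground
truth against which the whole chain is validated.

## Behavioral model

Each trial is a two-boundary Wiener diffusion: evidence accumulates at drift
rate `v` with unit diffusion coefficient between absorbing boundaries at 0
and `a`, starting at `z·a`. The model is accuracy coded — the upper boundary
is the correct response for every stimulus class (`match` for targets,
`nonmatch` for novels and lures) — so each class's drift measures the quality
of evidence toward the correct answer. Per load condition (0-back, 2-back)
there are eight free parameters: three class drifts (`v_target`, `v_novel`,
`v_lure`), boundary separation `a`, non-decision time `t0` with uniform
between-trial variability of width `st0`, relative start point `z`, and a
contaminant-omission probability `p_contam`. Between-trial drift and
start-point variability are deliberately not modeled: they are poorly
recoverable at 80 trials per condition. The diffusion coefficient is fixed at
1 as the scaling convention; estimates are comparable only across fits that
share it.

Omissions are a two-part mixture. With probability `p_contam` the trial is a
contaminant non-response arising outside the decision process (inattention);
otherwise the diffusion runs and the response is censored whenever decision
plus non-decision time exceeds the 2-s response window. Writing `M` for the
probability that either boundary is reached within the window,

    P(omission) = p_contam + (1 - p_contam) · (1 - M),

and an observed response at time `t` contributes
`(1 - p_contam) · f_boundary(t - t0')` averaged over the uniform
non-decision-time distribution. Because the correct/error/omission
probabilities are defined from the same within-window masses, they sum to one
by construction.

### Numerics

The first-passage density uses the classic pair of series expansions — a
small-time expansion in Gaussian terms and a large-time Fourier sine series —
with an elementwise switching rule based on the number of terms each series
needs for a 1e-10 truncation target. A compiled (numba) kernel evaluates the
density; a pure-numpy implementation of the same series is kept and
cross-checked in the tests to 1e-12.

Integration over the non-decision-time interval `[t0, t0 + st0]` uses
10-node Gauss–Legendre quadrature, validated against adaptive quadrature at
relative tolerance 1e-6. Within-window absorption masses integrate the
density under the rational map `t = c·s/(1-s)` with `c = a²` (the
characteristic diffusion time); this resolves the sharp density peak at short
times while remaining accurate for arbitrarily long horizons (worst-case
absolute error ~3e-6 at 48 nodes; the sampler uses 32 nodes, ~6e-5, which is
negligible against Monte-Carlo error in the posterior).

Trial simulation uses Euler–Maruyama at `dt = 1e-4` with a Brownian-bridge
within-step crossing test: after each step the path is scored as absorbed
with probability `exp(-2·d0·d1/dt)`, where `d0, d1` are the distances of the
step's endpoints from the boundary. The naive scheme without this correction
misses within-step crossings and biases passage times late by
O(√dt) ≈ 6 ms — enough to push the distributional (KS) distance from the
analytic density to ~0.008, above tolerance; the bridge correction removes
the leading bias (measured KS 0.0007–0.0025 at 10⁶ trials, i.e. at the
Monte-Carlo noise floor).

### Quality exclusions

Fast guesses (RT < 200 ms) are removed trial-wise first, so they are not
scored as errors. A subject is then excluded when, in either load condition,
accuracy over non-omitted trials falls below 55% or the omission rate over
all trials exceeds 25%. Accuracy and omission rates use different
denominators (scored trials vs all trials) because the two criteria address
different failure modes.

## Bayesian estimation and EEA

Each subject's 16 parameters are estimated under truncated-normal priors by
differential-evolution MCMC (DE-MCMC): proposals are scaled difference
vectors between randomly chosen chains (γ = 2.38/√(2d), with occasional
γ ≈ 1 mode-jump proposals and small uniform jitter), which automatically
adapts to the strong parameter correlations of sequential-sampling
posteriors. Because the two conditions share no parameters, the posterior
factorizes into two 8-dimensional blocks; the sampler exploits this by
updating the blocks alternately within each sweep — an exact scheme that
mixes far better than joint 16-dimensional proposals (which, in testing,
left the split-rhat stuck near 1.2). Defaults: 24 chains (three per free
block dimension), 400 burn-in sweeps with a low-probability migration move
(stuck chains adopt better states; burn-in only), then rounds of 500 sweeps
repeated until every parameter's split-chain potential-scale-reduction
statistic over the latest round is below 1.1, capped at five rounds. A fit
that never converges is retained but flagged, and downstream analyses warn
when they consume it. `p_contam` is sampled on a logit scale (with the
Jacobian in the prior) to respect its bounds; all other parameters are
sampled natively with bound rejection through the prior support.

Truncation bounds — `a ∈ (0, 10]`, `t0 ∈ [0.05, 1]`, `st0 ∈ [0, 1]`,
`z ∈ (0.1, 0.9)`, `v ∈ [-10, 10]`, `p_contam ∈ [0, 0.5]` (seconds /
evidence units) — cover the plausible human RT regime under the
unit-diffusion convention.

EEA per condition is the mean of the posterior medians of the three class
drifts; the headline index `eea_mean` averages the two conditions. Model
adequacy is checked by posterior predictive simulation (accuracy, omission
rate and RT deciles per condition against 95% predictive intervals).

### Informative priors

The shipped priors (`eeanet/data/default_priors.yaml`) emulate a two-step
prior-construction procedure: fit the model to an independent 300-subject
calibration cohort, pool the posterior draws across subjects per parameter,
and fit a truncated normal to each pooled distribution by maximum likelihood.
The calibration cohort here is synthetic (drawn from the generator's default
population) and is fitted subject-by-subject under weakly informative priors;
pooled individual-level fits replace the hierarchical group model of the
original procedure, whose group-level machinery is out of scope. Priors for a
population expected to differ from the calibration sample can be widened by
multiplying every scale by a factor (e.g. 1.5) without touching locations or
bounds. The truncated-normal MLE constrains location to within two interval
widths of the bounds and scale to ten widths: beyond that box the family
degenerates into exponential tilts whose parameters are not identifiable.

## Synthetic cohorts

The generator emulates the statistical structure the downstream analyses
assume, with every planted quantity recorded as ground truth.

**Task schedule.** Per condition: 8 blocks × 10 trials, each block with
exactly 2 targets, 2–3 lures (uniform), remainder novel, order randomized
within block — 80 trials per condition.

**Behavioral population.** Class drifts decompose as
`μ(class, condition) + σ_common·u_condition + σ_class·ε + covariate and
cluster effects`, where the condition-level latents `u` are correlated so
that overall EEA correlates 0.45 across load conditions (the latent
correlation is solved analytically from the variance components). Non-drift
parameters are independent truncated normals. Defaults give ~85–95% accuracy
and a few percent omissions — an engaged participant — with means such as
`v_novel` 3.0 (0-back) vs 2.2 (2-back) and `a` 1.1 vs 1.2 (harder condition:
lower drift, slightly wider boundary, longer non-decision time).

**Activation.** Activation is generated at parcel level (400 parcels
labelled into the 7 canonical resting-state networks), not at the ~90k
grayordinate level, for desk-scale speed; the prediction module is agnostic
to column count. The model is linear-Gaussian and written directly in
residual-standardized terms: for network `n`, condition `c`,

    net_mean = baseline(n,c) + r(n,c)·E + q(n)·G + site + family + u(n,c)

with `E` the standardized covariate-free part of overall EEA, `G` a shared
general-activation factor, and variance components summing to one — so
`r(n,c)` *is* the population partial correlation of the network mean with
EEA. The general factor's loading is solved per network from the target
cross-condition correlation (0.35) after subtracting the site/family shares
(0.04/0.06) and the EEA channel, which makes positive-definiteness explicit
and checkable at construction. Parcels add independent noise (SD 0.8), a
nuisance structure (age, motion, sex effects on selected networks), and a
fixed zero-mean within-network loading pattern on EEA whose two conditions
carry opposite signs; the pattern's scale is calibrated by root-finding at
construction so the population R² of EEA given the full 2-0 parcel map is
0.36 (computed exactly from the generative covariance). Because the pattern
is centered within networks it leaves the network-mean correlations
untouched.

The default (`table1_preset`) plants per-condition correlations with the
divergent task-positive pattern (FPN −0.27/+0.17, DAN −0.07/+0.17,
SMN +0.02/−0.29 for 0-back/2-back, smaller values for the other four
networks), which implies 2-0 contrast correlations of about +0.39 (FPN),
+0.21 (DAN) and −0.27 (SMN). These are targets of the generator, not
results.

**Clustering and covariates.** Families (80% singletons, 20% sibling pairs)
are nested in 20 sites; age is uniform 9–11 years, motion (framewise
displacement) log-normal around 0.18 mm, sex balanced, race/ethnicity a
4-level categorical with arbitrary labels, dummy-coded downstream. Site and
family random effects enter both behavior and activation (independently), so
observations are dependent within clusters in every analyzed variable.

**What the generator does not emulate.** Spatial autocorrelation within
networks (parcel noise is exchangeable), fMRI time-series/HRF structure
(maps are generated directly at the contrast level), stimulus-category
effects, longitudinal structure, and missingness. Passing tests therefore
show that the estimators are correct and calibrated under the planted
dependence structure — not that real activation maps satisfy that structure.

## Cross-validated PCR

Within each training fold: features are centered on training means (no
per-feature scaling — activation features share units); principal components
are computed by SVD; the retained component expressions *and* the outcome are
regressed on the nuisance design (intercept; age, age²; sex; race/ethnicity
dummies against a fixed level set; FD, FD²); and OLS maps residualized
expressions to the residualized outcome. Test rows are centered, projected
and residualized with training-fold parameters only, and the fold's score is
the Pearson correlation between predicted and residualized observed outcome —
a cross-validated partial correlation. Per-fold correlations are averaged
unweighted.

K (number of components) is chosen per outer fold by nested 5-fold CV inside
the training rows, scored by the same partial-correlation metric
(self-consistency between inner and outer objectives); ties break toward the
smaller K; candidates beyond the feasible rank are dropped. The default grid
is {5, 10, 25, 50, 100, 250}.

Fold schemes: leave-one-site-out, or k-fold with whole families dealt to
folds (largest-remaining-deficit balancing); family-respecting assignment is
the conservative default even for single-site data because sibling pairs
violate exchangeability. Consensus feature maps multiply each component
loading by its regression weight and sum over components; per-fold maps are
averaged and then z-scored (a full-sample refit mode is also provided, since
"consensus" admits both readings).

Calibration facts established by the validation studies: on
covariate-confounded null cohorts the mean out-of-fold partial correlation is
0 ± 0.04 (the residualization removes the confound); with the preset's
planted R² = 0.36 at n = 2000 the mean out-of-fold r is ≈ 0.53 — √0.36 = 0.6
attenuated by estimation noise.

## Network association statistics

Network means are unweighted averages over member parcels per contrast
(0-back, 2-back, 2−0). All variables are residualized on the same nuisance
design before analysis. Correlations are Pearson throughout.

**Clustered bootstrap.** Confidence intervals are percentile intervals over
2000 (default) replicates of a cluster bootstrap. The default scheme
resamples whole sites with replacement and keeps every member of each drawn
site; since families never span sites, this respects both levels of
dependence. A two-stage variant (additionally resampling families within
each drawn site) is provided for sensitivity analyses but is *not* the
default: resampling both stages double-counts within-site variance — when
family-level variance dominates, the bootstrap SD is inflated by up to √2 —
and in simulation its nominal 95% intervals covered 97.5–99.5% of the time,
whereas the site-resampling scheme covers 93–95% across realistic cluster
designs (30 sites, sibling pairs, intraclass correlations ≤ 0.1). Degenerate
replicates (zero variance) are redrawn, erroring if they exceed 1% of
replicates.

The difference statistic `|r₁| − |r₂|` is computed inside each shared
replicate, giving a CI for the difference of absolute correlations. The
regression comparison fits OLS of residualized EEA on a subset of network
means (default FPN, DAN, SMN) and on all seven, reporting r(fitted,
observed) for each with the model refit inside every bootstrap replicate.

**Bins and quadrants.** The decile-bin summary ranks subjects by
covariate-adjusted EEA, splits them into 10 near-equal bins (remainder
spread over the lowest bins), and reports per-bin activation means with
normal-theory 95% CIs plus the OLS slope of bin mean on bin rank (fit on the
bin means, matching the plotted construction). The quadrant analysis
z-scores 0-back activation, 2-back activation and EEA, fits OLS of 2-back on
0-back activation, and crosses above/below that line with 0-back activation
above/below its mean; it reports mean standardized EEA and counts per
quadrant. Empty quadrants report NaN with count 0.

## Problem sizes used in the validation suite

The studies are sized to be decisive yet desk-scale: density–simulator
agreement at 10⁶ trials per parameter regime (5 regimes); EEA recovery with
50 subjects × 80 trials/condition under the shipped priors; null calibration
over 100 confounded cohorts (n = 500, 100 features); signal recovery at
n = 2000 with leave-one-site-out folds; bootstrap coverage over 300
clustered datasets (420 subjects each, 500 replicates); pattern reproduction
at n = 4000. The acceptance script (`scripts/acceptance.py`) reruns the same
studies, with the simulator-equivalence study at 4×10⁵ trials per regime.

## Known limitations

- Individual-level fits only; no hierarchical shrinkage across subjects
  (priors carry the population information instead).
- The omission likelihood's mixture-with-censoring form is a modeling choice;
  other decompositions of non-responses are possible and not distinguishable
  from 80-trial data.
- The percentile bootstrap has no second-order (BCa) correction; with ~20–30
  sites its intervals run slightly anti-conservative (93–95% coverage).
- Parcel-level generation omits spatial autocorrelation, so consensus-map
  smoothness seen with real data has no synthetic counterpart.
- The truncated-normal prior family cannot represent multimodal pooled
  posteriors; with the default population this was not observed.
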