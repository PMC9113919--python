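# Methods

`speedscale` re-implements, as a tested pipeline, an analysis of speed
estimation for reflexive ocular tracking: how human ocular following
responses (OFRs) to drifting gratings (DGs), motion clouds (MCs) and
composite patterns reveal a speed representation organised along speed and
scale axes of the spatiotemporal-frequency plane, and how a dynamic
probabilistic channel-interaction model accounts for it.  This note records
the model, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## Coordinates

All geometry lives in (x, t) = (log2 sf, log2 tf), octaves.  The *speed
axis* is the iso-velocity direction (x and t increasing together, tf/sf
constant); the *scale axis* is orthogonal (speed varying, tf·sf constant).
Channel and kernel computations use base-2 logarithms throughout: kernel
widths are stated in octaves, and only under log2 does the packaged
weight polynomial peak at 0.21 c/deg.  Pure geometry (angles, normalized
distances) is log-base invariant.

Catalog distances are expressed in *grid units*: the c1–c5 log distance
(0.4334 octaves), the innermost ring spacing, which is the only
normalization consistent with every printed catalog row.  A pattern's
nominal speed is the median of its component speeds — the central
component for the symmetric triplets, the midpoint for pairs — which is
what the packaged catalog prints; the arithmetic mean would not reproduce
the triplet rows.

## Stimulus models

A motion cloud is parameterized by centre frequencies (sf0, tf0) and
FWHM bandwidths B_sf = B_v = 1 octave (Gaussian sigma = FWHM / (2 sqrt(2
ln 2))).  Its spectral envelope is a product of Gaussians in (log2 sf,
log2 v) sheared onto (log2 sf, log2 tf) via log2 tf = log2 sf + log2 v;
the orientation dimension (theta0 = 90 deg, 15 deg spread) is
marginalized out because the channel model is two-dimensional.  The
default envelope grid is 64x64 nodes over +-3 octaves around the centre
(union box for patterns); mass is normalized to one and a warning is
raised if the grid truncates >1% of the analytic mass.  A grating is a
Dirac point; the channel model evaluates it exactly rather than through
the grid.  Pattern envelopes are node-wise averages of their components.

Movies are synthesized directly at desk scale: MCs as a sum of N
random-phase drifting Gabor elements with characteristics sampled from the
envelope distributions (default N = 300, spatial envelope SD of one
carrier wavelength), gratings as analytic sinusoids, patterns as scaled
sums; the result is rescaled to 60% RMS contrast.  Streaming
autoregressive synthesis is out of scope.  Because tf = sf·v with sf and
v drawn independently, the movie's temporal-frequency content has a
sqrt(2)-octave FWHM; spectral checks therefore use a box of two octaves
per side around (sf0, tf0), inside which the synthesized movie holds
~98% of its power.

## Eye-trace analysis

Positions (1 kHz, 400 ms) are low-pass filtered (5th-order Butterworth,
40 Hz), differentiated by central differences over samples 10 ms apart,
and the velocity filtered again at 30 Hz.  Filters run zero-phase
(forward–backward `filtfilt`), so latency-sensitive quantities carry no
group delay; phase handling is not otherwise constrained.  Leftward
trials are sign-flipped.  Artifact rejection defaults to |v| > 80 deg/s
or |a| > 5000 deg/s² sustained for >=5 ms (the original screening was by
eye; thresholds are configuration, not doctrine).  The mean blank-trial
velocity is subtracted from every valid trial.

Mean eye velocity is summarized over five inclusive 50-ms windows,
[51,100] … [251,300] ms; the first is a pre-response baseline.  Per
condition and window, the across-trial distribution of window means is
summarized by moment matching (the Gaussian MLE): mu, sigma, CV =
sigma/mu (mu > 0 only) and sigma_d = sigma − sqrt(mu), the deviation
from the shot-noise-like square-root variability law.

Quadric tuning surfaces R(x,t) = q0 + q1 x + q2 t + q3 x² + q4 x t +
q5 t² are fitted by unweighted OLS to the 15 response amplitudes (the
pipeline fits raw amplitudes; analytic anchor tests fit the log of
Gaussian surfaces, which is exactly quadratic).  Derived quantities:

* Q = −(1 + q4/(2 q5)), taken as the definition here (0 = speed tuned,
  −1 = separable); undefined when |q5| is below tolerance.
* Angles use one convention: for a direction (dx, dt), angle =
  atan2(dx − dt, dx + dt) folded into (−90, 90], measured from the speed
  axis, so the temporal-frequency axis direction sits at +45 deg, the
  spatial-frequency direction at −45 deg and the scale axis at 90 deg.
  Theta is the angle of the per-speed argmax locus (analytically the
  straight line (q1+q2) + (2q3+q4)x + (q4+2q5)t = 0; defined only when
  curvature along the speed axis, q3+q4+q5, is negative).  Phi is the
  angle of the Hessian eigenvector with the smallest absolute curvature
  (the surface's long axis); saddle Hessians are flagged.

The linear prediction for a pattern is the sample-wise mean of its
component mean traces; R_NL = e_obs/e_pred per window, undefined for
non-positive predictions.  Separation times bin traces into 5-ms windows
and use Welch's two-sided t test (unequal variances are the safe default),
declaring separation at the
first bin opening a run of k consecutive significant bins.  k defaults
to 3 (a single-bin criterion at alpha = 0.05 over 80 bins inflates false
alarms; k = 1 remains available for literal replication); analyses on
cohorts with trial-wise smooth noise use k = 10, since temporally
correlated noise can sustain short spurious runs.  The prediction's
trial population is built by resampling: each pseudo-trial averages one
randomly drawn trial per component, giving the prediction an empirical
variance (this package's convention).  Separation-time samples are compared with a
bootstrap trimmed-mean test (default 1000 resamples, 20% trim,
two-sided add-one p value).

## Channel model

The bank holds N = 722 channels on a 19 x 38 lattice over log2 sf in
[−3, 1] and log2 tf in [1, 6], so every preferred speed tf/sf lies in
[1, 512] deg/s.  Each channel is a bivariate Gaussian over (x, t) with
sigma_x = sigma_t = 0.5 octaves and correlation rho = 0.6 (elongation
along the iso-velocity diagonal).  Channel weights follow a quadratic
polynomial of the channel centre with packaged coefficients
b = (−23.88, −3.63, 1.95, −0.72, 0.61, −0.45).

*Weight rule.*  That polynomial is negative everywhere on the lattice
(its maximum, at 0.21 c/deg and 1.6 Hz, is −19.2), so flooring it at
zero would silence the entire bank.  The package reads the coefficients
as log-weights: w = exp(poly − max poly), a Gaussian-like profile with
peak weight one and the same arg-max; channels far from the peak get
exponentially small weights ("beyond the window of visibility").  The
literal floored polynomial remains available
(`weight_transform="linear_floor"`).  Under peak-normalized weights the
participant gain g is O(1); gains quoted for unnormalized weightings are
not comparable.

Feedforward activity is m_i = g² w_i ⟨phi_i, s⟩ c: exact point
evaluation for gratings, envelope-grid integration for clouds (within 1%
of a 512x512 brute-force grating sum), component averaging for patterns.

*Interaction kernel.*  d(Delta) = alpha (E(Delta)/E(0) − I(Delta)/I(0)),
a difference of peak-normalized zero-mean Gaussians whose covariances are
rotated by theta = 3 pi/4 — the first rotated axis is the scale
direction, the second the speed direction.  The packaged parameter set
(alpha = 2.16) gives excitation SDs (0.2542, 0.7718) and inhibition SDs
(0.7711, 0.2501) over (scale, speed): excitation elongated along the
iso-velocity line, inhibition along the scale axis.  The per-axis
assignment of the inhibition SDs is this package's reading: assigning
both Gaussians the same axis order makes excitation strictly broader than
inhibition on both axes, hence d >= 0 everywhere — no inhibition anywhere,
contradicting the crossed excitation/inhibition pattern the model exists
to express.  `InteractionParams.same_axis_order()` constructs that variant
for comparison.

*Interaction field.*  I_i = sum_j (m_j / max_k m_k) d(Delta_ij): the
kernel is driven by the peak-normalized population activity.  The
divisive normalization makes the field gain-invariant, and it is what
allows supralinearity: with the raw activity, a P-component pattern's
within-component interaction dilutes by 1/P² (pattern activity is the
component average) and no parameter choice can make speed-axis patterns
supralinear.  With it, summed network activity is sublinear for
scale-axis patterns (ratio ~0.6 for the pure scale triplet) and
supralinear for speed-axis patterns (~1.16), reproducing the crossed
pattern.  Default combination is n = m (1 + I) rectified at zero, which
reduces to n = m without interactions; the literal multiplicative n = m·I
is available but reduces to nothing sensible in any limit.

*Decoding.*  Each channel carries a unit-peak Gaussian speed tuning over
log2 speed at its preferred speed with variance sigma²(1−rho) (the
cross-section derivation suggesting 2 sigma²(1−rho) is
exposed as `variance_mode="cross_section"`).  The population
log-likelihood is the activity-weighted sum of log tunings — a quadratic
in log2 speed.  The posterior recursion starts from a log-normal
slow-speed prior (mu_prior = 2.51, sigma_prior = 0.86 in natural-log
speed units, i.e. a prior mean near 12 deg/s, converted internally to
log2) at the [101,150] ms window (omega = 0) and multiplies in the same
likelihood at each of the three following 50-ms windows; the feedforward
drive carries no window index, so all temporal dynamics come from the
recursion.  The speed grid is 512 points over log2 speed in [−2, 10]
(0.25–1024 deg/s); densities are trapezoid-normalized.

## Fitting and model comparison

Observed per-trial window-mean velocities are scored under each window's
posterior density (log2 change of variables included); trials at or
below 0.25 deg/s are excluded from the log mapping and counted, and
densities below 1e−12 are floored and counted.  Parameters are fitted by
bounded multi-start Powell search (derivative-free; 8 starts by default,
the first from the supplied baseline, the rest drawn within bounds,
log-uniformly for the positive scale parameters).  AIC = 2k − 2 loglik;
the interaction variant frees five extra parameters (alpha and the four
kernel SDs; the rotation stays fixed), so equal likelihoods give a
difference of exactly 10.

## Synthetic cohorts

The phenomenological generator emulates the study conditions: Gaussian
tracking latency 85 +- 10 ms; saturating-exponential velocity rise
(60-ms time constant) to a condition plateau, with plateaus capped near
10 deg/s for 24 deg/s stimuli (ocular following reaches only a fraction
of stimulus speed) and scaled by v0^0.4 across speeds; blank trials with
exponentially decaying postsaccadic drift (0.5 deg/s); saccade-like
artifacts (100–300 deg/s transients) in 8% of trials; balanced
left/right directions with positions integrated from velocity.
Across-trial variability follows sigma = kappa sqrt(mu) (kappa = 1) per
window: one noise draw per trial is shaped by a square-root amplitude
profile whose variance is reduced by the (numerically computed) variance
the latency jitter already contributes — so the law holds for the
*measured* window statistics, not just the injected noise — and
inflated by a factor 1.5 after 200 ms for high-scale grating conditions.
Pattern plateaus default to the component average, making R_NL = 1 the
built-in null; divergences (step onset and size per condition) can be
injected for separation-time checks.

The model-driven generator samples per-window velocities from the channel
model's posteriors (the prior at omega = 0) for closed-loop parameter
recovery; its default ground-truth gain is g = 0.5, chosen once so the
posterior sharpens gradually over the fitted windows (log2-speed SD
falling from ~0.4 to ~0.25, i.e. trial-to-trial velocity scatter of a
few deg/s) rather than collapsing in one update.

What passing tests show — and what they do not: the synthetic cohorts
have exactly the statistical structure the analyses assume (Gaussian
window means, the square-root law, stationary plateaus, independent
trials).  Real eye traces have saccadic intrusions with main-sequence
structure, closed-loop feedback after ~180 ms, serial dependence across
trials and participant idiosyncrasies, none of which are emulated;
recovery of generator parameters here validates the estimation machinery,
not the model's adequacy for real cohorts.  Participant-specific fitted
values from the original study (gains, priors, latencies, separation-time
medians) depend on the unavailable human data and are deliberately not
reproduced.

## Problem sizes

Default test-suite workloads: 64x64 envelope grids (512x512 for oracle
comparisons), 722-channel bank, cohorts of 150 trials per condition,
parameter recovery over 10 seeds with 4 optimizer starts, and AIC model
selection over 10 seeds per regime with 2–3 starts and a capped function
budget — sizes chosen to exercise the full pipeline at desk scale.
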