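# Methods

## The model

SmChiA processively hydrolyses single chitin chains on the crystal
surface, advancing one chitobiose unit (1.04 nm) per catalytic turnover.
The package models its motion as a renewal process over four event kinds:

* **1-nm forward step** (`forward1`) — the productive cycle.  The pause
  before it is the *sum* of two sequential exponential waiting times:
  fast substrate-assisted catalysis (τ_cat, default 2.9 ms) followed by a
  lumped slow process (τ_forward_long, default 23.9 ms) covering product
  release, decrystallization of the next chitobiose unit and chain
  sliding.  The dwell density is therefore the convolution
  `f(t) ∝ exp(−t/τ_long) − exp(−t/τ_short)`, rising from zero and peaking
  near 7 ms.
* **2-nm forward step** (`forward2`) — a double-length advance with its
  own single-exponential dwell (τ, default 26.0 ms), attributed to spots
  of incomplete surface crystallinity where only one unit needs peeling.
* **Backward step** (`backward`) — a thermal excursion into the
  chain-twisted state (single exponential, default 18.3 ms).
* **Recovery step** (`recovery`) — the forward step that always and
  immediately follows a backward step, repeating the forward mechanics
  *without* product release (default 17.1 ms).  The difference
  τ_forward_long − τ_recovery = 6.8 ms is therefore the product-release
  time constant — the central subtraction of the scheme assembly.

Step kinds are drawn with fixed probabilities (0.693 / 0.142 / 0.165 for
forward / double / backward), not from rate competition; this matches the
ratio-based sampling the analysis is validated against, and makes the
emitted forward fraction 83.5 % by construction.  The branching
probability computed from the fitted rates, k_cat/(k_cat + k_back) =
86.3 %, is the mechanistic counterpart; the two agree within the
uncertainty of the fitted rates, which is the internal-consistency check
the pipeline reports.  The closed-form mean velocity of the chain,

    v = (q_f + 2 q_d)·d / (q_f·(τ_cat+τ_fl) + q_d·τ_f2 + q_b·(τ_b+τ_rec)),

serves as the independent oracle for ensemble-velocity tests (38.8 nm/s
for a backward-free cycle at d = 1.04 nm; ≈ 39 nm/s with the default
mix at the measured 1.1 nm step).

## Synthetic data

The generator emulates the statistical structure the detector faces:
piecewise-constant staircases sampled at 0.5 ms, with zero-mean Gaussian
localization noise whose SD is redrawn **per pause** from a Gaussian
(peak 0.34 nm, spread 0.10 nm, truncated below 0.05 nm) — pause-to-pause
variation of localization precision is what makes some pauses much harder
than others.  The off-axis channel is pure noise.  A configurable axis
angle rotates the track into the raw camera frame.

It does **not** emulate: stage drift, probe-linker dynamics (noise is
white within a pause), intensity fluctuations coupled to position,
enzyme dissociation/rebinding, or curved fibrils.  Passing tests
therefore demonstrate the soundness of the analysis chain under the
stated noise model, not robustness to correlated experimental
disturbances.

`min_dwell_ms` optionally rejection-samples dwells above a floor.  It
exists for detector-validation fixtures only: step-*count* identification
is meaningful only when every pause is resolvable at the camera rate, so
the count-accuracy fixture draws staircases with all dwells ≥ 10 ms
(matching the resolvability threshold used for the boundary-recovery
check), while detection-rate and size-distribution checks use the
unconditioned mix.

Image fixtures (`synth_spot_stack`) render pixel-integrated symmetric
Gaussian spots (erf differences, exact) with Poisson noise and 12-bit
saturation on a 66.7 nm pixel grid.

## Step detection

`StepFinder` implements greedy chi-square plateau splitting: each round
exhaustively searches every plateau for the split minimizing the residual
sum of squares (cumulative-sum arithmetic, ties to the earlier index;
minimum plateau 3 frames = 1.5 ms) and accepts the best one.  The step
count is selected by the counter-fit statistic S(n) = chi²(counter-fit) /
chi²(fit), with counter-boundaries at the midpoints of the n-step fit's
plateaus; S peaks at the true count on clean staircases and the peak S
must exceed `s_threshold` for a trace to be accepted.

Two practical findings shaped the defaults:

* On median-filtered traces the noise is correlated over the filter
  window, so deep over-fitting keeps reducing chi²(fit) and argmax-S
  over-counts.  A **pruning pass** therefore merges, weakest first, any
  selected step that is smaller than 0.55 nm (half the unit step — below
  the instrument's own "can it resolve 1-nm steps" criterion) or whose
  level difference is below 5 local standard errors (the SE combining the
  two flanking plateaus' residual scatter).  With pruning, exact
  step-count identification on resolvable 8-step staircases reaches
  ~90 % and spurious sub-nm steps essentially vanish.
* The default median half-window is **1.0 ms** (5 samples), not the
  ±2 ms of common practice: a 9-sample median erases plateaus shorter
  than ~2.5 ms, and simulations show the shorter window recovers the
  fast forward time constant with several-fold less censoring at equal
  boundary accuracy.  The window is configurable.

`s_threshold` defaults to 2.0, calibrated against the null: the maximum
S over white-noise traces stays below ~1.6, while real staircases at the
default noise give S ≥ 5.  (On filtered traces the null S is inflated to
~3–4.5 by noise correlation; step-free stuck particles are rejected
earlier by the axis-anisotropy check, which requires a ≥ 2:1 eigenvalue
ratio of the position covariance.)

## Dwell-time fitting

Histogram fits use the **bin-averaged model expectation** (exact
integrals over each bin), not the density at bin centres — centre
evaluation biases the convolution's fast constant by ~15 % at 4-ms bins.
Defaults: 4-ms bins for single-exponential categories, 2-ms bins for the
convolution (the rise carrying τ_short is unresolvable at 4 ms);
sensitivity at 2/4/6 ms is exercised in the tests.  Weights are uniform
by default (`weights="poisson"` available); the first bin is excluded by
default.

First-bin exclusion matters because detection miscounts the shortest
dwells: the detector cannot resolve pauses below its dead time
(~min-plateau, 1.5–2 ms), so the first bin of a detected-dwell histogram
is depleted, and fits that include it are pulled away from the truth
while fits without it sit on the undistorted part of the distribution.
The tests demonstrate this on dead-time-censored samples.

For *parameter recovery* the pipeline goes one step further and assembles
the kinetic scheme from **censoring-corrected maximum-likelihood fits**
(`scheme_estimator="censored_mle"`): the hypoexponential likelihood
conditioned on t > 2 ms for the forward convolution, and the shifted-mean
estimator `mean(t | t > 3 ms) − 3 ms` for single-exponential categories
(exact by memorylessness; the larger dead time reflects that these
categories need two resolvable flanking steps).  The binned
least-squares fits remain the reported/display convention
(`scheme_estimator="ls"` restores them as the scheme source).  With the
defaults, a 50-trajectory self-consistency run recovers all five time
constants within ~10 %.

## Other estimators

* **Step-size mixture**: least-squares sum of Gaussians on a 0.3-nm
  histogram; 3 components by default with physics-informed initialization
  (−m, m, 2m around the positive median); k-means re-initialization on
  non-convergence; event ratios from analytic component areas
  (amp·sd·√2π), invariant to bin width by construction.
* **Velocity**: OLS slope of on-axis vs time, in nm/s.
* **Run length**: single-exponential histogram fit (first bin excluded,
  10-nm bins); processivity = mean run length / 1.04 nm, rounded.
* **Substrate inhibition**: `v = kcat·[S]/(Km + [S] + [S]²/Ksi)` fitted
  with the inhibition term parameterized as 1/Ksi ≥ 0, so "no detectable
  inhibition" lands at a finite bound (flagged when 1/Ksi is within twice
  its own standard error of zero) instead of a diverging parameter.
* **KIE**: τ_D₂O/τ_H₂O for time constants, kcat_H₂O/kcat_D₂O for rates;
  both conventions report the slow-down fold.
* **Thermodynamics**: K = k_dec/k_back, ΔG = −RT ln K with
  R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ at 298.15 K.  K is additionally printed
  rounded to one decimal; ΔG always uses the unrounded ratio (rounding
  first would shift −0.04 to −0.06 kcal/mol).  Rates print at three
  significant figures; exact values are accessible as `k_*_exact`.

## Problem sizes and reproducibility

Default self-consistency runs use 50 trajectories × 150 events
(≈ 7 000 detected steps, ≈ 4 500 forward dwells), chosen so each category
pool supports its fit (n ≥ 500 for single-exponential categories) and the
fast constant's sampling error stays under ~10 %.  Every simulation takes
one seeded NumPy generator; child trajectory seeds derive from the master
seed and are echoed in each trajectory's metadata sidecar, making runs
bit-reproducible.  Outputs carry a hash of the scientific configuration
(output directory and log level excluded), so re-running a config
overwrites its bundle identically.

## Known limitations

* The axis is one straight line per trajectory (PCA of the position
  scatter, sign from net displacement); curved fibrils are out of scope,
  and the experimental alternative — drawing the axis along the fibril
  image — is available only as a manual θ override.
* No drift correction; stationarity within a trajectory is assumed.
* Detection systematically loses backward/recovery pairs whose member
  dwells fall under the dead time, so the *detected* forward fraction
  (~87 %) sits above the emitted 83.5 %; the same loss affects any real
  recording at these rates, which is why the scheme is validated by the
  rate-derived branching probability rather than raw event counts.
* One spot per ROI; no multi-particle linking.
* The 2D-Gaussian PSF is symmetric with a constant offset; ellipticity is
  not modelled.
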