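# Methods

This note records the models implemented in `sharkmove`, the conventions
and numerical choices behind them, and what the synthetic testbed does and
does not establish about analyses of real footage.

## Trajectory model

A video yields positions p_t = (x_t, y_t), one per frame (30 fps by
default). The analysis consumes the derivative structure only:

- step length  L_t = ‖p_{t+1} − p_t‖  (T−1 values for T positions),
- heading      h_t = atan2(Δy_t, Δx_t),
- turning angle φ_t = wrap(h_t − h_{t−1}) ∈ (−π, π]  (T−2 values).

Both are invariant under rigid motions of the image plane, which is why
initial position and heading are irrelevant everywhere downstream.

**Body-size correction.** Coordinates are divided by the animal's body
length (same units), so steps are in body lengths per frame and speeds in
body lengths per second. Larger sharks swim faster in absolute units;
this is the simplest correction that makes individuals comparable. When no
body length is available the track passes through unchanged and is flagged.

**Smoothing.** An undulating swimmer's head oscillates laterally (yaw),
which inflates angularity statistics without reflecting path geometry.
x(t) and y(t) are therefore Savitzky–Golay filtered (window 21 frames,
polynomial order 3) before metric extraction. The filter reproduces any
cubic exactly, so genuine curvature at that scale is untouched. The HMM
stage deliberately uses the **non-smoothed** series: smoothing correlates
neighbouring observations and would distort the emission distributions the
model estimates. The pipeline enforces this routing; both stages accept an
override flag.

**Zero-length steps.** A stationary frame has no movement direction. The
convention here: the heading is carried forward unchanged through the run,
the turning angle of a zero-length step is recorded as *missing* (NaN),
and the first step out of the run gets the full turn relative to the
carried heading. Recording zeros instead (a plausible alternative) injects
a point mass at angle 0 that measurably biases the fitted von Mises mean
toward zero, so missingness is the package convention; the zero-mass
emission model evaluates only the step part at such frames.

**Gaps.** Detection gaps of ≤ 5 frames are filled by linear interpolation
of x and y (the hidden-state machinery needs contiguous series); longer
gaps split the video into independent sub-sequences. The threshold is a
pragmatic choice — a sixth of a second of interpolated travel is benign at
these frame rates.

## The 16 movement metrics

Per video: min/max/mean/SD of speed (L_t·fps), of acceleration (first
difference of speed times fps), and of |φ_t|; mean directional
autocorrelation; eMaxA and eMaxB; corrected sinuosity.

- Angle summaries use magnitudes by default. Signed angles are symmetric
  about zero for any swimmer without a turning bias, so their min/mean
  carry no information; magnitudes quantify angularity. A
  `signed_angles` toggle restores signed summaries.
- Directional autocorrelation: C(d) = mean_t cos(h_{t+d} − h_t), averaged
  over lags d = 1..max_lag, with max_lag defaulting to ⌊n/4⌋ of the
  heading count. The first-local-minimum convention used by some toolkits
  is available via `mode="first_min"`.
- eMaxA = b/(1−b) with b the mean cosine of turning angles; a perfectly
  straight path returns +inf (sentinel, propagated honestly). eMaxB
  multiplies by the mean step length, giving body lengths.
- Sinuosity2 = 2·[p̄((1+c)/(1−c) + b²)]^(−1/2) with p̄ the mean step, c the
  mean cosine of turning angles, b the coefficient of variation of step
  length. Decreasing in c; → 0 for straight paths.

## Ethospace and linear models

The video × metric matrix is z-scored column-wise (sample SD, n−1;
zero-variance columns are dropped with a warning) and ordinated by PCA via
eigendecomposition of the covariance of the z-scored matrix. Eigenvector
signs are fixed by making each component's largest-magnitude loading
positive. Per-metric contributions are squared loadings scaled to 100% per
component.

Group structure uses *data ellipses*: the 95% ellipse of a group's PC1–PC2
scores is its score covariance scaled by the χ²(2 df, 0.95) quantile. The
reported verdict is whether each group's mean score falls inside the other
group's ellipse — an overlap heuristic, not a formal test (no PERMANOVA is
attempted). Groups with < 3 videos get no ellipse and a null verdict.
Standard-error-of-mean ellipses can be had by scaling the covariance by
1/n before construction.

Each metric is separately regressed on the binary human-presence indicator
by OLS. With one binary predictor, the slope is the between-group mean
difference, the intercept the absence-group mean, df = (1, n−2), and
F = t². A metric constant across all videos is reported as a null
relationship (t = 0, p = 1, R² = 0) rather than a 0/0 artifact.

## The covariate hidden Markov model

Observations are the pooled step/angle series of all videos, treated as
independent sequences sharing one parameter set. Per hidden state k:

- step: 0 with probability ζ_k, else Gamma with mean μ_k and SD σ_k
  (shape μ²/σ², rate μ/σ²);
- angle: von Mises(θ_k, κ_k); κ = 0 degenerates to uniform; missing angles
  (sequence starts, zero steps) contribute only the step part.

Transitions follow a multinomial logit with the diagonal as reference:
η_ij = β0_ij + β1_ij·c for j ≠ i, η_ii = 0, rows softmaxed. The covariate
c is constant within a video (with- and without-swimmer videos are separate
recordings). One shared initial distribution δ_init (K−1 free parameters)
covers all sequences — standard practice for pooled independent tracks.

Free parameters: 5K + 2K(K−1) + (K−1) with the covariate (29 at K = 3),
5K + K(K−1) + (K−1) without (23 at K = 3). AIC = −2LL + 2·#params.

**Likelihood and gradient.** The exact likelihood comes from the scaled
forward recursion (normalized-alpha form, running log of the normalizers),
implemented as a numba kernel over the concatenated sequences; per-state
emission log-densities are precomputed vectorised. The score is exact, via
Fisher's identity: one forward–backward pass yields posterior state and
transition-pair probabilities, and the gradient of the marginal likelihood
is the posterior expectation of the complete-data score. This makes each
quasi-Newton iteration cost one forward–backward pass rather than ~p
likelihood evaluations.

**Optimisation.** L-BFGS-B on transformed parameters — log for μ, σ, κ;
logit for ζ and δ_init; identity for β and θ — with wide box bounds that
serve only to keep the exponentials finite. Convergence tolerance 1e-8 on
the relative objective change; up to 1000 iterations per start. 75 random
starts (the study's protocol) are drawn inside data-driven plausible
ranges: μ and σ log-uniform between the 10th and 90th percentiles of the
nonzero step lengths, κ log-uniform on [0.01, 20], θ uniform on (−π, π],
β0 uniform on [−5, 0] (sticky chains), β1 uniform on [−2, 2]; ζ always
starts at the pooled observed zero-step proportion. The best-likelihood
converged start wins. Fitted states are canonicalized by ascending μ, which
resolves label switching deterministically.

**Inference.** The observed information is the finite-difference Jacobian
of the exact gradient at the optimum (step 1e-5, symmetrized). Its
pseudo-inverse — eigenvalues floored at 1e-12 — is the working-scale
parameter covariance; near-flat directions (θ of a nearly uniform-angle
state, ζ of a state that emitted no zeros) then yield honestly large
standard errors instead of failures. Natural-scale emission SEs follow by
the delta method. Wald z-tests on the β1 coefficients quantify the human
effect per transition: the transition model *is* a multinomial-logit
regression of the next state on the covariate, so its embedded
coefficients are tested directly (a post-hoc regression on decoded
transitions would ignore decoding uncertainty).

**Stationary occupancy.** δ solves δΓ(c) = δ, Σδ = 1 (least-squares on the
rank-checked linear system; a numerically reducible Γ raises). 95% CIs by
parametric bootstrap (B = 500, seeded): β is resampled from its asymptotic
normal, δ recomputed per draw, percentiles taken. The bootstrap respects
the simplex constraint, which a delta-method interval does not.

## The synthetic testbed

`whale_shark_preset()` encodes the study conditions: 39 sequences (20 with
swimmer), lengths uniform on [167, 1121] frames, 30 fps, and the three
fitted emission states (μ, σ, θ, κ, ζ as estimated from the field
footage). The transition coefficients were never published, so the preset
uses synthetic defaults chosen once: off-diagonal intercepts −2.2 (sticky
chain, mean dwell ≈ 10 frames) and covariate effects that raise entry into
and lower exit from the fast erratic state, reproducing the study's
qualitative finding that human presence raises that state's long-run
occupancy. The effect size was not calibrated to the study (it could not
be); recovery tests therefore validate the estimator against the preset's
own truth, not the field data.

The simulator draws the hidden chain, emits steps and angles, and
integrates a correlated random walk (initial position at origin, initial
heading uniform — irrelevant by rigid-motion invariance). It does not
emulate: pose-tracker detection noise or identity switches, head-yaw
oscillation (so smoothing is exercised only mechanically, not against its
motivating artifact), frame gaps, within-video covariate switching (the
study design has none), or behavioural heterogeneity between individuals
beyond what hidden states express. Passing recovery tests shows the
estimator is correct and well-calibrated under the model; it cannot show
the model is adequate for any particular piece of footage.

## Problem sizes in the checks

The statistical checks run at sizes chosen for tight asymptotics at
desk-scale cost: parameter recovery at the full study design (39
sequences, 75 starts); AIC order selection on 20 replicates of 6
sequences × 120–240 frames with 10 starts per model order; Wald type-I
calibration on 500 replicates of a well-separated two-state design (6
sequences × 200 steps, no true effect, 3 starts), expecting a 5% ± 2%
flag rate; forward-algorithm exactness against exhaustive path enumeration
at K ≤ 3, T ≤ 8 (tolerance 1e-10).

## Known limitations

- Lengths stay in body-length or pixel units; no pixel-to-metre scale is
  assumed at any altitude.
- No continuous-time HMM, no position-level state-space smoothing, no
  random effects across individuals; individual variation enters through
  per-video sequences and hidden states only.
- Wald tests are asymptotic; at few videos or rare transitions their
  calibration degrades (the type-I check quantifies this at one design).
- The ellipse-overlap verdict is a visual heuristic inherited from the
  ordination tradition, not a hypothesis test.
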