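# Methods

## Model

Each of the `P` cortical parcels (46 in the study atlas) carries three
population states — excitatory `h_E`, inhibitory `h_I`, and a slow
adaptation variable `h_A`, all confined to [0, 1] — and the whole cortex
carries one recurrent network state `h_net` with a component per canonical
large-scale system (DMN, TPN, SN, Other).  The excitatory population of
parcel *i* receives five inputs: the observed activity `x_t`, top-down
network feedback `W_out h_net`, recurrent excitation `W_EE h_E`, recurrent
inhibition `W_IE h_I`, and subtractive adaptation `−β h_A`:

    I_E(t)   = x_t + W_out h_net(t−1) + W_EE h_E(t) + W_IE h_I(t) − β h_A(t)
    h_E(t+1) = h_E + (dt/τ_E) (−h_E + σ(I_E))
    h_I(t+1) = h_I + (dt/τ_I) (−h_I + σ(W_EI h_E))
    h_A(t+1) = h_A + (dt/τ_A) (−h_A + h_E)
    h_net(t) = tanh(W_in x_t + W_net h_net(t−1) + b_net)

`σ` is the logistic sigmoid; `W_in` (4×46) is the fixed row-normalized
membership projection, so a network component is the mean of its member
parcels; `W_out` is the membership indicator scaled by one learnable
non-negative gain per network.  `W_net` (4×4) is the quantity of interest:
entry (i, j) is the signed, directed influence of network *j* on network
*i*.  The observation model is a per-parcel learnable affine readout of
`h_E` (`gain · h_E + offset`); series are z-scored per parcel (training-
split statistics only) before fitting so the readout starts near identity.

Discretization is forward Euler with `dt` = 1 sample = 1 ms (1000 Hz
acquisition).  With `dt/τ ≤ 1` every population update is a convex
combination of the current state and a bounded target, which yields the
boundedness invariant checked in the tests.

Constraints (enforced by hard projection after every optimizer update, so
they hold exactly at all times, not just at convergence):

- sign constraints on the couplings: `W_EE, W_EI ≥ 0`, `W_IE ≤ 0`
  (a population excites or inhibits, never both);
- time constants clipped to physiological ranges: τ_E ∈ [5, 30] ms,
  τ_I ∈ [10, 100] ms, τ_A ∈ [50, 500] ms; inhibitory kinetics are
  initialized slower than excitatory ones;
- sparsity masks restrict each parcel-level matrix to 30% of possible
  connections (diagonal always retained).  When parcel centroid
  coordinates are available, off-diagonal retention probability decays
  exponentially with distance (decay constant = median distance / 4), and
  the mask seed is fixed so the anatomical scaffold is a property of the
  atlas, shared by every model fitted to it.

## Training

The objective is mean squared one-step prediction error plus a biological
penalty `R_bio` weighted by `bio_lambda` (default 1):

    R_bio = Σ min(W_EE, 0)² + Σ min(W_EI, 0)² + Σ max(W_IE, 0)²
          + Σ (τ-range excursions)²
          + l1_lambda (‖W_EE‖₁ + ‖W_EI‖₁ + ‖W_IE‖₁ + ‖W_net‖₁)

After projection the sign and τ terms are exactly zero, so in practice the
penalty reduces to the L1 sparsity prior (`l1_lambda` = 0.001).

Optimization is AdamW (decoupled weight decay 1e-5, learning rate 5e-4,
plateau-driven learning-rate decay by 0.8, early stopping on the
validation MSE with best-state restore).  The validation segment is the
chronological final 20% of the series, which avoids leakage through
temporal autocorrelation.  Gradients are computed analytically by
backpropagation through the unrolled dynamics over truncated windows
(default 200 samples); the forward/backward passes are numba-compiled, and
the test suite verifies every parameter's gradient against central finite
differences at 1e-4 relative tolerance.

The network-coupling matrix is warm-started from a lag-1 linear
autoregression of the network-aggregated training series, rescaled to a
maximum magnitude of 0.5 (`TrainingConfig.wnet_warm_scale`; 0 starts from
zeros).  The linear estimate's coefficient magnitudes are poor but its
signed pattern is informative, and a system-identification warm start is
standard practice; the constrained fit refines it freely.

Windows are processed chronologically with carried-over state (classic
truncated BPTT).  A seed-shuffled variant, with window initial states
cached from a whole-series pass at the top of each epoch, is available as
`TrainingConfig.shuffle_windows=True`; the two performed equivalently in
our recovery studies and the chronological form is the default because it
carries state exactly rather than approximately.

"Improvement" for both the scheduler and early stopping means a relative
validation-MSE decrease greater than 1e-4.

### Desk-scale study sizes

The reference recording is minutes long; the packaged studies use 4 s
series (T = 4000).  An epoch over a 4 s series contains ~31 window updates
versus ~1200 for a full-length recording, so epoch-denominated budgets are
scaled to keep the total number of optimizer updates comparable: the
recovery studies run up to 1000 epochs of 100-sample windows with
early-stop/scheduler patience 60/45.  `TrainingConfig` *defaults* keep the
reference values (150 epochs, patiences 20/15, window 200).  One subject
fits in roughly a minute on one CPU.

## Synthetic cohorts

The generator rolls the model's own dynamics forward under known
parameters, closing the loop through the observation readout: at each
step the observation `x_t = gain · h_E + offset + ε_t` (white Gaussian
noise, SD 0.2 by default) is fed back as the model input, so the data
carries exactly the temporal dependence the model assumes.  An exogenous
1/f ("pink") drive is available by configuration.  The first 500 samples
(initial transient) are discarded.

Getting informative data out of a closed-loop nonlinear system required
deliberate regime placement, all fixed ahead of the packaged studies:

- **Oscillatory operating point.**  Row-sum targets for the parcel
  couplings (`s_ee`=5, `s_ei`=2, `s_ie`=2.7 in the generator's units,
  with the readout feedback contributing ~3 more units of effective
  self-excitation) and adaptation strength β=4 balance the excitatory
  drive against inhibition and adaptation near the sigmoid's steep
  region.  Per-entry (rather than per-row) weight normalization leaves
  realistic degree heterogeneity across parcels; the high-in-degree
  parcels act as pacemakers that keep the relaxation oscillation alive
  (a homogeneous network at the same mean coupling settles into a stable
  fixed point).  Adaptation timescales τ_A ∈ [60, 120] ms set oscillation
  periods of a few hundred ms.
- **Centered observations.**  The readout offset is calibrated to the
  noise-free operating point (damped fixed-point iteration), so simulated
  observations are zero-mean with O(1) variance and standardization before
  fitting is a mild rescaling rather than a regime change.
- **Anatomical scaffold.**  Parcels are embedded on a unit sphere in four
  network clusters (tetrahedron vertices plus jitter); the resulting
  distance matrix drives the sparsity masks of both the generator and the
  fitted models.  Because couplings are predominantly within-network,
  cross-network interaction is only expressible through the network
  channel — which is what makes the planted `W_net` identifiable rather
  than absorbable into the parcel matrices.
- **Validity vetting.**  A parameter draw whose probe simulation leaves
  any network's activity at the observation-noise floor is rejected and
  redrawn (bounded attempts, deterministic given the seed).  A "dead"
  network contributes no signal and its couplings are unidentifiable in
  principle; vetting ensures every generated subject exercises all 16
  couplings.

Condition templates plant six strong couplings (|w| ≥ 1, zero elsewhere,
plus N(0, 0.2²) per-subject jitter on every cell): salience-network
facilitation of both other systems, task-positive inhibition of the
default-mode network that is stronger at rest, and a task-vs-rest sign
flip of the DMN→SN coupling.  These mirror the qualitative pattern the
method is designed to resolve; magnitudes are template choices on the
order of reported group means, not reproduction targets.

The covariate generator emulates a 16-item, 1–5 scale imagery-vividness
questionnaire (totals 16–80): scores are an affine map of the
standardized coupling values mixed with independent noise to achieve a
target correlation, then rounded and clipped.

**What the generator does not emulate:** volume conduction and sensor
mixing, inverse-solution leakage between parcels, 1/f and line noise,
artifacts, nonstationarity across recording blocks, and any mismatch
between the neural-mass model class and real cortical dynamics.  Passing
recovery tests therefore show that the estimation machinery works when
the generative assumptions hold — a necessary condition — not that real
EEG yields couplings of this fidelity.

## Group statistics

Per-connection one-sample t-tests across subjects (two-sided, against
zero) with Benjamini–Hochberg step-up FDR correction within each
condition's family of 16 tests (12 for the Granger baseline, whose
diagonal is undefined); discoveries flagged at q < 0.05.  Zero-variance
cells: all-zero samples give t = 0, p = 1; identical nonzero samples are
flagged degenerate with p at its limit 0.  The covariate analysis defaults
to a rank-based association (Spearman r and its p-value, variance
explained by a monotone isotonic fit), with ordinary least squares
available; family correction uses the Hochberg step-up procedure.

## Granger baseline

For each ordered network pair and each lag k ∈ 1..10, the target is
regressed on its own k lags (restricted) and additionally on the source's
k lags (full), both with intercepts and both using the last T − k samples,
and the joint lagged-source contribution is F-tested with
(k, n − 2k − 1) degrees of freedom, n = T − k.  The lag minimizing the
p-value is selected per pair — reproducing the baseline as specified,
including its uncorrected selection over lags (per-lag p-values can be
retained by flag).  F statistics are unsigned by construction, which is
exactly the contrast with the constrained model: the baseline detects the
strong TPN→DMN dependence but cannot reveal that it is inhibitory.

## Numerical choices

- Logistic sigmoid evaluated in a branch-stable form (no overflow for
  |x| up to the float range).
- All randomness flows through `numpy.random.SeedSequence` derivations of
  a single seed; every generator and fit is a pure function of its seed,
  and training is bitwise reproducible given (data, config).
- Ties in distance-weighted mask sampling are resolved by the seeded RNG.
- Standardization guards against zero variance with a 1e-8 floor.
- Divergence (non-finite states or loss) raises immediately with the
  time/epoch index rather than propagating NaNs.

## Known limitations

- Recovered coupling magnitudes are shrunken relative to the planted
  values (L1 plus finite optimization budgets); sign patterns and
  relative magnitudes are the reliable output, mirrored in the recovery
  metrics (sign agreement and correlation rather than absolute error).
- The one-step-prediction objective admits a near-degenerate solution in
  which an amplified memoryless network projection substitutes for the
  recurrent coupling; the anatomical scaffold and study lengths were
  chosen so this basin is distinguishable, but individual fits can still
  land in it, which is why recovery is assessed at cohort level.
- The Granger baseline's minimum-p lag selection inflates its type-I
  error across lags; calibration is therefore checked at fixed lag.
- Subject-level fits are independent; no hierarchical pooling.
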