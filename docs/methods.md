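# Methods

This note documents the models implemented in `wearbci`, the defaults
chosen where the underlying procedures leave the design open, what the
synthetic data emulate, and the package's known limitations.

## Preprocessing (`signal_core`)

All filters are **causal IIR Butterworth** filters applied with
`scipy.signal.sosfilt`. Zero-phase (forward–backward) filtering would be
acausal and is deliberately not used: both decoders have a real-time
contract, and offline analyses should see the same transients the live
system does. The `order` argument always names the overall filter order
(`butter` doubles the order for band-pass/band-stop designs, which the
implementation accounts for).

* **Notch**: 4th-order band-stop at 50 ± 2 Hz. The mains frequency and
  order are fixed by the deployment; the ±2 Hz bandwidth is a design
  choice — narrow enough to leave beta-band content untouched, wide enough
  to attenuate the steady-state mains tone by well over 40 dB.
* **Band-pass**: 4th-order by default. Engagement filter bank 4–8, 6–10,
  8–12 Hz (overlapping on purpose — the bank stays below frequencies where
  muscle artifacts from task-related tension dominate); broadband prefilter
  0.5–40 Hz for the grid system.
* **Bad channels**: a channel is flagged when, in any 10-s block, its peak
  amplitude exceeds 200 µV (railing/motion) or its standard deviation
  falls below 0.1 µV (flat-lined/disconnected). This is a documented
  heuristic stand-in for proprietary online signal-quality scoring;
  deterministic and order-invariant by construction. Flagged channels are
  re-referenced but excluded from the common average and from all
  downstream features.
* **Common average reference**: subtracts the per-sample mean of the good
  channels from every channel, so the included-channel mean is 0 at every
  sample (checked to 1e-9 of the input scale).
* **Segmentation**: non-overlapping 1-s windows, half-open intervals
  `[start, end)`, 0-based samples, trailing partial windows dropped,
  labels constant within an interval.

## Engagement decoder (`engagement`)

Covariances for CSP are estimated per 1-s window, normalised by trace (so
every window contributes equally regardless of amplitude), averaged per
class, and shrunk by λ = 0.05 toward the scaled identity. The shrinkage is
necessary: a 4-channel covariance from 250 samples is noisy, and the
generalized eigenproblem `C_a v = λ (C_a + C_b) v` needs a well-conditioned
composite. Filters are the `n_pairs` top and bottom generalized
eigenvectors, normalised so `W (C_a + C_b) Wᵀ = I`.

* **`n_pairs` = 1** by default: four channels admit at most four filters,
  and one pair per band across three bands already gives six features for
  240 training windows.
* **Variance floor** ε = 1e-12 before the log, so silent windows produce
  finite features.
* **LDA** is the two-class closed form `w = S⁻¹(µ₊ − µ₋)` with the bias
  midway between the projected class means (equal priors — the calibration
  protocol is balanced by design, and the boundary should not drift with
  accidental class imbalance). Pooled covariance gets a relative diagonal
  loading of 1e-4. Engaged windows score positive; ties at 0 are labelled
  engaged (documented convention).
* **Score scaling**: raw LDA scores are divided by the 95th percentile of
  the absolute training scores, multiplied by 10 and clipped to ±10. The
  display layer assumes a −10..+10 range; the 95th percentile (rather than
  the max) keeps a single outlier window from compressing the whole scale.
* **Calibration protocol**: two 1-min task blocks interleaved with two
  1-min rest blocks — 4 min and 240 training windows in total.

Scores are antisymmetric under swapping the class labels of the training
data (a property test verifies this), and CSP agrees with a dense
generalized-eigendecomposition oracle on random window sets up to sign.

## Band-power decoder (`bandpower`)

The per-channel power estimate is the **mean of squared band-passed
samples over a trailing 256-sample buffer**, emitted every
256 − 128 = 128 samples — a moving average of instantaneous power. At
256 Hz this yields frames at exactly 2 Hz; the frame count for any valid
configuration is `floor((n − N_buffer)/(N_buffer − N_overlap)) + 1`. Log
transform after averaging (band powers are roughly χ²-distributed;
the log improves Gaussianity), floored at 1e-12.

Aggregation order is: channel power → mean log power per grid (over the
grid's good channels) → region-weighted mean across grids. The per-grid
statistic being the channel mean, and the weighting applying to log powers,
are design choices; the weights themselves (frontal θ×2, occipital α×2,
pre/postcentral β×2, all else 1) encode which cortex most informs each
rhythm.

* **Minimum-power threshold**: the 90th percentile of each band's weighted
  score over a 60-s idle baseline (`BandPowerStateDecoder.fit`). No
  absolute threshold generalises across montages and skull anatomies, so
  the gate is calibrated per session; 90% keeps idle frames from
  triggering patterns while a genuine band elevation clears it easily.
* **Decision**: if no band clears its threshold the target state is idle,
  else the band with the highest score; ties break θ > α > β (fixed,
  arbitrary, documented).
* **Dwell**: every newly entered state — idle included — is locked for
  6 s; frames arriving during the lock are ignored for switching. The lock
  starting at state entry matches a system that re-evaluates only after
  performing a pattern, and makes the "transitions ≥ 6 s apart" guarantee
  unconditional (a property test drives the machine with adversarial
  random score streams).
* **Task-battery evaluation** (`run_task_battery`) scores the decoder
  itself: per 1-s segment, the argmax of the mean frame scores, without
  the dwell lock and (by default) without the power gate, which belong to
  the live actuation layer. Segment confusion matrices are row-normalised
  percentages.

The default montage is 64 grids × 16 electrodes = 1,024 channels; grids
are assigned regionally in blocks (16 frontal, 12 occipital, 8 precentral,
8 postcentral, 20 other), overridable via `default_uhd_montage`.

## Permutation statistics (`stats`)

Shuffles are uniform permutations of the label vector; accuracy is the
fraction of matching segments, with no class-balance correction. The
p-value uses the add-one rule `p = (#(Acc_perm ≥ Acc_obs) + 1)/(B + 1)`,
bounded in `[1/(B+1), 1]` and invariant under consistent relabeling.
Uniform shuffling ignores the autocorrelation of consecutive 1-s EEG
segments — a known limitation (block permutation would be more
conservative; it is out of scope here because the procedure under test is
the uniform shuffle).

`chance_level` reports the mean permutation accuracy; when no predictions
are supplied, the labels themselves stand in, so the estimate converges to
`Σᵢ pᵢ²` over class frequencies (1/k balanced — 50% / 33% for the two
deployed designs, 82% for a 90/10 split).

Score densities use a Gaussian kernel whose standard deviation equals the
requested width (1 score unit by default). Note the kernel widens the
estimate: a standard-normal sample with width 1 peaks near
1/√(4π) ≈ 0.282, not 1/√(2π).

## Actuation (`actuation`)

Eye mapping defaults: P₀ = 0.5 (neutral pupil in normalised display
units), M₀ = 0 (centred), α = 0.04 and β = 0.05 per score unit — chosen so
the full ±10 score range spans most of, but never leaves, the display-safe
ranges [0, 1] and [−1, 1]. Positive scores additionally set a horizontal
oscillation frequency of 0.2 Hz per score unit. The mapping is affine by
design; nonlinear mappings are possible in principle but not implemented.

Pattern tempos quantify qualitative choreography: theta sweeps one scale
level per 0.4 s (bottom-up, then reversed), the alpha wave travels at
0.2 s per scale from one lower hem over the shoulders to the opposite hem,
beta jumps every scale to 60° and returns after 0.5 s with a 0.1-s white
flicker, idle returns all servos to their default angle with LEDs off.
Servo angles are validated to [0°, 90°]; compiled programs are
deterministic, time-sorted, and exactly left/right mirror-symmetric for
beta. Default angles and LED brightness are hardware details exposed as
configuration.

## Synthetic EEG (`synth`)

Each state is a spectral recipe: per-band oscillation amplitudes (scalar,
per region, or per channel), pink-noise standard deviation (default 5 µV,
1/f exponent 1.0), and an optional common 50 Hz component. Oscillations
are **amplitude-stable sinusoids at the band centre whose phase
random-walks** at 1.0 rad²/s. The phase diffusion matters: a phase fixed
per block imprints a stable block-specific cross-channel covariance
(cov ∝ cos Δφ) that a CSP+LDA pipeline learns *instead of* the intended
band-power contrast — with fixed phases the decoder reached 100% training
accuracy on sessions with zero effect and its evaluation output flipped
sign on some seeds. Diffusing phases keep channels decorrelated within a
block while the signal stays band-limited (Lorentzian linewidth well under
1 Hz) and its per-window variance stays A²/2.

The engagement session follows the deployed protocol: four alternating
1-min calibration blocks plus an identically structured evaluation run
(240 segments, 120 per class). The engaged state adds a 6–10 Hz
oscillation of amplitude `effect_size × 5 µV` on two of the four channels
over a shared 8 µV occipital alpha background. `effect_size` is an honest
knob: 0 is indistinguishable from rest (decoding sits at chance), the
default 2 yields ≈95% mean held-out accuracy, and 4 decodes at >90% on
every seed tested. The task battery interleaves 1-min trials of three
states, each raising its namesake band to 12 µV against a 4 µV background.

What the generator does **not** emulate: volume conduction and realistic
spatial covariance, eye-blink/EMG artifacts, non-stationary band power
within a state, inter-subject variability. Passing tests therefore
demonstrate that the pipelines recover the structure they are designed
for under controlled SNR — not field performance on real scalp EEG.

## Problem sizes in the test suite

Tests and the acceptance script run on desk-scale inputs: the engagement
chain uses the full 8-min, 4-channel session; grid-system tests use a
scaled-down montage (8 grids × 4 channels) with 2–3 trials of 30–60 s per
state, since the statistical structure under test is independent of the
channel count; the chance-level computations use the full label sets (240
and 3,600 segments, B = 10,000). The full 1,024-channel, 60-minute battery
is supported by the same code paths but is not exercised wholesale in the
suite.

## Known limitations

* EDF files can be read (via mne) but not written; the lossless on-disk
  format is CSV + JSON sidecar.
* The bad-channel heuristic is a stand-in; real deployments use richer
  impedance/spectral quality measures.
* Uniform label shuffling overstates significance on autocorrelated
  segments (see above).
* Single-subject calibration only; no cross-subject transfer.
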