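# Methods

`smrnf` simulates and analyses a single-session, sham-controlled SMR
neurofeedback experiment end to end. This note records the models, the
numerical choices, and what the synthetic data can and cannot establish.

## Study structure being simulated

Each subject contributes one baseline run and six feedback runs (default
3 min each at 256 Hz) on a 16-channel 10-20 montage (12 scalp electrodes,
3 EOG, two mastoids; Cz is the feedback site). Subjects fall in four cells:
visual paradigm (3D rolling ball vs. 2D bar) x feedback veracity (real vs.
sham). The trained band is SMR (12-15 Hz); Theta (4-7 Hz) and Beta
(16-30 Hz) act as artifact-control bands. The original cohort sizes
(13/15/17/16 per cell) are supported via `StudyDesign(n_per_cell={...})`;
the test suite uses smaller cells and shorter runs purely as a problem-size
choice.

## Synthetic EEG generator

The generator is deliberately minimal: every feature exists because some
pipeline stage must be able to detect or remove it.

- **Background**: spatially correlated 1/f^a noise (default a = 1), built by
  spectral shaping of white noise, flattened below 1 Hz. Each channel is
  `sqrt(c) * shared + sqrt(1-c) * private` with c = 0.3, scaled to 10 uV
  RMS (mastoids 2 uV, so the linked-mastoid conversion is near-neutral).
- **Oscillators**: narrowband sinusoids at each band's centre frequency with
  band-specific topographies (SMR peaks at Cz, Theta frontal, Beta
  diffuse). Default source amplitudes: SMR 3 uV, Theta 3 uV, Beta 2 uV.
- **Learning**: run r (1..6) multiplies the SMR source amplitude by
  `1 + slope * r`. The default 3D group slope is 0.025/run so SMR *power*
  grows about 5% per run ((1.025)^2 ~ 1.05); 2D defaults to 0. Per-subject
  slopes are normal around the group slope (SD 0.01/run); baseline
  amplitudes are log-normal (sigma 0.2). Theta/Beta run slopes exist as
  parameters but default to 0 — the drifts reported for those bands in real
  data have no stated mechanism, so the generator does not guess one.
- **Artifacts**: blinks are 400 ms half-sine transients, 150 uV peak on EOG
  and 90 uV frontally (realistic for frontal blink deflections), decaying
  towards posterior sites; muscle bursts are 500 ms Hann-tapered 20-40 Hz
  noise at 30 uV RMS with diffuse, randomly jittered gains. Event times are
  Poisson (defaults 4 blinks/min, 2 bursts/min) or fixed lists for exact
  tests; every event is logged with onset/duration as ground truth.
- **Determinism**: all draws descend from one seed through spawned child
  seeds, so any subject, session or study regenerates bitwise-identically;
  large studies are therefore generated lazily instead of stored.

What this generator does **not** emulate: volume conduction and realistic
forward-model topographies, non-Gaussian ongoing EEG, non-stationary
amplitude dynamics, eye movements other than blinks, electrode drift, or
line-noise harmonics. Consequences: ICA separation quality here is a lower
bound in one sense (Gaussian backgrounds are the hardest case for ICA) and
an upper bound in another (blink topography is exactly rank-one); passing
tests demonstrate that the pipeline's machinery is correct on data with the
assumed statistical structure, not that it would achieve the same numbers
on human EEG.

## Online feedback engine

Band power at Cz is estimated causally by complex demodulation: mix down at
the band centre, low-pass with an order-4 Butterworth applied twice forward
(cutoff as below), take `2 * |z|` as the in-band amplitude envelope, and
average `envelope^2 / 2` over a trailing window (default 1 s) at each
update tick (default 0.25 s). Applying the same order-4 filter twice
forward reproduces the magnitude response of the offline forward-backward
filter, so online and offline power agree on stationary input; only the
phase (latency) differs, which an envelope does not see. Ticks whose
window is not yet full are flagged as warm-up and excluded from
calibration.

Calibration uses the baseline run only: the SMR threshold is the mean
baseline SMR power; Theta and Beta thresholds are mean + 1 sample SD
(n-1). Gating per tick: if Theta or Beta strictly exceeds its threshold
the state is ARTIFACT (display frozen and shown red — artifact control
takes precedence over reward); otherwise MOVE iff SMR strictly exceeds its
threshold; otherwise STILL. Equality never triggers ("exceeds" is strict).

Display dynamics are numeric, not rendered: the ball adds
`speed * update_interval` distance per MOVE tick (default 1 unit/s); the
bar adds/subtracts one step per MOVE/STILL tick, freezes on ARTIFACT, and
is clamped to [0.05, 10] so it never vanishes. In sham mode the display is
gated on a donor subject's stream (deterministic seeded rotation pairs each
sham subject with a real-condition subject of the same group) while the
subject's own EEG is still recorded for offline analysis.

## Offline pipeline

1. **Filters** (zero-phase): 50 Hz notch (Q = 30), 1 Hz high-pass (order-4
   Butterworth), and a 40 Hz band limit realized as an order-6 Butterworth
   with -3 dB at 43 Hz. The shifted cutoff keeps the 2-38 Hz analysis band
   flat within 1 dB after the forward-backward pass and makes refiltering
   change 4-30 Hz band powers by well under 2%; line noise is attenuated
   > 20 dB by the notch.
2. **Linked-mastoid reference**: with data recorded against the left
   mastoid and the right-mastoid channel available, each channel becomes
   `x - M2/2`; mastoid channels are then dropped.
3. **ICA ocular correction**: extended Infomax (the standard choice for
   EEG) on the 12 scalp channels after PCA whitening; every component whose
   time course correlates with any EOG channel at |r| >= 0.7 is zeroed and
   the data back-projected. FastICA is available as an alternative; a
   failed unmixing passes the data through unchanged with a warning. Note
   the generator's source count exceeds the channel count, so a few percent
   of background power at Cz inevitably rides along the removed ocular
   component (measured ~9% of clean-second SMR power); this is a property
   of the data model, not of the correction.
4. **Rejection criteria**, applied per channel to the filtered data, all
   defaults as the study prescribes: voltage step > 50 uV per elapsed ms
   between adjacent samples (3.90625 ms at 256 Hz, so a 60 uV adjacent-
   sample jump is ~15 uV/ms and does *not* trigger); peak-to-peak range
   > 200 uV within a 1-s segment (the same segmentation used for power);
   absolute amplitude > 120 uV; range < 0.5 uV within a sliding 100 ms
   window (50% overlap). Provoking samples are dilated by 200 ms on each
   side. A naive per-sample reference implementation is kept in the package
   and must agree bitwise with the vectorized one (tested on hundreds of
   random signals).
5. **Band power**: zero-phase complex demodulation per band. The
   demodulation low-pass cutoff is half the band width scaled by the
   reciprocal of the filter's equivalent noise bandwidth (x1.114 for the
   order-4 forward-backward response), so a sinusoid of amplitude A in band
   reads A^2/2 *and* broadband noise reads the PSD integral over
   [f_lo, f_hi]. Without this calibration the estimator under-reads
   broadband power by ~10%; the cost is slightly wider skirts (a strong
   13.5 Hz SMR source leaks ~1.4 uV^2 into the Beta estimate).
6. **Aggregation**: non-overlapping 1-s segments aligned to run start
   (partial trailing segment discarded); a segment is rejected for a
   channel if any of its samples is masked; the run's value is the mean of
   per-segment mean power over surviving segments, with used/rejected
   counts carried along (a fully rejected run yields NaN, which the model
   stage drops).
7. **Outlier exclusion**: per band, a subject whose session-mean power at
   the feedback channel deviates >= 3 cohort SDs from the cohort mean (one
   pass, no iteration) is excluded for all bands. Session-level (not
   run-level) screening was chosen because exclusion is per subject. Note
   a single-pass 3 SD rule cannot fire for cohorts smaller than ~12 because
   the outlier inflates the SD it is judged against.

When ICA is disabled, the chain from filters to aggregation is strictly
per-channel, so the pipeline restricts itself to the requested channels
plus the mastoids — identical numbers at a fraction of the cost. The
simulation studies in the test suite use this fast path with a Cz-only
montage (the endpoint uses Cz only); ICA efficacy is validated separately
on the full montage.

## Statistical endpoint

For one band, per-run power at Cz over the six feedback runs is modelled
as

    y_ir = beta0 + beta_g g_i + beta_c c_i + beta_r r~ + (all interactions)
           + b0_i + b1_i r~ + e_ir,

with g (3D/2D) and c (real/sham) effect-coded +-1, r~ the run number
centred at 3.5, independent random intercept b0_i ~ N(0, s0^2) and random
run slope b1_i ~ N(0, s1^2) per subject ("crossed" subject and slope
effects read as the standard uncorrelated intercept + slope structure),
and residual e ~ N(0, s^2). No response transform is applied by default
(raw uV^2); a log option exists.

Estimation is REML, profiled over the two variance ratios and optimized
with bounded multi-start L-BFGS-B; ratios driven to the zero boundary are
reported as singular fits, not errors. Balanced designs use a single
shared covariance block per evaluation. Fixed effects are tested by a
sequential (Type I) ANOVA: hypothesis rows come from the triangular factor
of the fixed design's QR decomposition, which reduces exactly to ordinary
sequential ANOVA when the random-effect variances are zero. Denominator
degrees of freedom use the Satterthwaite approximation:
`nu = 2 var(l'beta)^2 / (g' A g)`, with g the gradient of the contrast
variance in the variance components (finite differences) and A the inverse
REML information from the numerical Hessian; components at the zero
boundary are held fixed. A plain residual-df method (`n - p`) is available
and is used automatically when the residual variance is exactly zero. The
implementation is cross-checked in the tests against R's lmerTest
(variance components, F, and denominator df agree to ~4 decimals) and
against statsmodels OLS sequential ANOVA in the zero-variance case.

Effect sizes are reported as partial eta squared via the standard
conversion `F df1 / (F df1 + df2)`. Per-group post-tests refit the model
without the group terms on each group's subset. Term order for the
sequential decomposition is main effects, two-way interactions, three-way
(configurable); with effect coding and balanced cells the order is nearly
immaterial.

A generative power-table simulator (`simulate_power_table`) draws directly
from this model (defaults: mu = 4.5 uV^2 matching a 3 uV SMR source,
intercept SD 2.0, slope SD 0.1, residual SD 0.5 — the EEG generator's
heterogeneity translated to the power scale for 60-s runs) for endpoint
calibration and power studies without simulating raw EEG. Under the null
(all slopes 0) the group x runs test rejects at close to the nominal 5%;
at the default effect (3D power growth ~5%/run) the full EEG pipeline
detects the interaction in well over 80% of replicates at 8 subjects per
cell with 60-s runs.

## Problem sizes and runtime

Simulation-heavy checks are scaled to desk hardware as the package's own
test-design choice: null calibration uses 500 power-table replicates at
15 subjects/cell; full-pipeline recovery uses 100 replicates of 8
subjects/cell with 60-s runs and a Cz-only montage; ICA efficacy uses 20
seeded 60-s runs on the full montage. `scripts/acceptance.py` re-runs the
same computations from scratch (60 recovery replicates) and writes the
measured quantities as JSON.

## Known limitations

- The generator's Gaussian background makes full ICA separation formally
  unidentifiable beyond the non-Gaussian (artifact) components; only the
  ocular component's identification and removal are meaningful.
- The online estimator is shared with the offline one by design; the
  original acquisition software's estimator is unspecified, so absolute
  threshold values are not comparable to the original hardware's.
- The voltage-step criterion normalizes per elapsed millisecond; software
  that interprets "50 uV/ms" as "50 uV between adjacent samples" will mask
  more aggressively.
- Manual inspection steps of the original offline workflow are replaced by
  the automatic criteria only.
- EDF export covers the 16-bit single-rate subset of the format (one
  record per second); annotations (EDF+) are not written.
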