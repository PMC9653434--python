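# Methods

This note documents the models, statistics and numerical choices behind
`obfeedback`, and what the synthetic-data generator does and does not
emulate.

## The circuit rate model (`obfeedback.model`)

The olfactory bulb's output neurons (mitral and tufted cells, treated as one
excitatory population MC) are reciprocally coupled to granule cells (GC),
the bulb's main inhibitory interneurons. GCs additionally receive inhibition
from deep short-axon cells (dSACs), which are not modelled as a dynamic
population: they enter as a constant drive SAC. Long-range GABAergic
feedback from olfactory cortex (FB) inhibits both populations and shunts
the dSAC→GC input. With unit time constants:

    dMC/dt = -MC + I - w·GC - w_fb·FB
    dGC/dt = -GC + w·MC - w_sac·SAC - 2·w_fb·FB

where `I` is the odor drive, `w = w_mc_gc` the reciprocal MC–GC coupling,
`w_sac = w_sac_gc`, and FB ∈ {0, 1}. Two structural constraints are baked
into `NetworkParams` rather than exposed as free parameters, because they
encode the circuit anatomy the model exists to test:

* the feedback onto GC is always `2·w_fb` (slice recordings show roughly
  twice-stronger feedback synapses on GCs);
* under feedback, `SAC = 0.1 / w_fb` — the residual dSAC drive shrinks with
  the inverse of the feedback strength, standing in for the (even stronger)
  feedback inhibition of dSACs themselves. The constant 0.1 is a fixed
  model constant; without feedback `SAC = 1`.

GC rates are rectified at zero (fixed points on the constrained branch have
`GC = 0`, `MC = I - w_fb·FB`); MC is left unconstrained but integration
warns if it goes negative. The Jacobian of the linear branch is
`[[-1, -w], [w, -1]]` with eigenvalues `-1 ± i·w`, so every real-weight
configuration is stable and the fixed point is unique; `integrate_dynamics`
(forward Euler, default `dt = 0.01` time units — comfortably inside the
stability region of a system whose fastest eigenvalue has real part −1)
converges to the same state that `solve_fixed_point` computes in closed
form. A divergence guard (default bound 1e6 rate units) exists for
defensive robustness, not because any reachable regime is unstable.

Sign convention: the GC nullcline is implemented as
`GC = max(0, w·MC - w_sac·SAC - 2·w_fb·FB)`, i.e. rising with MC, which is
what setting `dGC/dt = 0` in the GC rate equation yields (and what the
phase-plane geometry requires for the nullclines to cross as drawn).

`feedback_delta(params, w_fb)` is defined as `(0, 0)` at `w_fb = 0`, where
the shunting rule `SAC = 0.1/w_fb` is undefined — no stimulation, no
change. Both `solve_fixed_point` and `feedback_delta` accept
`rectify=False` to work on the unconstrained linear branch. This matters
for one quantitative statement: at the reference point
(`I = 10, w = 0.3, w_sac = 1`) the feedback-induced change grows strictly
in magnitude with `w_fb` on the linear branch, but the *rectified* GC
change saturates at `-GC_baseline` once `w_fb ≳ 1.27` (the with-feedback
fixed point hits the GC ≥ 0 floor; the roots of `2.3·w_fb² − 3·w_fb + 0.1`
delimit the positive-GC window). The strict-monotonicity checks therefore
run on the linear branch, with the rectified MC magnitude checked
alongside (it is strictly monotone in both cases).

Defaults `I = 10` and `w_sac_gc = 1` are arbitrary positive values; they
shift basal rates but not the slope of the nullclines, and are exposed in
the config.

## Two-photon pipeline (`obfeedback.imaging`)

Processing order: out-of-plane QC on the raw stack → rigid lateral
registration → 10-component PCA reconstruction → within-ROI PCA refinement
→ trace extraction → 5-frame smoothing → trial statistics. The PCA
reconstruction guides ROI refinement only; trace intensities always come
from the registered movie, never from the reconstruction.

* **Out-of-plane frames.** Each frame's zero-lag Pearson correlation with
  the average projection of the entire stack; frames at `r ≤ 0.65` are
  flagged not-kept. Zero-variance frames (undefined correlation) are
  flagged too. The correlation is evaluated at zero spatial lag — small
  lateral drift barely moves it, while a focal-plane jump collapses it.
* **Registration.** Per-frame integer translation against the average of
  kept frames, estimated by FFT cross-correlation *without* phase
  whitening (the phase-normalised variant is noticeably noise-sensitive at
  calcium-imaging SNR). Shifts beyond 10% of the frame size flag the frame
  instead of shifting it. Estimated corrections are defined up to the
  reference's global offset (a gauge freedom inherent to registration);
  drift-recovery tests therefore compare correction *differences* between
  movie segments.
* **PCA reconstruction.** The stack is reshaped to (time × pixels),
  mean-centred per pixel (centring choice: temporal mean, added back on
  reconstruction), and reconstructed from the top 10 components (fitted on
  kept frames, randomized SVD with a fixed internal random state). The
  operation is idempotent and exact on movies of rank ≤ 10.
* **ROI refinement.** A second PCA inside each manually drawn ROI (samples
  = time, features = pixels). Each of PCs 1–3 is weighted by its signal
  above the noise floor, estimated as the median singular value across all
  components — pure-noise directions then contribute nothing — and pixels
  whose combined weighted loading falls below 25% of the ROI maximum are
  dropped (threshold exposed in config; the choice of 25% is ours).
  Degenerate ROIs (no mode above ~2× the noise floor, or shrinking below
  3 px) keep their original mask with a warning.
* **Traces.** Mean over the mask per frame; not-kept frames are linearly
  interpolated between neighbouring kept frames so trial windows keep
  fixed sample counts. Smoothing is a centred 5-frame moving average with
  shrinking windows at the edges.
* **Windows.** Half-open 1-s intervals over frame-centre times
  `(index + 0.5)/rate`: baseline is the 1 s before the shutter closes,
  response starts 50 ms after it reopens (scan realignment time). Trials
  without shutter events use stimulus onset/offset.
* **The z statistic.** `z = (µ_resp − µ_base)/sqrt(s_resp²/n − s_base²/n)`
  with sample SDs (n−1), exactly as defined — including the minus sign in
  the radicand, which is likely a typographical variant of the two-sample
  form. When the radicand is non-positive, `z` is NaN and the conventional
  pooled `+` form (`z_pooled`) is reported alongside; a zero numerator
  reports `z = 0` regardless. Nothing downstream depends on this
  convention: significance labels come from a two-sided paired t-test on
  per-trial differences (α = 0.01 for light responses, α = 0.05 for odor
  responsiveness), with degenerate conventions p = 1 for identically zero
  differences and p = 0 for zero-variance nonzero-mean differences.

## Photometry pipeline (`obfeedback.photometry`)

Signals (fluorescence and co-recorded reflected excitation light) are
smoothed with a 0.02-s boxcar and downsampled to 500 Hz by bin averaging
(the boxcar provides the anti-aliasing; no additional filter). Per-trial
ΔF/F uses F0 = mean fluorescence in the 2 s before odor onset; trials with
F0 ≤ 0 are dropped with a log message. Sessions whose reflected-light
channel changes by strictly more than 1% ΔF/F (mean absolute change over
stimulation windows — polarity unspecified, hence the absolute value) are
discarded; a missing reflection channel marks the session "unverified"
rather than silently passing. The net light impact is the mean ΔF/F during
the 1-s light window minus the mean over the 1 s immediately before it,
per trial; the same latencies applied to no-light trials give the
comparable null impacts, and a shifted window gives the post-offset
analysis.

## Population statistics (`obfeedback.popstats`)

Population vectors hold the averaged responses of qualifying cells for one
odor condition; the separation measure is the Euclidean distance
`d(p,q) = sqrt((p−q)(p−q)')`. Designs:

* **between odors** — one vector per odor over cells responsive to *both*
  odors (α = 0.05 rule, computed upstream on all odor trials);
* **within odor** — two vectors from a split of the same odor's trials
  over cells responsive to that odor. The split is odd/even trial order by
  default (deterministic and exchangeable); a seeded random split is the
  alternative strategy. Distances are not normalised by cell count.

Sessions enter only with ≥ 5 qualifying cells (threshold exact: 4 is
excluded, 5 included), applied per odor for the within design and on the
dual-responsive set for the between design; exclusions are recorded with
counts and reasons. `distance_analysis` embeds no statistical verdict —
`compare_conditions` pairs per-session distances across conditions and
applies a two-sided paired t-test downstream.

Because the Euclidean distance is translation invariant, a uniform
("common-mode") subtraction of the same offset from both vectors leaves
their distance exactly unchanged — this is the formal content of the
observation that a linear subtraction of odor responses does not alter
within-odor separation, while a decorrelating shift (vectors pushed apart
along their difference) increases between-odor separation.
`linear_subtraction_fit` quantifies which regime holds: OLS of odor+light
on odor-only responses with 95% CIs, plus the correlation between the
light effect and the odor-response magnitude (≈ 0 for pure subtraction,
slope < 1 for divisive scaling).

## Synthetic data (`obfeedback.synth`)

The generator produces ground-truth-labelled inputs with the statistical
structure the analyses assume. Everything is deterministic under a seed.

**Protocols.** The two-photon preset: 8 s baseline, 2 s stimulation, 10 s
inter-trial interval, blocks of 20 trials at 15 Hz, stimulus order
shuffled within block, shutter closing/reopening 50 ms around light
windows. The photometry preset: 5-s odors every 60 s, a 1-s light pulse
3.5 s after odor onset on light trials, 10 repetitions per condition at
5 kHz.

**Movies.** Hard-edged Gaussian somata (the tail below 0.3 of the peak is
cut — indicator-filled cell bodies have crisp boundaries) on a constant
background plus a static smooth neuropil-like texture (Gaussian random
field, 12-px correlation length, amplitude 8 intensity units) and i.i.d.
Gaussian pixel noise (σ = 3). Each cell has a tonic fluorescence level
(20–40 units) and spontaneous transients (≥ 3 per cell; rate 0.06 Hz,
amplitudes 8–20) convolved with a double-exponential indicator kernel
(0.1-s rise, 1-s decay — literature-informed slow-indicator values, not
measured ones). "Excited" cells add a stimulus-locked transient (peak 40;
only its decay tail is visible after the shutter reopens, so the peak must
be large); "inhibited" cells lose 60% of their tonic component during
stimulation + 1 s. Optional corruptions, all recorded in the ground truth:
lateral drift applied to the trailing 40% of frames (the undrifted
position must dominate the stack average for the registration reference to
be well posed) and out-of-plane frames replaced by uncorrelated noise.
The default field is 128×128 px — a scaled-down stand-in for the 512-px
acquisition so tests run in seconds; unit tests scale further (64×64,
12 cells, shortened trial segments).

**Trace sets.** Direct per-trial window-mean fixtures for statistic
calibration: baseline and response means are independent normal draws
(σ = 1) with per-cell mean shifts. Defaults: 20 trials per condition (one
block), inhibited/excited effects ∓1.5 in window-SD units — chosen so the
paired t-test at α = 0.01 has a theoretical power of ≈ 0.96 (noncentral-t
with ncp = 1.5·√(20/2) ≈ 4.74).

**Photometry sessions.** Odor trials evoke a plateau ΔF/F transient
(amplitude 0.05, 0.5-s rise, 1-s post-odor decay); on light trials the
odor-evoked component is multiplied by (1 − s) during the light window,
with s cycling through the configured suppression levels. The reflection
channel is flat except for an optional injected artifact step (percent of
baseline) during light windows.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: photon shot noise scaling with intensity,
slow drift in baseline fluorescence or bleaching, neuropil contamination
with its own temporal structure, non-rigid or sub-pixel motion, correlated
network activity between cells, respiration- or sniff-locked dynamics, and
hemodynamic artifacts in photometry. Recovery results bound what the
pipeline can do under its own assumptions; they are not field performance
claims.

## Problem sizes in the checks

The acceptance script and end-to-end tests use: 200 random parameter sets
for the model oracle; a 20×20 parameter grid for nullcline residuals; 1000
null and 400 inhibited synthetic cells for classifier calibration; an
8-trial, 2400-frame 128×128 movie for image-pipeline recovery; and 4-level
suppression over 16 photometry trials. These sizes give stable statistics
at interactive runtimes; they are the package's own defaults, and all are
parameters of the respective functions.
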