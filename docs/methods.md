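# Methods

`leadrecon` asks a deliberately skeptical question: when a neural network
reconstructs the missing leads of a 12-lead ECG from one or two measured
leads, is the output personalized, or does the model quietly predict the
population average?  The package provides every piece needed to answer that
question on synthetic data: a dipole-model ECG simulator with analytic ground
truth, a 1-D U-Net/GAN reconstruction model with analytic baselines, an open
measurement module, and a statistical battery whose composite output is a
regression-to-the-mean verdict.

## The synthetic cohort

### Dipole model

The heart's net electrical activity is modelled as a 3-D dipole vector
`D(t)`; each of the 8 independent leads (I, II, V1–V6) is a fixed linear
projection of `D(t)`, and the four remaining limb leads are derived exactly
via the Einthoven/Goldberger identities (III = II − I, aVR = −(I+II)/2,
aVL = I − II/2, aVF = II − I/2).  Axes: x = leftward (lead I), y = inferior,
z = anterior.  Rows I and II of the projection matrix lie in the frontal
plane; V3's row is dominated by z and is therefore nearly orthogonal to
lead I — the geometric reason single-lead reconstruction of V3 is
information-starved.  The exact projection values are configuration, not
science; only this orthogonality structure matters for the analysis.

Within a beat the dipole is a sum of Gaussian bumps — P (center 80 ms,
σ 15 ms), Q (188, 6), R (212, 8), S (238, 6), T (470, 45), amplitudes per
axis in μV — plus an explicit ST-segment plateau (raised-cosine ramps over
the J-point→T-onset span) so that ST-level measurement has a nonzero target.
For RR intervals under ~620 ms the whole template compresses linearly
(factor `min(1, 0.9·RR/span)`), a crude analogue of physiologic QT-rate
adaptation.  Records default to 10 s at 500 Hz in μV; the desk preset uses
4 s.

### Ground-truth fiducials

Fiducials are computed from the known wave timing, never re-detected:
onsets/offsets sit 2.5 σ from the wave center (where a Gaussian reaches
4.4 % of its peak), and T end sits at exactly 2 σ past the T peak because
that is where the tangent at the steepest descending slope of a Gaussian
crosses baseline.  These analytic definitions make the measurement module
falsifiable: its detector must land within samples of numbers it never sees.
Beats whose search windows would cross a record edge are excluded from the
ground truth under the same geometric rule the delineator uses, so on
noise-free records the two beat sets coincide exactly.

### Inter-subject variability

Per subject: heart rate ~ Normal(70, 10) truncated to (45, 120) bpm;
beat-to-beat RR jitter SD 15 ms; frontal-plane (azimuth) electrical-axis
angle ~ Normal(0°, 25°); anterior elevation ~ Normal(0°, 8°); a shared
log-normal habitus factor `global_scale` (σ = 0.25) multiplying every
amplitude; independent per-axis log-normal scale factors (σ = 0.35); mild
per-wave multipliers (σ = 0.10); white noise 10 μV; baseline wander 30 μV at
0.25 Hz.

Two of these choices deserve justification.  First, the elevation SD is
kept well below the azimuth SD: a large shared rotation toward the z axis
would itself correlate limb-lead and precordial amplitudes (analytically
R² ≈ 0.19 at 25° even with no shared scale factor), which both misrepresents
the physiology — inter-subject axis variation is predominantly frontal —
and would mask the role of the explicit shared factor the analysis is
designed around.  Second, the shared factor is the single knob controlling
cross-lead amplitude coupling: at its default the per-subject R amplitude in
lead I versus V3 has R² ≈ 0.1–0.15 (real normal ECGs show ≈ 0.04–0.2), and
setting it to zero drops the coupling below 0.05.

### What the simulator does not emulate

Pathology (infarction, bundle-branch block), non-dipolar local potentials,
respiration, electrode-placement variation, pediatric morphology, and
non-Gaussian wave shapes (notched QRS, asymmetric T).  Passing tests
therefore show that the *pipeline machinery* behaves as specified under a
known generative model, not that any conclusion transfers quantitatively to
clinical recordings.

## The reconstruction models

The generator is a 1-D U-Net: six stride-2 convolutions with leaky
rectifiers (slope 0.2) down, six upsample+convolution blocks with plain
rectifiers up, skip connections joining down-block *i* to up-block *6−i*,
dropout (p = 0.5) on the three deepest up blocks, reflection padding, and a
final tanh scaled by 6000 μV (physiologic R amplitudes with headroom).
Strided convolutions use ceil-mode lengths and upsampled maps are cropped to
the skip length, so any signal length ≥ 64 samples (including 5000) passes
the 6-level ladder.  The discriminator is a Wasserstein critic over randomly
positioned 8-channel × 800-sample patches — one offset per training batch,
identical for real and fake so the comparison is aligned — with seven
stride-2 convolutions and a linear head (a sigmoid head is available for
non-Wasserstein use, but the gradient-penalty objective conventionally uses
the unsquashed critic).

Everything runs on NumPy with hand-written forward/backward passes.  The
gradient penalty λ_gp·(‖∇ₓD(x̂)‖₂ − 1)² needs a derivative of an input
gradient with respect to the critic's weights; because the critic is
piecewise linear, this double backprop is exact and cheap: with the
activation pattern frozen, the score is affine in the input, so the
parameter gradient of ⟨∇ₓD, v⟩ is obtained by propagating v forward through
the frozen-mask network and correlating with the cached backprop signals
(bias gradients vanish identically).  The scheme is verified against finite
differences in the test suite; discrepancies appear only when a finite
difference straddles an activation kink, as theory predicts.

Training follows the GAN schedule: Adam (lr 1e-4, β₁ 0.5, β₂ 0.9), batch
32 at paper scale and 16 at desk scale, critic updated every batch and
generator every other batch, global gradient-norm clipping at 1.0 in
addition to the penalty, loss = −D(fake) + λ_L1·L1 with λ_gp = 10 and
λ_L1 = 100 (the canonical penalty and reconstruction weights; the source
method prints none, so both are flagged as assumptions and are
config-overridable).  The pure U-Net variant trains on MSE at lr 5e-5.
The returned model is the epoch with minimal validation reconstruction
error, and runs are bit-reproducible given the config seed.

Two analytic baselines frame the analysis: a mean predictor (outputs the
per-lead, per-sample training average regardless of input — the exact
regression-to-the-mean extreme, with Bland-Altman slope −1 and R² = 1 by
algebra) and an instantaneous linear map (per output lead, the least-squares
affine function of the input leads at each time point; with leads I and II
as inputs it recovers III = II − I to machine precision, a useful
self-check).

### Desk-scale preset and model sizing

The desk preset — 200 subjects, 4-s records, 20 epochs, batch 16, one CPU —
fixes the number of generator updates at 100.  Capacity interacts with that
budget in an instructive way.  A wide generator truncated at 100 updates is
caught in an amplitude-copying transient: its V3 output tracks the input
lead's amplitude nearly one-to-one (much like the linear baseline), so
reconstructed variance is *not* shrunk — an artifact of stopping a large
model early, not a property of any converged solution.  The desk generator
is therefore deliberately narrow (4→8 channels, kernel 9, ~11 k parameters):
within the same budget it reaches its information-limited optimum, which —
because the input lead carries almost no information about the orthogonal
precordial amplitudes — is the population-typical waveform timed by the
input lead.  That is precisely the failure mode under study, and it appears
robustly across seeds.  The final convolution is initialized at small scale
(a standard GAN stabilization) so early output sits near baseline rather
than amplified noise.

## Measurement

An open stand-in for a commercial ECG measurement system, fully
deterministic:

* **R detection** on a designated lead (default II): 5–40 Hz zero-phase
  band-pass, squared derivative, 100-ms moving-average envelope, peak
  picking with a 200-ms refractory, then refinement to the raw-signal
  extremum.  A noise gate compares refined peak prominences against a robust
  noise scale (MAD of the first difference), so flat or noise-only input
  raises "no beats detected".  If the designated lead fails the gate — a
  subject whose R vector is nearly orthogonal to that lead — detection
  falls back to the across-lead L2 magnitude, where the QRS loop is never
  silent.
* **Delineation** on the across-lead magnitude, where every wave is a
  positive bump: wave crests by local argmax in rate-adapted windows around
  R; onsets/offsets as crossings of baseline + 4.4 % of the local crest
  (matching the 2.5 σ ground-truth convention — a threshold calibrated to
  the simulator's Gaussian morphology, and a documented caveat for real
  data); T end by the tangent method; baseline from the PR segment.
  Unordered or edge beats are skipped and counted, never silently measured.
* **Markers**: per lead, baseline = median of the PR segment; R = window
  maximum − baseline; S = baseline − window minimum (positive by
  convention); T and STM = amplitude at the T peak / ST midpoint − baseline;
  STM is defined at the temporal midpoint of J→T-onset (the commercial
  rule is proprietary; this one is documented so results are comparable
  across runs).  Whether commercial systems reference amplitudes to the PR
  segment or to QRS onset is unknowable from outside; PR-median is used and
  documented.  Intervals: RR = median inter-R interval; QT, PR, QRS from the
  fiducial columns.  Per-record values are medians across beats (the open
  analogue of measuring on a median beat).  Missing markers are NaN with the
  beat count flagged — never silent zeros.

On noise-free cohorts this pipeline recovers amplitude markers within 2 % of
the generator's closed forms (with a 0.5 μV absolute floor — markers near a
zero crossing make pure relative error meaningless, and stored signals are
quantized to whole μV anyway) and intervals within 4 ms.

## Evaluation battery

All comparisons measure real and reconstructed versions of the same test
records identically — same detector, same delineator, same detection lead.
In reconstruction mode the detection lead is the input lead I, the one lead
guaranteed to be real on both sides.  Reconstructed leads are first
re-assembled with the true input leads into a full record.

* **RMSE** per lead over all test samples, in μV.
* **Error percentiles** (5/10/90/95 %) of per-record marker error
  (recon − real), linear interpolation between closest ranks; fewer than 20
  records sets an instability flag.
* **Means and variances**: two-sided paired t-test (pairing reflects the
  design — both groups measure the same records; an unpaired option is
  retained) and a two-sided variance-ratio F-test, p = 2·min(F.cdf, F.sf);
  α = 0.05.  Degenerate cases (identical groups, zero variance) are flagged
  with NaN p-values rather than tested.
* **Bland-Altman**: diff = recon − real against real, limits of agreement at
  mean ± 1.96 SD, plus the squared Pearson correlation and least-squares
  slope of diff on real.  (A figure caption in the source literature reads
  "±0.96 SD"; this is treated as a typo for the conventional 1.96.)
* **Inter-lead correlations**: squared Pearson correlation of each
  precordial marker (V1, V2, V3, V6) against the lead-I marker, which is
  always taken from the real table since lead I is never reconstructed.
* **Verdict**: a marker × lead cell is flagged as regression-to-the-mean
  when reconstructed variance is significantly below real (F ratio < 1,
  p < 0.05), the Bland-Altman slope is negative, and the inter-lead R² is
  inflated.  A reconstruction with exactly zero marker variance makes the
  inflation correlation undefined; it is counted as inflated, being the
  degenerate extreme of the phenomenon.

Numerical degeneracy (e.g. an SD of 1e-13 on a "constant" column built from
floating-point means) is handled by treating spreads below 1e-9 of the data
scale as zero.

The feature set for all tables is fixed to {R, S, T, STM} × {V1, V2, V3, V6}
plus the four global intervals (RR, QT, PR, QRS).

## Problem sizes

The test suite and acceptance script use: 200-subject desk cohorts (4-s
records) for training-based checks; 50 noise-free 10-s subjects for
measurement recovery; 1000 replicates of n = 500 for F-test calibration;
100 random instances (n ≤ 1000) for the statistics-vs-brute-force oracles.
The full suite runs in well under a minute of compute plus ~25 s for the
desk GAN study.

## Known limitations

* The delineator's thresholds are calibrated to Gaussian wave morphology;
  on real ECGs (notched QRS, biphasic T) its onsets/offsets would need
  re-validation against expert annotations.
* The desk-scale GAN study demonstrates the regression-to-the-mean
  *machinery* on a cohort whose inter-lead information content is known by
  construction; effect sizes are not comparable to full-scale results on
  real data, and the desk generator is far smaller than production models.
* With default noise and baseline wander, delineation wobbles by a few
  samples; amplitude markers are robust (windows are wide and baselines
  medianed) but individual fiducials on noisy records should not be treated
  as ground-truth quality.
* Real-data mode reads WFDB records (format 16) and filters by a metadata
  label, but end-to-end training on an external cohort is intentionally out
  of scope for the default build.
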