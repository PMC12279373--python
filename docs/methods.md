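# Methods

`steerlab` implements the analysis chain that links descending-neuron (DN)
electrophysiology to steering behavior in walking *Drosophila*, together
with synthetic-data generators that give every stage a known ground truth.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Signals and conventions

All continuous signals are `TimeSeries` (uniform rate, explicit units).
Treadmill kinematics are rotational, sideways and forward velocity
(`v_r`, `v_s`, `v_f`), all kept in deg/s; translational channels can be
viewed in mm/s via the ball radius (3.175 mm). Total speed is
|v_r| + |v_s| + |v_f|, a scalar activity index. Positive filter lag means
behavior follows the neuron. Ellipsoid-body sectors are indexed 0–7
counterclockwise viewed from the rear; increasing bump position is
counterclockwise. For leg analyses, positive stance direction is rightward
of straight-backward and positive swing direction is leftward of
straight-forward, so mirror reflection negates both.

## Kinematic preprocessing

1. **Offset correction.** Samples whose successive absolute difference is
   below 0.025 deg/s are treated as rest; the median over that index set
   is subtracted globally. If no sample qualifies the trace passes
   through with a warning flag.
2. **Gaussian smoothing.** A 50 ms (FWHM) Gaussian kernel truncated at
   ±3.5 σ and renormalized to unit sum; edges reflect-padded.
3. **Random-walk MAP smoothing.** The local-level model with drift:
   z_i ~ N(z_{i−1} + μ, (1−α)σ²), y_i ~ N(z_i, ασ²), α = 0.2 (20% of the
   signal variance assigned to observation noise). Because the model is
   linear-Gaussian the MAP path equals the posterior mean; we compute it
   exactly with a forward Kalman filter and backward RTS pass instead of
   an iterative optimizer, keeping the optimizer only as a test oracle
   (they agree to < 1e-6 RMS; the closed form is deterministic and fast).
   μ is estimated as the mean first difference (the MLE for this model)
   and σ² by moment-matching on first differences
   (var(Δy) = (1+α)σ²). The smoothed path depends on σ² only through the
   diffuse initial prior; the gain is set by (1−α)/α. Both estimates are
   reported in the output metadata and can be overridden. μ is fit once
   per recording.

**Inactivity classification** builds Freedman–Diaconis-width bins centered
on each channel's modal value (count ties broken toward zero, since rest
sits near zero on the rig); a sample is inactive iff all three channels
fall inside their modal bins. A constant channel is degenerate and is
flagged, counting every sample as inside.

**Resampling** of neural signals to the kinematic rate uses polyphase
rational resampling with a linear-phase FIR anti-alias filter (delay
compensated; the ×4 upsampling factor and the FIR design are exposed as
configuration since the filter order/cutoff is otherwise unconstrained).

## Spike processing

Detection: zero-phase (forward–backward) first-order Butterworth
high-pass at 100 Hz → division by a 500 ms rolling MAD estimate
(deviations about the global median, scaled by 1.4826 = 1/Φ⁻¹(0.75) for
Gaussian consistency) → `scipy.signal.find_peaks` with relative
prominence evaluated in 10 s neighborhoods and a 1 ms refractory
distance. The stated "band-pass … first-order Butterworth … 100 Hz"
names a single corner; we default to the high-pass reading (spike-band
emphasis is the stated purpose) and expose an optional upper corner for
the band-pass alternative. The rolling MAD is evaluated on a hop grid
(window/4) and linearly interpolated — the envelope varies slowly
relative to the 500 ms window — with edge windows truncated, never NaN.
A locally flat trace (zero MAD) is an error naming the offending window.
Prominence is a per-recording choice; the default (8 local-noise sigmas)
is calibrated on the synthetic session at spike SNR 8, where detection
achieves precision and recall > 0.99.

Rates: the fine estimator bins at 1.25 ms and smooths with a 2.5 ms σ
Gaussian (±3.5 σ, unit sum, zero-padded edges so edge mass leaks out
rather than folding back); the coarse estimator bins at 10 ms and applies
a causal exponential moving average whose time constant is half the 30 ms
window, so the window holds 1 − e⁻² ≈ 86% of the kernel mass (the
geometric kernel sums to one, conserving counts). Both estimators
integrate to the spike count up to edge mass.

Subthreshold voltage: initial offset = median of the first 30 s; 35 ms
median filter (spike removal); 5 ms Gaussian; detrend by the average of
independent linear fits over tiled 30 s and 120 s segments; offset added
back. Tiling (rather than overlapping) segments is our reading of the
under-specified detrend. Note the detrend deliberately removes all
sub-≈0.03 Hz structure, including genuine slow components such as
immobility hyperpolarization — recovered traces are compared against
ground truth in that light.

QC: recordings shorter than 15 min fail; epochs of ≥ 1 s where the
median-filtered voltage is more depolarized than −33 mV are marked for
exclusion.

## Linear-filter estimation (Wiener deconvolution)

F(Ω) = ⟨input*·output⟩ / ⟨input*·input⟩ over 4 s windows, inverse-FFT to
a two-sided lag filter, then smoothed with a unit-sum 0th-order Slepian
(DPSS) taper — 15 Hz half-bandwidth for neuron→behavior, 6 Hz for
behavior→neuron. The taper length is rate/bandwidth samples (NW = 1);
"bandwidth" is read as half-bandwidth, with the full-bandwidth
alternative obtainable by doubling the argument. A ridge of 1e-6 × max
input power regularizes the division; its activation is logged.

Numerical choices beyond the base procedure:

* **Segment taper.** Each 4 s segment is Hann-tapered before the FFT.
  Locomotor signals have red spectra; untapered segments leak
  low-frequency power across bins and bias the deconvolved kernel
  (measured: 0.96 → 0.997 recovery correlation on a noise-free
  single-cell simulation). A boxcar mode is kept for the literal
  procedure.
* **Lag debiasing.** Finite windows shrink the lag-τ filter value by the
  segment taper's autocorrelation ρ(τ) (the triangle 1 − |τ|/T for a
  boxcar). We divide by max(ρ, 0.5): amplitudes are restored wherever
  the correction is at most 2×, and the noise-dominated far tail is left
  attenuated (smaller floors amplified tail noise and degraded biphasic
  recovery).
* **Hop.** "1-sample overlapping windows" read literally is hop = 1; the
  default hop is window/4, which is statistically equivalent (tested
  < 1% RMS) and far cheaper. `hop=1` gives the exact mode.

Prediction: filters are estimated on the first 20% of a session and
evaluated on the final 80%. The two-sided filter is truncated to
candidate lengths on a 0.1 s grid between 0.1 and 4 s; each candidate's
prediction is scored by the R² of an OLS regression (with intercept; an
intercept-free variant would only change R² through the means) of
observed on predicted, and the best length is reported. Dual (two-cell) predictions
are the equal-weight sum, with inactive periods masked. Autocorrelations
are biased-normalized (exactly 1 at lag 0).

## Event analyses

Movement starts/stops are 75 deg/s threshold crossings of total speed
with 750 ms / 90% consistency windows on both sides (starts: pre ≤ half
threshold, post > threshold; stops mirrored). Event-triggered averages
are two-level: within experiment, then across (SEM across experiments;
a single experiment flags SEM as undefined rather than raising). The
~250 ms neural lead at transitions is measured as the cross-correlation
peak of the mean traces, never hard-coded.

Binned behavior maps shift neural data forward by 150 ms (exactly 15
samples at 100 Hz, no interpolation), reduce all series to 50 ms
non-overlapping window means, and bin behavior on the 2-D grid of the
two neural channels (default bin width 10 spikes/s; bins with fewer than
20 windows masked — 20 is our choice of display threshold). Right–left difference tuning bins Δrate = left − right the same
way and reports the binned means plus an OLS slope/intercept on the
unbinned pairs.

## Heading-bump analysis

Sector ΔF/F uses F = mean of the samples at or below the sector's median
(the "lower half"), so a mostly-baseline trace gets its baseline as F.
The PVA weights the 8 sector unit vectors by ΔF/F (negative weights
clipped to zero and logged); position is the resultant angle in sectors,
magnitude the resultant modulus; zero-magnitude frames have undefined
(NaN) position.

Trial classification applies, in order: (1) exclude if PVA magnitude
stays below the experiment-wide 7th percentile (computed on the raw,
unsmoothed magnitude) for > 1 s during the trial; (2) exclude if the
circular SD of position in the 1 s pre-puff window exceeds 1.5 sectors;
(3) initial position = circular mean of that window; (4) exclude if the
bump never moves ≥ 0.5 sectors from it; (5) exclude if it never dwells
within 0.5 sectors of it for ≥ 0.5 s afterwards. Circular mean and SD
use the resultant vector (SD = √(−2 ln R)); displacement and dwell use
the shortest arc. The return period runs from maximum excursion to
re-entry into the 0.5-sector band; return speed is the derivative of the
3-frame Gaussian-smoothed position (the smoothing is our choice; the
procedure is otherwise silent), and ties for the maximal return speed
take the earlier frame. Averages aligned on the maximal-return-speed
frame are grouped by return direction (never mixed) and averaged within
fly, then across flies.

## Leg kinematics

Body velocities come from the head–abdomen vector: forward = centroid
velocity projected on the axis, sideways = |orthogonal component|,
rotational = |d(axis angle)/dt|, averaged over non-overlapping 500 ms
windows; windows with mean forward velocity < 2.0 mm/s are discarded.
A leg is in stance when its camera-frame speed, averaged over 3
consecutive frames, is below 8 mm/s (camera frame "as tracked" is our
reading; a body-frame alternative would shift the threshold's meaning).
Rotation events are 20 deg/s excursions sustained ≥ 0.1 s, analyzed in
500 ms windows starting 100 ms before the crossing; the inner side is
the side the fly turns toward.

The five turning metrics (stance direction of oF/iF/iM; swing direction
of oF/iF/iM; swing distance of oF,oM over iM,iB; stance duration of iB
over iF,oF,oM,oB; swing duration of iM,iB) are computed on body-centric
tarsus trajectories — positions transformed into the moving body frame so
translation and rotation drop out — over complete epochs only; a metric
whose relevant legs lack a complete epoch is omitted with a reason. The
swing-direction metric is defined here on swing epochs; a literal
stance-epoch variant is available behind a config switch (the stance-epoch variant would simply duplicate the stance-direction
metric). Step frequency is the mean of
1/stride-duration over complete stance-onset-to-stance-onset strides of
all six legs; step length is the body-centric extent of the tarsus
trajectory over each complete swing (projected on the swing's principal
direction, which is robust to one-frame labeling blur at epoch
boundaries).

## Perturbation statistics

**Unilateral-activation bootstrap.** Control flies with bilateral
expression are resampled with replacement and each resampled fly is
randomly labeled right- or left-expressing; the replicate statistic is
the mean label-signed ("ipsilateral") rotational velocity. 1000
replicates give a percentile interval (2.5/97.5; the basic-bootstrap
alternative is noted but not used); an observed mean outside it is
significant. Labels are re-randomized within each replicate by default
(the description is ambiguous; a fixed-labels variant ships for
sensitivity checks). The coverage simulation draws each experiment's
17 control-fly means from a zero-mean normal and checks an independent
draw of the same label-randomization statistic (from the same flies,
independent of the interval replicates) against the interval — for that
statistic the percentile interval is exact, so coverage is nominal
(~95%). Checking a *fresh sample* of flies instead also probes
small-sample variance estimation and sits near 93.7% at n = 17 — an
intrinsic property of percentile intervals on 17 flies, reported by the
unit tests at a correspondingly wider tolerance.

**Genotype × light ANOVA.** Per metric, a fixed-effects two-factor ANOVA
with interaction on 500 ms windows (windows as datapoints, with the
fly-ID check as the guard — we deliberately do not substitute a mixed
model);
flies contributing < 5 windows to a metric are dropped first. The
interaction p-values are Holm step-down corrected across the m metrics;
where the corrected interaction is significant, Tukey HSD compares light
on/off within each genotype. The fly-ID check fits value ~ fly + light
and reports SS_fly/SS_total, flagged above 0.2 (configurable).

## Connectome pathways

Unitary connections with < 5 synapses are discarded; survivors are
grouped by (pre type, post type), pooling hemispheres, and summed.
Groups are then discarded below an absolute synapse count or below a
fraction of either cell type's grand pre-/post-synaptic total
(presets: 200 / 1% and 70 / 0.4%). Fractions use totals computed after
the unitary filter but before group filtering, so the rule is
order-independent across groups; a group is discarded when *either*
fraction is below threshold (the conjunctive alternative is noted).
Reported weights are per hemisphere: exactly half the group total.
Two-hop pathway search ranks intermediates by the weaker of the two
per-hemisphere edge weights.

## Synthetic data: what it emulates, and what it does not

**Steering sessions.** One unit-variance Ornstein–Uhlenbeck latent drive
(τ = 0.5 s) per cell-type pair; the right cell's rate is baseline
(20 spikes/s) + gain (8 spikes/s per unit drive) × drive, the left
cell's drive is −c × drive + √(1−c²) × an independent OU, so the pair's
rate anticorrelation equals the see-saw coupling c (default 0.8 — the
anticorrelation magnitude of real DN pairs is not a measured quantity
here, so c is a free parameter, not a fitted value). Kinematic axes are sums of
ground-truth kernels (a monophasic "low-gain" and a biphasic "high-gain"
shape, mirrored across hemispheres) convolved with baseline-subtracted
rates, plus Gaussian noise (default 40 deg/s on v_r, giving session SNR
≈ 3–6); kernels live on the 100 Hz kinematic time base, where all the
analyses operate. Immobility bouts (2/min, mean 2 s) gate the kinematic
output to zero, suppress rates to 30% of baseline, and hyperpolarize the
voltage — a multiplicative gate, chosen so transition-detection tests
have exact onset times. Spikes are inhomogeneous-Poisson by thinning
with a 2 ms refractory period (disable it to test time-rescaling
exactly); voltage is the spline-interpolated subthreshold potential
(0.3 mV per spikes/s) plus a fixed 2 ms biphasic template (amplitude
8 mV over 1 mV noise, i.e. SNR 8) at each spike time. Equal seeds give
bit-identical sessions.

Not emulated: biophysical membrane dynamics, ball physics, measurement
nonstationarities, bursting or adaptation. Passing tests show the
*analyses* are correct under the stated statistical structure, not that
real recordings satisfy that structure.

**Bump movies.** A von-Mises-shaped profile (width 1.2 sectors) over 8
sectors follows heading/45° plus scripted jump offsets that hold and then
ramp back (the return); fades are scripted amplitude collapses. The
scripted experiment cycles jump-CCW / jump-CW / no-jump / jump-CCW /
faded trials (±2.5-sector jumps), so classification, jump signs and
return directions all have ground truth, and faded frames stay well
under 7% of the experiment so the magnitude-percentile criterion is
meaningful.

**Gait.** Alternating-tripod stride trajectories scripted in the body
frame and transformed to the camera frame; the body advances at the
speed that keeps stance tarsi world-fixed. Turn biases (iB stance
prolongation, stance/swing direction rotations, inner/outer swing
scaling, path curvature) are applied directly in the quantities the
metrics measure, so each metric's ground truth is exact. Defaults:
2.5 Hz stride, 2 mm steps, duty 0.5, 200 Hz frames.

**Synapse tables.** Each spec entry connects every presynaptic cell to
every same-hemisphere postsynaptic cell with fixed or uniform-drawn
unitary counts.

## Problem sizes

Test and validation runs use 60–600 s sessions at 100 Hz (voltage at
10 kHz only where spike detection is exercised), 20-seed recovery
ensembles, 50-trial bump experiments, 500-experiment bootstrap coverage
studies, and 1000-run ANOVA calibrations — sizes at which every
statistical check is well-resolved while the full suite runs in a few
minutes.

## Known limitations

* The kernel-recovery correlation is computed against the true kernel
  over its support; the Slepian smoothing slightly rounds sharp kernel
  features by design.
* The detrending step removes genuine sub-0.03 Hz voltage structure;
  recovered subthreshold traces are high-pass versions of the truth.
* The percentile bootstrap undercovers slightly (~93.7% at 17 flies)
  when judged against fresh samples; this is a property of percentile
  intervals at this sample size, not of the implementation.
* Fixed-effects window-level ANOVA carries a pseudo-replication risk; the fly-ID variance check is the guard, not a
  cure.
* The gait generator scripts kinematics; it does not enforce physical
  ground-contact consistency under combined direction biases, and the
  resulting small tarsus drift is negligible only on the sub-second
  analysis windows used here.
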