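# Methods

## Field model

The tissue below the pia is an isotropic, homogeneous conductive half-space
with resistivity ρ = 5×10³ Ω·mm (the in vivo value for cortex). A point
source carrying current I produces the hemispherically spreading potential
V(r) = ρI/(2πr); the 0.25 mm disk electrode is discretized as a uniform
square lattice of point sources at 12.5 μm pitch clipped to the disk
(≈317 sources), each carrying an equal share I/M of the total current. The
lattice is integer-indexed so the point set is exactly mirror-symmetric,
which makes the computed field reflection-symmetric about the disk center
to rounding error. The 2.2 × 2.2 mm evaluation grid (10 μm spacing by
default) is the vertical plane through the disk center of the 3-D
half-space solution; lattice points off the plane contribute through their
full 3-D distance. Distances are clamped below at half the grid spacing so
pial nodes under the disk stay finite — this is a regularization choice,
not physics; potentials within one grid cell of the disk surface should
not be interpreted quantitatively.

Assumptions deliberately not modelled: anisotropic or layered
conductivity, CSF shunting along the pia, electrode polarization
chemistry, and any time dependence (the field is the DC steady state).

## Rod polarization (mirror estimate)

Each neuron type is a vertical rod from its dendritic top to bottom depth
with a discrete soma depth approximating the electrotonic center and the
colocalized axon initial segment. For a rod at lateral position x the
mirror estimate is ΔVm(z) = mean over the rod of Vₑ − Vₑ(z): the DC analog
of the extracellular activation function for a passive cable with sealed
ends. By construction ΔVm integrates to zero along the rod; compartments
where the local potential is below the rod mean depolarize. The rod is
sampled at the field grid spacing with bilinear interpolation of Vₑ; the
soma value uses the interpolated potential at the exact soma depth.

The packaged morphology table (depths in mm from the pia: L2py
0.10–0.55/0.25, L3py 0.10–0.80/0.50, L4sp 0.30–1.05/0.90, L4ss
0.60–1.10/0.90, L5st 0.10–1.35/1.20, L5tt 0.05–1.50/1.25, L6cc
0.60–1.90/1.65, L6ct 0.40–1.95/1.70, BC ±0.15 about 0.90, MC
0.90–1.30/1.25) approximates the anatomical literature for rat S1 and is
**an implementation default, not a measured dataset**; relative densities
(0.11/0.17/0.09/0.15/0.11/0.10/0.14/0.13 for the excitatory types, with
BC 0.12 and MC 0.06 giving an ~15% inhibitory fraction) are likewise
defaults. Both are configurable via CSV, and every laminar statement made
by the tests is relative to this table. Layer bands: L1 0–0.15, L2/3
0.15–0.75, L4 0.75–1.10, L5 1.10–1.55, L6 1.55–2.00 mm.

With this geometry the physics produces the expected laminar pattern
rather than it being asserted: L5 rods span the strongest vertical
gradient, so their somas dominate; superficial rods sit near the field's
biphasic zero-crossing and invert sign at lateral offsets > 0.2 mm; the
compact symmetric inhibitory rods come out near zero.

## Gain kernel

Rods are scattered laterally, per-type counts by largest-remainder
rounding of density shares (500 rods across excitatory types by default).
The minimum lateral gap (5 μm default) is enforced **within each type**:
the stated non-overlap constraint cannot hold jointly across 500 rods in a
2.2 mm section (500 × 5 μm > 2.2 mm), and rods of different types occupy
different rows of the cross-section, so within-type spacing is the
physically meaningful reading. Rejection sampling is capped at 10⁵
attempts per type, after which a packing error is raised. The population
score S(x,y) is the Gaussian-weighted (σ = 0.1 mm) sum of *excitatory*
soma polarizations on a 200×200 grid; inhibitory rods are placed and
polarized for reporting but excluded from S. S is linear in source
current; it is a polarization score in volt-weighted units, not a firing
rate.

## ESA pipeline

Band-pass: 4th-order zero-phase Butterworth (forward–backward), 300–5000
Hz; the filter family and order are implementation choices (only the band
is prescribed by the method). ESA: full-wave rectification followed by
bidirectional (forward then backward) convolution with a discrete
Gaussian, σ = 1 ms, truncated at ±3σ (length 6σ) and renormalized to unit
sum; edges use reflection padding. Because the kernel is symmetric, the
bidirectional pass equals convolution with the kernel's autocorrelation —
a unit impulse maps to peak Σk², which the tests exploit as a closed form.
Spontaneous envelopes are binned in 50 ms non-overlapping bins over the
29 s epoch windows (0.5–29.5, 30.5–59.5, 60.5–89.5 s; trailing partial
bins dropped), and the percent change is 100·(during − pre)/pre per
channel, with a hard error on nonpositive baselines. Layer summaries
average channels within a layer per animal first, then report mean ± SEM
across animals (SEM is reported as 0 with a count flag when only one
animal is present).

## Evoked-response MSE analysis

Per trial, the 5–55 ms post-stimulus segment (5 ms artifact window
excluded, 5 ms pads) is ESA-transformed, cropped to 10–50 ms, binned at
1 ms, and trials are averaged arithmetically (10 per condition) into a
channels × 40 heatmap. MSE between two heatmaps is the mean squared
elementwise difference in μV². Matrices are oriented with reference maps
(rows) and query maps (columns) both ascending in intensity; "above the
diagonal" (row < column) therefore measures similarity of queries to
lower-intensity references. Trials overrunning the recording are dropped
with a warning; losing all trials is an error.

## Spectral analysis

The column signal is the first principal component score of the
mean-centered channels × time segment (sign fixed so channel loadings sum
positive). PSD: median over time of squared STFT magnitudes with 2 s
Hamming windows and 0.5 s overlap between consecutive windows (hop 1.5 s —
the literal reading; a 0.5 s hop is available via the overlap argument),
interpolated linearly in log-frequency onto a log-spaced 0.5 Hz–3 kHz
axis, smoothed with a centered 10-point moving average (shrinking at the
edges), floored at machine epsilon, and converted to dB re 1 μV²/Hz.
Analysis segments default to 10.5–29.5 s (pre) and 40.5–59.5 s (during).

## Behavior

SUDO: five-trial staircase on the packaged Touch Test ladder (0.008–300 g,
20 filaments); X steps one filament down, O one up, clamped at the ends.
The threshold index is the fifth trial's index −0.5 (X) or +0.5 (O) and
the force is the geometric mean of the flanking filaments, with
out-of-range indices clamped to the end force. The estimator is verified
exhaustively against an independent enumerator over all 32 outcome
sequences × all start indices.

Mixed model: REML fit of threshold ~ amplitude (categorical, 0 μA
reference) with random intercepts for rat and session-within-rat, via
statsmodels MixedLM. Wald t contrasts vs 0 μA use **residual** degrees of
freedom (n − rank X); the fitting backend does not provide Satterthwaite
df, and the fit object reports `df_method` explicitly. Contrast estimates
and SEs are backend-independent (one test cross-checks them against an
lme4 fit to 0.01 g). BH-FDR is applied across amplitudes within a paw.
With two rats the rat variance component is weakly identified and may sit
at the boundary; estimation proceeds with a warning, which is the expected
behaviour for this design.

## Synthetic generators

All generators are pure functions of their config (including the seed).

**Spontaneous** (defaults = study conditions): 32 channels at 24.414 kHz
for 90 s, contacts at 50 μm pitch from 0.1 mm depth (1.55 mm span).
Per-channel inhomogeneous Poisson spiking, rate = base·(1 + m·sin(2πft))
with f = 1 Hz, m = 0.8, and L5-dominant base rates (L1 1, L2/3 5, L4 8,
L5 25, L6 6 Hz); spikes are Bernoulli thinned at sample resolution and
convolved with a 1 ms biphasic 80 μV template. A shared 150 μV slow-wave
LFP at the same ~1 Hz is added so the *raw* signal carries the
anesthetized-state spectral peak (biphasic spikes alone have almost no
1 Hz spectral mass); the 300 Hz high-pass removes it before any ESA
computation. Gaussian noise (5 μV default) completes the signal. A
per-channel gain multiplies the rate during 30–60 s, optionally derived
from a gain-kernel column (`gain_profile_from_kernel`, gain = 1 +
coupling·S/max|S|).

**Evoked**: 10 onsets at 2 s intervals; each adds a Gaussian rate
transient (σ = 4 ms) at 20 ms latency (0.5 ms jitter), peak rate =
1500 Hz × A(intensity) × gain, depth-weighted (Gaussian centered 1.0 mm,
σ 0.35 mm, the thalamorecipient input layers). A(i) is a saturating Hill
map (i²/(i² + 1.5²)); the default intensity family 0.8–2.4 mA in 0.4 mA
steps sits on its steep region so adjacent intensities produce distinct
response levels, as the in vivo intensity range was chosen to do.
Ipsilateral mode adds no transient.

**Von Frey**: latent block threshold = 8 g baseline + effect(amplitude,
paw) + rat intercept (SD 1.0 g) + session intercept (SD 0.5 g) + residual
(SD 2.0 g); default contralateral effects are the reported coefficients
(+20: −3.794, +40: −4.329, −20: +0.250, −40: +4.213 g), ipsilateral
effects zero. The staircase starts at the 8 g filament with a
deterministic response rule (withdraw iff force ≥ threshold; a logistic
rule is available). Baseline and start sit in the densest near-geometric
section of the Touch Test ladder (4–15 g), where the SUDO quantizer
resolves ~4 g shifts — the same consideration an experimenter applies when
choosing the start filament. Design size: 2 rats × 7 sessions × 2 blocks
per amplitude per paw per session (≈10 blocks/paw/day over 5 amplitudes),
i.e. 28 blocks per amplitude per paw.

**What the generators do not emulate**: refractory structure, spike
waveform diversity and amplitude decay with distance, cross-channel spike
correlations beyond the shared rate envelope, up/down-state bistability
(the slow wave is sinusoidal), recording artifacts, and any nonlinear
network response to iDC (the gain is imposed, not emergent). Passing
recovery tests therefore demonstrates that the *analysis stack* is
correct and unbiased under the assumed statistical structure — not that
real cortex behaves this way.

## Numerical choices and problem sizes

Units are fixed internally (mm, A, Ω·mm, V; μV for recordings; grams for
forces); converters live at the I/O boundary. Recordings are float32;
filtering preserves the input float dtype. Ties in largest-remainder
rounding break by original table order. The acceptance checks run at the
study's native recording scale (90 s × 32 channels × 24.414 kHz) with 10
seeds for ESA gain recovery, 3 seed-replicates of the 5-intensity evoked
family, 10 scatter seeds for the kernel structure, and 200 replicates of
the behavioral design for mixed-model recovery — sizes chosen to keep the
full suite in a few minutes while leaving Monte-Carlo error well inside
the stated tolerances.

## Known limitations

The half-space field model ignores the probe shank and the finite
catheter geometry; the mirror estimate ignores branch geometry, active
conductances, and ephaptic feedback; S weights somas only and does not
transduce polarization into firing-rate changes (the linear gain link in
the generator is a modelling convenience); residual-df p-values are
slightly anticonservative relative to Satterthwaite at this design's
group counts, though the estimates and SEs are unaffected.
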