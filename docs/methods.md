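# Methods

`ptstroke` implements the quantitative analysis chain of an acute
photothrombotic-stroke monitoring experiment in mice: electrophysiological
detection of spreading depolarizations (SDs) and 4-aminopyridine (4-AP)
seizures, intravital-imaging read-outs of perfusion, blood–brain-barrier (BBB)
permeability and propidium-iodide (PI) cell damage, ex-vivo MRI lesion
volumetry, optical-fractionator stereology, and the non-parametric group
statistics connecting them.  Because no animal data ship with the package, a
calibrated synthetic-data generator emulates the experimental arms; every
analysis stage is validated as a round trip against the generator's ground
truth.

## Experimental arms

Three monitored groups plus one control, mirroring standard photothrombosis
(PT) protocols: PT under urethane anesthesia; PT + topical 4-AP (starting
70 min after PT) under urethane; PT + 4-AP under ketamine/xylazine; and 4-AP
without PT (no-stroke control).  The timeline is 30 min pre-PT baseline plus
240 min post-PT monitoring; the Rose Bengal injection marker defines t = 0
for latencies.

## Electrophysiology

**Band splitting.** The DC-coupled electrocorticogram of each electrode is
separated with zero-phase 4th-order Butterworth filters: DC ≤ 0.5 Hz
(carrying the SD potential shift), AC 0.5–45 Hz (spontaneous activity,
seizures), and AC power = squared AC smoothed over 1 s.  Only the corner
frequencies are physiologically fixed; the filter order and zero-phase
realization are implementation choices.  Sampling below 90 Hz is rejected
(45 Hz band unresolvable).

**Potassium conversion.** Ion-sensitive electrode potentials map to
extracellular potassium by the Nernst relation `K = 3 mM · 10^(ΔV/s)` with
slope `s = ln(10)·R·T/F ≈ 61.54 mV` per decade at 37 °C.  ΔV is referenced to
the median ion potential of the pre-PT window, so the slow inter-event
baseline drift (3 → ~4.5 mM by the fourth hour) is preserved in the
converted trace.

**SD detection.** An SD is scored where the DC band drops below −10 mV
relative to a 60 s pre-event baseline for ≥ 10 s *and* the potassium trace
exceeds 2× its local baseline within ±30 s.  The per-event baseline is the
90th percentile of the preceding 60 s (robust to the recovery tail of a
preceding SD); amplitude is the trough relative to that baseline; duration is
the time below half amplitude; events with onsets closer than 60 s on one
electrode merge; events are matched across electrodes within 120 s.
Detection runs on a 10 Hz decimation of the band-limited traces.  The −10 mV
/ 2× thresholds are engineering choices placed between the SD (≈ −21 mV,
≈ 40 mM) and seizure (≈ −3.7 mV, ≈ 9 mM) regimes.

**Classification and direction.** SDs with onset ≥ 70 min after PT (or after
the 4-AP marker where present) are *delayed*, the boundary itself assigned to
delayed; earlier ones form the *onset* complex.  Events preceding PT are
flagged, not classified.  Propagation is *outward* when the electrode nearer
the lesion border leads by > 2 s, *reverse* when it lags, otherwise
undetermined.

**Seizure detection.** A seizure is an interval with AC power above the
pre-4-AP baseline median + 5 MAD for ≥ 10 s, gaps < 5 s merged, and samples
whose concurrent DC excursion reaches SD scale (≥ 10 mV) excised and
attributed to the SD.  Event power integrates the squared AC signal;
cumulative duration/power and latency from 4-AP start summarize the burden.

**LDF.** The laser-Doppler response to an event is the peak within 3 min of
onset as a percentage of the median pre-PT baseline.

## Imaging

Fluorescein bolus stacks (5 Hz × 306 s, injection 6 s in) are normalized by
an arterial input function (AIF): among pixels whose first-pass peak falls in
the earliest-arrival quartile, the top 0.1% by peak amplitude are averaged
(an explicit arterial mask can override the automatic choice).  The
first-pass window runs from the AIF's 10%-of-peak rise to its decay below 20%
of peak, capped at 60 s — a definition chosen to be robust to leakage tails.
Hypoperfused pixels have first-pass peaks below 30% of the AIF peak; the BBB
permeability index is the pixel's post-first-pass integral divided by the
time-matched AIF integral (trapezoidal, negative values clipped to 0), which
makes the index 1 for a pixel tracking the AIF and invariant to global
intensity rescaling.  PI average images are corrected by subtracting a wide
Gaussian low-pass (σ = 50 px); pixels above the corrected pre-PT reference's
mean + 2 SD count as positive, with a 100 µm disc read-out at electrode
positions.  Spatial maps reduce to profiles of signed distance from an
equivalent-area circle (centroid + √(area/π)) fitted to the 1 h
hypoperfusion mask.  Movement correction is out of scope; synthetic frames
are motion-free.

## MRI lesion volumetry

Per axial slice, an ipsilateral voxel is hyperintense when it exceeds the
mirrored contralateral region's mean + 2 SD; 3-D connected components smaller
than 20 voxels are discarded.  The mirror-hemisphere rule is this package's
concrete realization of "hyperintense relative to the contralateral
hemisphere"; slice-wise statistics tolerate intensity drift along the
rostro-caudal axis, and the distribution-relative threshold makes the
segmentation invariant to affine intensity rescaling.  Midline defaults to
the sagittal center plane with a config override for tilted specimens.
Manual masks are ingested for comparison (Spearman volume correlation +
per-subject Dice).

## Stereology

The optical fractionator counts injured neurons in 50×50 µm frames, one per
250×250 µm grid square (area sampling fraction 1/25), on nine sections
160 µm apart at 20 µm thickness (section sampling fraction 1/8):
`N̂ = ΣQ × 25 × 8`.  Frames share one uniform random offset per section
(systematic uniform random sampling); left/bottom edges include, right/top
edges exclude.  Precision is the Gundersen–Jensen coefficient of error with
smoothness class m = 1 (the default of commercial stereology software), where
the systematic-sampling variance term may be slightly negative for smooth
section profiles and then reduces the Poisson noise term.  Morphological
classification of injured neurons is upstream human work: the package
consumes injury flags, and the generator produces them.

## Statistics

Group tables are summarized as median and IQR (25th/75th percentile, linear
interpolation).  Two groups compare by Mann–Whitney U (exact null when both
n ≤ 20 and there are no ties, asymptotic otherwise), more by Kruskal–Wallis,
paired variables by Wilcoxon signed-rank; correlations are Spearman with
average-rank ties.  p values are raw — no multiple-testing correction is
applied, matching the exploratory design.

## Synthetic-data generator

The generator is phenomenological: no reaction–diffusion tissue model, only
waveform templates with calibrated statistics.

**Calibration.** Group-level quantities are published as median (IQR).
Positive quantities are log-normal with the printed median and
σ = ln(q75/q25)/(2·z₀.₇₅); signed DC amplitudes are normal on the raw scale.
Where printed quartiles are asymmetric about the median in log space a
log-normal cannot match all three numbers; the IQR *width* is matched.
Draws are truncated to physical ranges (latencies within the onset window,
[K⁺]ₒ ≥ baseline, SD amplitudes ≤ −12 mV so injected events stay inside the
detector's validated regime).

**Balanced cohorts.** Per-recording values of calibrated quantities are
drawn by inverse CDF at a quantile that depends deterministically on the
seed: consecutive seeds form antithetic pairs (u, 1−u), and the pair-level
quantile is a van der Corput point digit-scrambled per quantity (an
Owen-style digital shift).  Marginally over seeds each quantity follows its
calibrated law, while any cohort of consecutive seeds is quantile-balanced —
a whole number of pairs has median quantile exactly 0.5.  This is a
Latin-hypercube-style variance-reduction design chosen so that study-sized
cohorts (n = 8–19) reproduce the calibrated medians faithfully; its cost is
that draws are not independent across seeds, and different quantities within
one recording are rank-coupled through the shared seed.  Within-recording
randomness (noise, event spacing, per-event scatter) uses an ordinary PCG64
stream keyed by the seed, so identical (config, seed) pairs are bit-identical.

**Ephys waveforms.**  SD: smooth 10 s DC fall, 30–60 s plateau, exponential
recovery (τ = 20 s); the potassium surge uses τ = 25 s for onset SDs and 75 s
for delayed SDs (slower, less complete return); background AC is suppressed
to 20% after each SD, recovering with τ = 120 s.  The per-recording maxima of
SD amplitude and potassium peak equal the calibrated draws (the first event
carries the envelope; later events scale by 0.78–0.98), matching how
per-animal maxima are reported.  Onset SDs lead on the proximal electrode,
delayed SDs on the distal one, with a 20 s conduction delay (no printed
value exists; this is an artifact choice).  Seizures are 5–12 Hz oscillation
bursts whose common amplitude derives from the calibrated cumulative
duration and power (amp = √(2P/D)), with a small DC plateau and a moderate
potassium rise; LDF transients use the calibrated hyperemia gains.  Events
are placed disjointly — delayed SDs keep their slow potassium tails ~10 min
clear of seizure windows and seizures avoid onset-SD zones — rather than
modelling SD-interrupts-seizure dynamics; the interruption flag is exercised
by constructed overlaps in tests.  Inter-event baseline potassium ramps from
3 mM (starting 1 h post-PT) to the calibrated fourth-hour level by 170 min,
then holds.

**Imaging.** Gamma-variate first pass (peak 8 s after a 2 s arrival) plus a
slowly decaying intravascular plateau on arterial pixels; perfused tissue is
a delayed 0.45× copy; the ischemic core (8% of arterial amplitude) is a disc
growing 150 → 240 µm from 1 h to 4 h; leakage pixels accumulate signal
proportional to the running AIF integral with a per-pixel transfer constant
concentrated in a peri-lesional annulus, so the measured permeability index
is monotone in the constant.  PI images carry σ = 3 px Gaussian spots
(amplitude 40× noise) whose count grows with time and is reduced 0.6× under
ketamine, on a background kept below the noise floor so the published σ = 50
px correction removes it even at small synthetic frame sizes; the ground
truth mask is the noise-free spot field passed through the same correction,
thresholded at 2 noise SDs.  A bright-field pair encodes the IOS front as a
bright annulus.

**MRI.** 256×256×84 voxels at 0.1×0.1×0.25 mm (scaled-down shapes accepted
for tests); bilateral Gaussian background (mean 100, SD 5) plus one
ipsilateral cortical half-ellipsoid at +5 SD whose volume is drawn from the
group calibration; a one-step axis rescale corrects voxelization bias so the
realized mask volume matches the draw within ~1%.

**Histology.** The nine sampled sections carry ssf × (true total) injured
neurons, allocated across sections by a smooth unimodal lesion profile and
placed uniformly in a rectangular ROI; intact neurons form a uniform
background.  The fractionator's estimand is the realized sampled count
scaled by 1/ssf.

**What the generator does not emulate.** Real electrode artifacts, movement,
vascular anatomy, spatially varying noise, partial-volume effects at the MRI
lesion rim, nonuniform neuron loss within sections, or any biophysics of SD
propagation.  Passing round-trip tests therefore demonstrates correctness of
the analysis implementations under the stated signal model, not performance
on real recordings.

## Numerical choices and degenerate inputs

Empty traces yield empty event lists; a missing pre-4-AP baseline, empty
hypoperfusion mask, missing PI reference, shape mismatches, and midline at
the volume edge raise `ValueError`.  Zero counted neurons give N̂ = 0 with
undefined CE.  Constant inputs to Spearman are flagged with NaN.  The
boundary SD at exactly 70 min is delayed by convention.  Detection operates
at 10 Hz; amplitudes are measured on the 0.5 Hz band so decimation is
lossless for SD-scale events.

## Problem sizes

Round-trip suites use the study's cohort sizes (16/8/10/13/19 recordings of
270 min at 200 Hz; 8 full-size MRI volumes), chosen to match the reported
group sizes.  Unit and property suites run on shorter recordings (100 min at
100 Hz) and smaller frames/volumes, which the configuration objects expose
directly.
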