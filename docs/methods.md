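# Methods

This note documents the models and procedures implemented in `arrestlab`,
the parameter defaults and why they were chosen, the conventions that make
the numerics exact where exactness is claimed, and what the synthetic
sessions can and cannot demonstrate.

## Corridor velocity and arrest timing

The chamber position is the x-coordinate of a single ventral marker
(tail base, standing in for a perianal marker). The trace is
offset-corrected by subtracting its first sample — velocity is invariant to
any constant offset, so subtracting the pre-light mean instead would give
identical results — then downsampled to 150 frames/s by decimation
(keeping every k-th frame; raw frame rates must be integer multiples of
150). Velocity is the finite difference times the frame rate; values
strictly below **0.045 m/s** are set to zero to remove tracking jitter,
which also removes the (physically meaningless here) negative values. A
20-ms rolling average is available (`smooth_for_plotting`) but is never
applied before event detection.

Arrest/resume use contiguity rules with a minimum run of **4 frames**
(26.7 ms at 150 frames/s). The clause that a candidate zero-run must not be
"followed by four contiguous non-zero frames" is interpreted as: a zero-run
terminated *within the light-on window* by ≥ 4 moving frames is a transient
hesitation and is skipped in favor of the next stable run. Threshold
comparisons are strict (`< 0.045`, `> 0`). Trials without 0.5 s of coverage
before and after the light window are flagged excluded rather than raising,
mirroring the assay's inclusion rule. Resumption is searched within a 1.5-s
post-light observation window (configurable); trials with no qualifying run
are reported `resumed=False` and excluded from time-immobile summaries.

## Limb-pair coordination

### Speeds and pause/play events

Marker positions are smoothed with a centered **30-frame** moving average
before differentiation; per-marker speeds are signed x-velocities in cm/s,
and the limb-pair speeds s_F, s_H average the two paws of a pair (for
anti-phase gaits the oscillatory components cancel, leaving the
translation). **Indexing convention:** speed sample k is the forward
difference over the frame interval [k, k+1), stamped at frame k. With this
convention the pause event (first sample after light onset with
|s| < ε_s sustained ≥ n_s samples; ε_s = 0.5 cm/s, n_s = 4, both
configurable) and the play event (first sustained |s| ≥ ε_s after light
offset) both index frames whose *positions* still hold the arrested
posture — the centered filter makes the speed trace respond half a window
early, which keeps both anchors strictly inside the held segment. This is
what makes the pause–play phase difference of an uninterrupted
pause-and-play trial exactly 0°, rather than 0° plus one frame of phase
advance.

### Phase

Two phase definitions are implemented because they serve different roles:

* **Displacement mode** (default): φ(t) = 180°·d(t)/d_max, where d is the
  left-minus-right displacement and d_max a robust per-trial maximum
  (99.5th percentile of |d|, then clipped to ±180°). This gives a
  continuous trace that is flat at its held value during an arrest —
  required for Δφ and continuity scoring. If d ≡ 0 (perfect synchrony
  throughout) the phase is reported as the synchrony value 0° with a
  `degenerate` flag, since the normalization is undefined.
* **Lag mode**: φ = 360°·(t − t₀)/T from per-cycle peak timing, with
  sub-frame quadratic peak refinement (without it the 150-Hz grid alone
  contributes ~10° of quantization at a 4-Hz step rhythm) and circular
  interpolation between cycles. This is the natural check that a known
  left–right offset is recovered.

**Body-axis correction.** The default (`projection`) projects the
left–right separation vector onto the instantaneous body axis
b = p_M − p_B. This is geometrically exact: rotating an entire trial
rotates b with it, so the corrected phase is invariant to heading changes
(the package tests require < 1° change under an 8° rotation, and the
projection meets it with margin). An `additive` mode — adding the signed
body-axis angle, from the arccos form with the sign of the slope of b, to
the phase at each time step — is also provided for compatibility with that
convention; it is approximate, since it adds a geometric angle to a
normalized-displacement phase, and is not the default for that reason.

### Continuity

m_pause is the mean phase slope between the pause event and the previous
phase peak/trough; m_play between the play event and the next one. Extrema
are detected with a **20° prominence floor** (slopes must be measured
between genuine cycle extrema, not noise wiggles), and a peak/trough held
flat through an arrest is timed at its *left edge*, so an arrest landing on
an extremum sees that extremum as immediately preceding the pause and gets
a near-zero m_pause. The decision rule scores 1 on matching slope signs,
1 on a sign switch when |m_pause| < ε_slope × (the trial's steepest
inter-extremum slope) with ε_slope = 0.1 (the "arrested at the peak" case,
where reversal is the natural continuation), and 0 otherwise. The exact
tolerance behind "|m_pause| ≈ 0" is a judgment call; 0.1 relative is the
package's choice and is configurable. Trials without a bracketing extremum
on either side are flagged unclassifiable.

### Posture classifiers

Mid-stance requires contact area strictly above 25% of the full-contact
reference area (exactly 25% classifies as swing); hind-paw alignment
requires the body-axis-to-paws angle within [75°, 105°].

## Activity states

"Active" is strictly above the inactivity threshold; a sample exactly at
the threshold is inactive (consistent with bouts being "activity below
threshold"). The threshold itself is setup-dependent (resolution, subject
size) and is deliberately a mandatory parameter with no default claimed
faithful to any particular rig. Epoch percentages use three equal epochs
(default 3 s) around light onset with half-open sample windows. Arrest
bouts are maximal below-threshold runs; qualification is
0.5 s ≤ duration ≤ 2 s, inclusive on both ends. An exact 50/50 chamber
split yields no preferred chamber and is flagged rather than decided.

## Cardiorespiratory analysis

Cleaning: centered moving averages of 3 ms (ECG) and 21 ms (flow), then
subtraction of the whole-recording mean. Breaths are peak inspiratory flow
events — the flow trace is inverted so PIFs are maxima; beats are R-waves.
`scipy.signal.find_peaks` does the detection, with defaults chosen to be
scale-free because the assay disregards absolute flow units: minimum
inter-event distance 100 ms for breaths (caps at 10 Hz) and 60 ms for
beats (caps at 1000 bpm), prominence 4× the median absolute deviation of
the cleaned trace, and a height floor of 20% of the 99.5th percentile of
the signal magnitude (the floor suppresses noise maxima inside long event
gaps, where a prominence criterion alone can pass them). All are
configurable; doubling the trace amplitude leaves event times unchanged.

PSTHs use 100-ms bins anchored so a bin edge coincides with light onset;
an event exactly on an edge joins the later bin. Rates are mean event
count per trial per bin width, in Hz for breaths and bpm for beats. The
per-mouse continuous mean rate (same binning, 5-s pre / 5-s post window)
feeds three summaries: **maximum change** (smooth with a 3-bin/300-ms
centered moving average, baseline = mean of the 5 s before onset ≡ 100%,
minimum over light-on plus 500 ms — the padding covers slow cardiac
dynamics and applies to all stimulus durations), **z-scores** (per-bin
z against the baseline mean and s.d., then the same smoothing; an exactly
constant rate is defined as z ≡ 0 rather than 0/0), and **epoch averages**
(5 s before / light on / 5 s after, unsmoothed). Binning conserves event
counts exactly, and a 100% drop magnitude requires a fully empty smoothed
window.

## Natural apneic arrests

Candidates are inter-breath gaps ≥ 500 ms (a default documented as the
assay's empirical 99th percentile of baseline inter-breath intervals;
`apnea_gap_percentile` recomputes it from user data). Acceptance requires
≥ 80% of the gap's activity samples inactive, with the same strict
threshold convention as above; gaps > 800 ms are flagged `is_long` (the
subset length-matched to 1-s stimulations). Boundary semantics are
"≥ 0.5 s" and "> 0.8 s" exactly as stated. Putative onsets subtract a
latency drawn uniformly from mean ± s.d. of the evoked latency to arrest
(defaults 110.83 ± 44.01 ms); onsets that would precede the recording are
clipped to 0 and flagged.

## Respiratory phase response

R = P/(P₋₁ + P₊₁) for the period containing each stimulus; the stimulus
phase is (t_stim − onset)/P ∈ [0, 1). Stimuli without complete neighboring
periods are skipped and counted. Bands: [0.4, 0.6] unaffected,
(0.6, 1.0] perturbed, anything else flagged "other". The boundary value
0.6 is assigned to *unaffected* — the bands are printed as overlapping at
0.6, and the tie is resolved toward the null. The statistic cannot
distinguish a phase advance with rhythm resetting from a phase delay
without resetting; both are "perturbed", and no further classifier is
offered. R is invariant to the time unit. Burst offsets (for delimiting
the expiratory phase) use a threshold crossing at 20% of the burst peak,
configurable.

## Anatomy

Densities divide summed counts by summed areas across section levels —
aggregation before division, so larger sections weigh more.
Colocalization is object-based with a strict < 5 µm centroid criterion;
candidate pairs are matched greedily by ascending distance, one-to-one, to
prevent a spot from being counted twice (the multiplicity handling of the
original spot-matching tools is unspecified; greedy nearest-first is the
package's choice). Min–max normalization of bouton densities is per
animal; injection-site ROIs (ipsi- and contralateral) are excluded from
the scale but reported on it, so their values may exceed 1. Output
fractions divide per-ROI counts by the animal's total over non-excluded
ROIs and sum to 1. Coexpression percentages pool counts within an animal
before averaging across animals.

## Synthetic sessions: what they emulate, and what they do not

`synthio` generates the study conditions each analysis assumes, with every
observable mirrored in a `GroundTruth` record:

* **Corridor trials** (150 frames/s, 4 s): paw x-displacements are
  sinusoids (default 4 Hz, 1 cm amplitude, left–right offset 180°) over a
  0.3 m/s translation; a 1-s light window triggers a full-body hold after
  a latency drawn from a truncated normal (110.83 ± 44.01 ms, truncated at
  0), and movement resumes 148.33 ms after light offset. `continue` mode
  resumes at the frozen phase. `reset` mode models the non-pause-and-play
  pattern: the paws reposition *during* the hold — a smooth ramp between
  30% and 55% of the light-on period — to a posture at a uniformly random
  new phase, and the cycle resumes from that posture; the trunk markers
  and forward position stay frozen throughout, so velocity-based arrest
  detection is unaffected. Optional heading rotation, postural drift with
  a continuous envelope, and Gaussian tracking noise.
* **Physiology sessions** (1 kHz): breathing as a renewal event train at
  4.79 Hz; stimuli remove (apnea) or thin (slowing) breaths and insert a
  rebound (6.16 Hz for 1 s, the post-stimulus rebound rate) before
  baseline resumes, with a 110-ms refractory floor keeping all intervals
  physiological. Flow is a stereotyped biphasic pulse per breath with the
  inspiratory minimum exactly at the event time — only event *times*
  matter downstream, absolute flow units are arbitrary. The heart train
  (646 bpm) slows by a configurable fraction from mid-stimulus to 500 ms
  past offset. Activity sits above the ground-truth threshold except
  during stimulation. Generated stimulus trains use uniform 45–90-s
  intervals gated on instantaneous activity > 0.1%.
* **Cylinder/open-field sessions** (25 Hz): behavior templates
  (single-peak ambulation, flat grooming, double-peak rearing), optional
  light-epoch suppression, and explicitly implanted sub-threshold arrest
  bouts.
* **Anesthetized recordings**: burst-onset trains with a tabulated
  perturbation Δ(φ); a stimulated period obeys P = T·(1 + Δ(φ)) with the
  stimulus placed at a uniform random phase, so the downstream
  phase-response curve should recover Δ exactly up to jitter.
* **Spot fields**: a chosen fraction of type-A spots get a type-B partner
  within a jitter radius; all other cross-type pairs are kept ≥ 2× the
  colocalization radius apart, making recovery unambiguous (generation
  fails loudly when the density makes that separation unsatisfiable).

These generators are stand-ins, not generative models fitted to data:
there is no biomechanical realism (no joint kinematics or EMG waveforms),
no video, sinusoidal rather than measured limb trajectories, stationary
rather than drifting baselines, and stereotyped rather than variable pulse
shapes. Passing recovery tests therefore demonstrates that the estimators
are correct under their stated assumptions — not that those assumptions
hold in any particular recording. Parameters that are setup-dependent in
real use (inactivity thresholds, peak-property values) must still be
chosen per rig.

## Problem sizes

The test suite and the acceptance script run at desk scale: corridor
recovery uses 50 pause-and-play and 200 reset trials of 600 frames,
latency recovery 100 trials, physiology sessions of 40–70 s with 2–4
stimuli, phase-response recovery 300 respiratory cycles (~60 stimuli), and
colocalization fields of 500 spots. These sizes put Monte-Carlo error well
inside the asserted tolerances while keeping the full suite under a
minute on one CPU.
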