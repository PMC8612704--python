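# Methods

## The cascade model

Each simulated axon is anchored by a latent *crisis time* — the moment
mitochondrial transport arrests — drawn from a truncated normal
(mean 5.5 h, sd 1.5 h, clipped to 3.5–10 h post-injury). The clip floor
matches the acquisition designs, which begin motility imaging at 3.5 h;
the spread reproduces the observed asynchrony of degeneration (calcium
onsets from under 4 h to nearly 10 h). Downstream events are placed by
independent normal offsets from their upstream event and clipped so the
order

ATP onset ≤ arrest ≤ TMRM drop ≤ calcium onset ≤ PS exposure ≤
degeneration ≤ fragmentation

holds by construction (ties allowed). Defaults, in hours unless noted:

| offset | mean | sd | rationale |
|---|---|---|---|
| arrest → calcium onset | 0.42 | 0.06 | cohort mean 0.42 ± 0.02 SEM at n = 9; sd = SEM·√n |
| TMRM drop → calcium (precedes) | 7.85 min | 4 min | calibrated by Monte Carlo so ~5/7 of axons show the drop one 10-min frame early and ~2/7 in the same frame |
| calcium → PS exposure | 0.51 | 0.1265 | cohort mean 0.51 ± 0.04 SEM at n = 10 |
| calcium → degeneration | 100 min | 0.25 h | reported ~100 min interval; sd chosen as a plausible per-axon spread |
| degeneration → fragmentation | 0.25 | 0.05 | endpoint definition is configurable; fragmentation here is the morphology endpoint |

The reported interval between calcium onset and the morphology endpoint
is stated two ways in the source material (~100 min to the beginning of
degeneration; ~1.4 h second-peak lead on fragmentation); the generator
uses 100 min for the sustained mRuby3-loss event and treats the
fragmentation offset as its own configurable parameter.

ATP follows a per-axon logistic decline (rate 1.2 ± 0.25 /h, floor-free)
anchored to the crisis: the level passes 0.95 at the ATP-onset event and
0.2 at arrest, so the curve is fully determined by the schedule. The
PercevalHR sensor maps relative ATP through a monotone piecewise-linear
response through (0, 0), (0.4, 0.3), (1, 1), i.e. a 60% ATP drop reads
as a 70% signal drop — the uncoupler (CCCP) calibration anchor. The
motility coupling scales the baseline mobile fraction (0.3) by a
logistic in relative ATP (threshold 0.5, width 0.15), with a hard stop
at the arrest time; per-bout track counts are binomial draws over a
constant 90 tracks (injury does not change mitochondrial number).

## Trace phenomenology

All channels are sampled on their own cadence (GCaMP6/TMRM/mRuby3/
Annexin-V every 10 min, PercevalHR every 5 min by default, 0.5 h of
pre-injury baseline) and multiplied by log-normal frame noise with
cv = 0.10, the documented frame-to-frame fluctuation; the noise cv is
assumed uniform across channels. Channel shapes: GCaMP6 shows a 2-frame
3-fold injury transient at t = 0 (the rapidly cleared first peak; its
spatial propagation is not modeled — traces are whole-axon scalars),
then a sustained plateau of 3.5 ± 0.5-fold from calcium onset. TMRM is
stable, steps to 50% of baseline at the drop time, then declines
steadily (0.15/h). mRuby3 steps to 40% at degeneration and decays to
near zero by fragmentation. Annexin-V sits at a small positive
background floor and jumps to 2.2-fold of it at PS exposure, saturating
to 4-fold; the immediate jump past the 2-fold readout guarantees the
detector's one-frame round-trip property at zero noise.

## Detectors and numerical choices

* Boundary semantics follow the wording of each criterion: "two-fold or
  greater" is ≥; "more than 30% / 50% / 5 µm" is strictly >; "less than
  0.2 DI" is strictly <.
* Calcium, Annexin-V and continuity calls require 2 consecutive
  qualifying frames (sustain rule) to debounce the ~10% frame noise; the
  calcium detector also excludes the first 0.5 h to skip the injury
  transient. The TMRM call requires the signal to stay below
  (1 − 30%) of the pre-drop level for the sustain window; without this
  confirmation the log-normal noise tail would false-call on roughly
  one in six event-free axons. All sustain windows and thresholds are
  arguments.
* Baselines are means over the pre-injury window [−0.5 h, 0); the upper
  bound is exclusive so the t = 0 frame (which carries the injury
  transient) never leaks into the baseline.
* The ATP-sensor decline uses the frame at or latest before the query
  time (imaging is discrete; no interpolation).
* DI: Otsu global binarization, 8-connected components, circularity
  4πA/P² with the perimeter from skimage regionprops, fragment-like iff
  circularity ≥ 0.2, particles under 4 px ignored, DI = fragment area /
  total area. These internals are config-exposed; they are chosen so
  the stated 0.2/0.4 threshold behaviors hold on the synthetic
  morphologies (thin 8-px strips score ≈ 0.02 circularity; rendered
  fragments score ≈ 1).
* Motility: net displacement is the endpoint-to-endpoint distance (not
  path length), matching the "net displacement" criterion and making
  the 5-µm boundary exactly testable; tracks entering/leaving the field
  are classified on observed frames only. Arrest is the first
  zero-mobile bout followed only by zero-mobile bouts, guarding against
  single-bout flukes.
* Track extraction (for image input): per-frame peaks above an Otsu
  threshold, greedy nearest-neighbour linking with a 2 µm/frame step
  bound, minimum 10 observed frames. Kymograph scoring of crossing or
  unresolvably close tracks is out of scope — the fidelity guarantee
  (≥ 99% label agreement) applies to resolvable tracks.
* ΔT is signed (later − earlier; positive = claimed order), axons
  missing either event are excluded pairwise, SEM = sd/√n. Ordering
  fractions bin detected times to acquisition frames at the slower
  channel's cadence. R² is unadjusted OLS (scipy linregress).

## Acquisition designs and quantization

Detected event times are ceiling-quantized to their channel's frame
grid. In each dedicated experiment design the two compared readouts
share one grid — bout starts and calcium frames both on a 5-min grid in
the arrest-vs-calcium design (contiguous 300-s bouts with calcium read
once per bout), and both 10-min channels simultaneous in the two-channel
designs — so the quantization biases cancel in expectation and the
recovered ΔT means are unbiased. Mixing cadences (as in the generic
pipeline run over all channels at once) shifts ΔT by up to half the
cadence difference; the analysis drivers note this where it applies.

## Calibration of the ATP–motility correlations

The observable correlations (ATP decline vs stalling, decline vs
time-to-arrest, across n = 9 axons) emerge from three frozen noise
sources: the crisis-time spread, the per-axon ATP rate sd (0.25 /h), and
measurement noise (frame cv 0.10 on the sensor; binomial sampling of 90
tracks per bout). These were set once by a Monte-Carlo sweep to yield
mean R² ≈ 0.61 and ≈ 0.76 over replicate cohorts and not revisited.
Because the two percent-drops are different nonlinear monotone
transforms of the same latent ATP level, their linear R² stays below 1
even with all noise off (≈ 0.95–0.99); and although the coupling
guarantees the ATP drop exceeds the motility drop in expectation for
every axon, finite-sampling noise can produce apparent violations in a
single noisy cohort — the analysis reports that count honestly rather
than suppressing it.

## What the generator does and does not emulate

It reproduces: the cascade ordering and its cohort-level intervals, the
onset asynchrony, the documented frame noise, channel cadences, bout
geometry, constant mitochondrial number, ATP–motility coupling strength,
and DI threshold behavior on morphology images. It does not emulate:
spatial calcium-wave propagation, photobleaching, focus drift,
segmentation artifacts on real micrographs, pharmacological
perturbations (beyond the CCCP anchor used to calibrate the ATP sensor),
or genotype contrasts beyond an event-free control mode. Passing the
round-trip suites therefore demonstrates that the detectors implement
their criteria faithfully and recover the generative statistics at
realistic noise — not that they are robust to every artifact of real
microscopy.

## Problem sizes

The reproduction script averages 100 replicate cohorts for the ΔT
targets, 500 for the ordering fraction, and 200 for the regressions —
sizes at which the replicate-mean standard errors are well below each
statistic's tolerance; the test suite uses 30/200/200 replicates for
the same checks. The library modules are the interface (the numbered
analysis drivers play the role of pipeline subcommands); no separate
shell CLI is shipped.
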