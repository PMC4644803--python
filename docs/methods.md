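# Methods

This note documents the models, estimators and design choices behind
`tonomap`: what the synthetic generator simulates (and deliberately does
not), how each receptive-field metric is defined, and where genuinely open
decisions were settled.

## Stimulus protocol

The default protocol is 66 pure tones covering 1–70 kHz, eight intensities
0–70 dB SPL in 10-dB steps, three trials per tone–level pair, 25-ms tones with
5-ms ramps at 2/s, and 1-ms PSTH bins.  A 66-tone, 1–70 kHz grid is not
consistent with a literal 0.1-octave step (that would give 62 tones); we honor
the tone count and the endpoints, giving geometric spacing with a step of
log2(70)/65 ≈ 0.0943 octave.  Each simulated presentation carries 50 ms of
pre-stimulus baseline and 100 ms after onset.

## Synthetic generator

**Geometry.** One animal = two 8×8 penetrations (375 µm between columns,
500 µm between rows), 128 sites, laid side by side along the rostro-caudal
(x) axis.  Real experiments occasionally yield other totals per animal (e.g.
cohort totals that are not multiples of 128, as when array placements
partially fail); the generator keeps the idealized 128 and documents the
simplification here.

**Tonotopic gradient.** True CF obeys `log2(cf_kHz) = log2(cf0) + g·x_mm + ε`
with `ε ~ N(0, σ_jitter)`.  By default `g` is chosen so the noiseless gradient
spans exactly 1–63 kHz across the map — the same range the tonotopic index
normalizes over — so a zero-jitter map lies on the diagonal up to grid
quantization (index ≈ 0.003).  With probability `hi_freq_bias` a site's CF is
instead drawn log-uniformly from 10–50 kHz, which simultaneously
over-represents high frequencies and scatters the map; the preset values
(0.135 control, 0.36 VPA) are solved from the reported band occupancies
(46.28% vs 60.29% of sites in 10–50 kHz) given the 37.9% that the uniform
gradient itself puts in that band.

**Receptive fields.** Each responsive site has a frequency-dependent
threshold `thr(f) = thr + (20/bw10)·|log2(f/cf)|`, so the supra-threshold
span 10 dB above the tip equals `bw10` exactly.  Inside the supra-threshold
region the evoked rate is `gain·(I − thr(f) + 10 dB)`, saturating at 100 Hz,
confined to the window `[latency, latency + tone + 10 ms]`, on top of a 2-Hz
Poisson baseline.  The +10 dB offset makes the response *at* the threshold
intensity detectable rather than identically zero; without it no estimator
could recover the true threshold on a 10-dB grid, and BW10 — measured 10 dB
above the *estimated* threshold on a curve whose span grows by bw10/10 per
dB — would be biased by design rather than by data.  For the same reason true
thresholds are sampled on the intensity grid and true CFs snapped to the tone
grid: the generative-consistency tests then demand exact CF and threshold
recovery on noise-free surfaces, and BW10 within two grid steps (symmetric
edge truncation loses at most one step per side).

**Shapes.** Single v-shaped fields use the V above.  Flat fields hold
`thr(f) = thr` constant over a 1.2–2.5 octave span before the arms rise.
Multi-peaked fields are the minimum of two Vs with narrow arms
(width `min(bw10, 1)` oct), separated by 1.6–2.4 octaves, secondary threshold
+10 dB: with 10-dB intensity quantization this provably leaves the saddle at
least one step above the secondary apex, which is exactly what the
classifier's 10-dB prominence rule needs.  Wider arms with the same apex
separation produce saddles shallower than 10 dB — such composites are then
*correctly* read as one broad peak, so the generator only emits multi-peak
truths the definition itself can distinguish.

**Condition presets.** `control` and `vpa` encode reported group means: BW10
1.24 vs 3.02 oct, latency 14.97 vs 10.27 ms, v-shaped fraction 93.47% vs
76.25%, high-threshold (>50 dB) fraction 9.99% vs 37.58%, CF jitter 0.25 vs
0.80 oct.  Thresholds are drawn from normals chosen so that
`P(rounded thr > 50 dB)` equals the printed fraction exactly — control
N(30, 19.51), VPA N(50, 15.79) — then rounded to the grid.  Site-level SDs
for BW10 (0.30/0.60 oct) and latency (1.5 ms) are the package's choices; the
published ± values are SEMs over animals, not site-level spreads.  15% of
sites per penetration (drawn from the grid perimeter) are non-AI: half
respond only above 50 dB, half not at all, mimicking the fields surrounding
AI.

**Seeding.** Per-animal and per-site generators derive from one master seed
via `numpy.random.SeedSequence.spawn`, so identical seeds give byte-identical
datasets and partial regeneration is stable.

## Estimators

**FRA significance.** Per (frequency, intensity) cell, spikes in the 5–50 ms
response window are pooled over trials and tested against a Poisson null with
the pooled pre-stimulus baseline rate (upper tail, p < 0.01); significant
cells must additionally belong to a 4-connected cluster of ≥3.  No per-cell
criterion is standard in the mapping literature; the cluster rule suppresses
the isolated false positives expected among 528 cells per site.  The 5–50 ms
window brackets reported AI latencies (6–20 ms) plus the 25-ms tone.

**CF/threshold.** Threshold = lowest intensity row with a significant cell;
CF = the significant frequency there, median (lower median when even) over a
flat tip.  When two apexes tie at the threshold row the lower-frequency run
wins; an apex with a strictly lower threshold wins outright because it alone
defines the row.

**BW10** = `log2(f_max/f_min)` over significant cells in the row 10 dB above
threshold; 0 for a single cell; undefined when that row is untested (threshold
at the top intensity) or empty.  "Responses" means significant cells, not any
nonzero count.

**Latency.** The PSTH pools all presentations at intensities ≥ threshold
(pooled rather than per-stimulus — the per-stimulus alternative is noisier at
3 trials).  Criterion: first run of ≥2 consecutive bins at or above
`baseline mean + 4·SD` of the PSTH's own pre-stimulus bins, searched 5–50 ms
after onset.  Requiring 2 bins (configurable to 1) rejects single-bin noise
crossings at 1-ms resolution.

**Irregularity index** is computed on the binarized significance mask (the
index is then scale-free); the conventional cutoff of 2 separates regular
from irregular fields.  For a compact a×b rectangle the index reduces to
`(a+b)/(2√(ab)) − 3`, which the tests verify exhaustively.

**Shape.** Apex finding runs on the 3-column median-filtered per-column
threshold curve (prominence ≥ 10 dB, separation ≥ 0.3 oct); more than one
apex ⇒ multi.  The minimal-threshold plateau is measured on the *raw* curve:
the median filter erases one-column tips, and measuring the plateau on the
filtered curve would misclassify every v-shaped field broader than one octave
as flat.  Plateau > 1 octave ⇒ flat, else single v.

**AI delineation.** AI = responsive, CF-defined, not VAF-like (significant
only below 30 dB SPL), and threshold ≤ 50 dB or ≥2 four-adjacent
low-threshold neighbors (the neighbor clause implements "strong responses to
low-intensity tones" as a regional rather than strictly per-site property).
Against generator truth this recovers AI membership at ≥85% (the residual
errors are perimeter high-threshold sites adjacent to healthy AI).

**Tonotopic axis and index.** The axis is the least-squares line through the
AI sites.  The default fit is the principal axis (total least squares):
unlike the y-on-x regression it makes positions — and hence the tonotopic
index — exactly invariant under rigid rotation of the map coordinates, which
the test suite asserts; ordinary regression with an axis swap for steep maps
remains available (`axis_fit="ols"`).  Positions are min-max normalized;
orientation is flipped if needed so position correlates non-negatively with
CF (synthetic maps carry no anatomical rostral marker).  CFs are normalized
linearly in log frequency over 1–63 kHz, clipping (not discarding) CFs above
63 kHz.  The index is `mean(|pos − cf|)/√2`.  The axis is fitted to AI sites
only.

**Cohort statistics.** Percentages are per animal over its responsive AI
sites, then averaged across animals (`pooled_group_percentages` offers the
site-pooled alternative).  Frequency bands default to 1–4.3, 4.3–10, 10–50
and 50–70 kHz — the bands nameable from the reported contrasts; the edges are
configurable.  Group tests are pooled-variance two-tailed Student's t with
df = n1 + n2 − 2, NaN animals dropped with df reduced, and a degenerate-
variance guard (equal means ⇒ p = 1, unequal ⇒ p → 0).  Repeated-measures
ANOVA across bands is out of scope; the per-animal × band table the summaries
emit is exactly what a standard ANOVA routine consumes.

## Validation experiments

`tonomap.validation` pins one truth at a time: `bw10_recovery` fixes true
BW10 (zero spread, high gain) on 500 single-peaked sites whose CFs are
confined to the interior of the tested range (gradient 0.3 oct/mm from
4 kHz, jitter 0.1 oct, no high-frequency bias) — an edge-truncated arm
measures a clipped span by construction, which would test the protocol rather
than the estimator; `latency_recovery` fixes true latency on 200 sites;
`jitter_tonotopic_index` sweeps CF jitter over truth-level all-AI maps,
isolating the geometric mechanism from estimation noise.  Problem sizes (500
and 200 sites, 20 replicates per jitter level, a 6-vs-8 directional cohort)
are the package's standard test scales and complete in seconds to tens of
seconds each.

## What the generator does not model

No spike waveforms, LFPs, adaptation, trial-to-trial latency jitter (off by
default), ramp-shaped onsets, or anatomical registration; non-AI surrounds
are reduced to "high-threshold or silent" border sites rather than modeled
PAF/VAF fields.  Passing recovery tests therefore show that the estimators
invert this generative family faithfully — not that they are robust to every
pathology of real recordings (electrode drift, bursting, correlated noise).

## Numerical conventions

Undefined metrics are `None`/NaN (empty CSV cells), never sentinel numbers.
Coordinates are µm; bin offsets are bin start times in ms relative to tone
onset (baseline bins negative).  Spike tables are stored sparsely (nonzero
bins only) with a dense-reconstruction rule of zero elsewhere.  All outputs
are deterministic given the seed; the run log carries no timestamps so reruns
are byte-identical.
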