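# Methods

This note documents the models, parameters, and numerical choices behind
`neurosync`. The package re-implements, as a tested pipeline, a joint
calcium-imaging / microelectrode-array (MEA) analysis of emerging
synchronous activity in stem-cell-derived neural cultures, together with a
synthetic-data generator that supplies ground-truth recordings so every
stage is verifiable without access to raw experimental data.

## The measurement model

A culture is observed two ways at once:

* **Calcium imaging** (2 Hz, Fluo-4-style intensity): each neuron appears as
  a soma-sized bright blob whose intensity rises rapidly when the cell
  fires and decays over seconds. Traces are min-max normalized per cell, so
  intensity 1 is the cell's maximum over the recording (usually its
  response to depolarizing agents near saturation of the indicator).
* **MEA voltage** (60 electrodes, 8×8 grid, 200 µm pitch, one internal
  reference): action potentials appear as brief ~1-ms biphasic deflections
  a few noise standard deviations above the background.

A *network event* is a transient, network-wide surge of activity — a
near-simultaneous calcium rise across cells and a spike-rate surge across
electrodes — separated by quiescent intervals. The pipeline quantifies
these events and how pharmacology (GABA, the GABA_A antagonist bicuculline,
the gap-junction blocker carbenoxolone, glutamate, high potassium) changes
them.

## Synthetic-data generator (`synth`)

The generator emulates the statistical structure the analysis assumes; it
is first-class, tested code, not a fixture.

**Event schedules.** Network events follow a renewal process whose
intervals are uniform on `(1±0.45)/rate`; at the default network rate of
0.03 Hz the intervals span ~18–48 s, i.e. roughly two events per minute
with irregular pacing. Three modes:

* `synchronous` — each cell keeps each network event with probability 0.8
  (cells do not join every event) jittered by ≤0.5 s; no independent
  activity between events.
* `loosely_synchronous` — participation 0.4, jitter 2 s, plus independent
  per-cell Poisson events at 0.02 Hz (substantial between-event activity).
* `asynchronous` — independent per-cell Poisson events only (0.02 Hz).

**Calcium rendering.** Somata are flat-top super-Gaussian profiles
(`exp(-½ (r/σ)⁴)`, σ = 5 px with ±15 % spread) on a jittered
non-overlapping grid — real somata are discs with fairly flat interiors,
not point-spread-limited Gaussians, and their intensity maxima are
plateau-like, which the marker pipeline exploits. Each scheduled event adds
a calcium transient (linear rise 1 s, exponential decay τ = 4 s; amplitudes
vary ±40 % around 0.12 of the cell's brightness scale). The kinetics are
stated defaults, not fitted values: with them, network calcium peak widths
fall in the several-second range typical of population events, while MEA
rate peaks are much narrower. Pharmacological epochs act
phenomenologically:

* GABA: a sustained baseline shift per response class — strongly
  depolarized +0.5, weakly depolarized +0.15, no response 0, inhibited
  −0.08 (fractions of the cell's brightness scale) — with strongly
  depolarized and inhibited cells dropping out of network events during the
  epoch. Default class mixture 5/25/45/25 %.
* K⁺: a sustained +0.3 rise in all neurons. A configurable fraction of
  "non-neuron" blobs lacks this response to exercise the viability filter.

Spontaneous transients are deliberately small (~⅓) relative to the evoked
K⁺ response: normalization is to the whole-recording maximum, which evoked
depolarization dominates, so spontaneous event amplitudes on normalized
traces land in the 0.1–0.4 range — the regime the 0.025 prominence
criterion is designed for. Noise is i.i.d. Gaussian per pixel and frame
(default sd 0.02 on a 0.2 background, ~0.5-peak cells); there is no
photobleaching, drift, or optics model by default.

**MEA rendering.** Spikes are a biphasic 1-ms template (derivative of a
Gaussian, negative peak normalized to −1) inserted at Poisson times: dense
bursts around each network event (mean 20 spikes/electrode/event, Gaussian
spread 0.5 s) over a sparse 0.1-Hz background, in Gaussian noise (default
3 µV sd, default amplitude 30 µV = 10σ). The default sampling rate is
10 kHz; 50 kHz is supported but slow. An optional common-mode waveform
(e.g. a perfusion artifact) is added identically to all electrodes. The
reference electrode carries noise (and common mode) only.

**What passing tests do and do not show.** The generator has isolated,
non-overlapping somata, stationary cells, white noise, and stereotyped
transients. Recovery and retention results on it validate the *mechanics*
of the pipeline (marker generation, watershed, assignment, filtering,
thresholds) — not robustness to overlapping cells, neurite signal, motion,
bleaching, or correlated noise, none of which are modeled.

## MEA analysis (`mea`)

1. **Median reference**: subtract the across-electrode median voltage at
   every sample; removes any common-mode waveform exactly.
2. **Bandpass** 200–3000 Hz, Butterworth order 3, zero-phase
   (forward–backward), so spike times are not biased by filter delay.
3. **Detection** in 30-s windows with 80 % overlap: per window the noise
   scale is the robust estimate σ = median(|x|)/0.6745 and the threshold
   5σ. (The alternative reading, 5 × median(|x|), is available via
   `threshold_mode="median"`.) Crossings are detected on |x| — both
   polarities, since polarity is layout-dependent — and each contiguous
   supra-threshold run yields one spike at its extremum. Duplicates from
   overlapping windows are merged by keeping the first detection within the
   1.5-ms dead time, enforced per electrode. Each spike stores a cut-out
   from 1 ms before to 2.2 ms after the extremum (edge-padded at recording
   boundaries).
4. **Rates**: per-electrode 2-s-bin rates, exported as grayscale with
   white→black spanning 0–0.5 Hz (values above 0.5 Hz clip to black);
   a combined rate over all non-reference electrodes in sliding 10-s
   windows stepping 2 s. The combined rate is min-max normalized before
   peak detection because the 0.05 prominence criterion for network events
   is unitless; the un-normalized rate in Hz is returned alongside.

## Segmentation (`ca_seg`)

Reference images are non-overlapping 50-frame means (one segmentation per
25 s at 2 Hz; a sliding mode exists), min-max scaled to [0, 1] (a constant
image maps to zeros).

**Foreground markers**: morphological opening with a disk (radius 6 px,
roughly a soma radius at 10×; configurable) → top-hat residual (image −
opening) → grayscale erosion with a disk of radius 2 → regional maxima →
binary erosion then dilation with a 3×3 neighborhood. Two numerical
choices make this robust on continuous-valued images: (i) *regional maxima
with plateau tolerance* — every pixel within `maxima_h` (default 0.45) of
its regional peak, computed as the h-dome of a grayscale reconstruction —
because the exact maxima of a smooth image are single pixels, which the
3×3 opening would annihilate; (ii) a *high-intensity gate*
(`marker_min_intensity`, default 0.1): erosion of pure noise creates wide
plateau maxima too, but they sit far below the soma residual level.

**Background markers**: foreground pixels are set to the image median
(configurable), the image is Otsu-binarized, and the watershed ridge lines
of the Euclidean distance transform of the binary image — the midlines
between cells — become background markers, dilated by a disk of radius 2;
any overlap is removed from the foreground so the marker sets never touch.
A degenerate (constant) image yields an all-border background marker and a
warning.

**Final watershed**: gradient magnitude `sqrt(gx² + gy²)` from the Sobel
horizontal kernel and its transpose (replicate padding), flooded with
minima imposed at both marker sets (Meyer watershed, with watershed
lines). Regions grown from background markers become label 0; the rest are
labeled 1..K with unweighted centroids (pixel-centered, 0-based,
row/column order).

## Tracking (`ca_track`)

Per-step detections are linked by minimum-cost assignment on raw Euclidean
centroid distances (units: pixels). Distances above the gating threshold
(20 px) cost the gating cost (5000); leaving a detection or track unlinked
costs 500; a pair costing more than the non-assignment cost is never
linked. The assignment is solved exactly via the standard augmented-matrix
reduction. Unmatched detections open new tracks; unmatched tracks persist
invisibly and keep competing. Tracks younger than 20 segmentation steps or
visible in fewer than half their steps are discarded. Traces are sampled
per original frame (full 2-Hz resolution) as the mean intensity over the
track's region — the region from the owning segmentation step, carried
forward over missing steps — then min-max normalized to [0, 1] (constant
traces map to zeros). No motion model, merge/split handling, or sub-pixel
registration is attempted.

## Trace analytics (`traces`)

* **QC**: (i) "noisy" — the 0.0013–0.02 Hz band-passed trace has sd >
  0.05. The sd is evaluated on the baseline epoch by default: evoked
  pharmacological responses (especially the K⁺ step) are genuine signal
  with large in-band energy, and with the 0.0013-Hz edge the filter
  response spans hundreds of seconds, so filtering the full trace would
  smear the K⁺ step across the baseline and reject nearly every responsive
  neuron. Full-trace mode is available (`qc_sd_window="full"`). (ii)
  "inactive" — the normalized fluorescence rises by < 10 % during the K⁺
  epoch, relative to the median level over the 30 s before application. A
  missing K⁺ epoch skips this filter with a warning. All removals are
  logged with reasons.
* **Peaks**: local maxima with topographic prominence ≥ 0.025 (the same
  criterion for single-cell and network traces); width is full width at
  half prominence; peaks carry time, height, prominence, width.
* **Network trace**: per-trace 0.005–0.2 Hz bandpass (Butterworth order 2,
  zero-phase, as are all trace filters — the cutoffs are the specified
  quantities, the order a stated default), per-trace min-max
  normalization, sum, min-max normalization of the sum.
* **Epoch metrics**: per-epoch median peak prominence and inter-peak
  intervals; change = epoch − baseline; relative change = change /
  baseline (NaN, never infinity, when a baseline metric is zero or an
  epoch has no peaks). For the slow-acting gap-junction blocker only the
  final 3 min of the application window are analysed (configurable).
* **Excitatory GABA response**: low-pass the trace at 0.024 Hz and subtract
  the baseline-epoch sum from the GABA-epoch sum. Because baseline epochs
  (≥10 min) are much longer than applications (3–4 min), each sum is
  duration-normalized by default (per-sample mean × a 180-s reference);
  raw sums via `gaba_reference_duration_s=None`.
* **Histograms**: responses binned (prominence 0.005, intervals 1 s,
  changes 5 %) as percentages of neurons with cumulative or
  reverse-cumulative sums ending/starting at exactly 100 %.

## Classification (`netstats`)

The synchronous / loosely-synchronous / asynchronous labels operationalize
a judgment that is usually made by eye from aligned trace rasters. The
rule is declared and configurable, and the label is always reported with
its diagnostics, never alone:

* network-peak rate (prominence-0.025 peaks per 5 min);
* mean event participation — the fraction of cells whose
  transient-timescale signal (0.05–0.5 Hz band) within ±2 s of a prominent
  network peak (prominence ≥ 0.3) exceeds 5 robust noise standard
  deviations (σ = median(|x|)/0.6745 per cell);
* in-event / out-of-event activity ratio — pooled mean square of that band
  inside event windows (extended 8 s past each event to cover the
  transient tail) versus outside.

Default rule: *asynchronous* if fewer than 2 network peaks per 5 min **or**
mean participation < 0.2; *synchronous* if participation ≥ 0.5 **and**
ratio ≥ 3; *loosely synchronous* otherwise; *undetermined* below 10
traces. Classification uses the baseline epoch when a protocol is
supplied: spontaneous pattern is a baseline property, and evoked steps
elsewhere would dominate the per-trace normalization. Two measurement
choices matter here: participation uses a faster band than the network
trace because the 0.005-Hz edge rings between events, and a robust
per-cell threshold because the 0.025 prominence criterion sits at the
noise floor of min-max-normalized filtered traces.

Statistics: paired comparisons use the two-tailed Wilcoxon signed-rank
test (zero differences dropped; exact null for ≤ 25 nonzero differences,
normal approximation above; all-zero differences flagged, not raised);
correlations are Pearson product-moment with two-tailed p. No
multiple-testing correction is applied; p-values are reported raw.

## Benchmark scales and determinism

Standard benchmark sizes, chosen as this package's own test scale: movies
of 640 s at 2 Hz (baseline 540 s, K⁺ 560–620 s), 448×400 px for 200 cells
or 320×288 px for 50; MEA recordings of 300 s at 10 kHz on 60 electrodes.
Every stochastic component takes a seed and is bit-reproducible under it;
movies render in float32 (the noise floor is far above float32
resolution).

Known limitations: watershed regions extend beyond the soma toward the
background ridge, so region area overestimates soma area (centroids are
unaffected); the tracker has no motion model and will swap identities if
cells approach within the inter-frame drift; the classification rule is a
declared operationalization, not a validated clinical criterion; and the
generator omits several realities of live imaging (listed above), so
quantitative agreement on synthetic data bounds, but does not guarantee,
performance on real recordings.
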