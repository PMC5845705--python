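# neurosync

Joint calcium-imaging and microelectrode-array (MEA) analysis of emerging
network synchrony in stem-cell-derived neural cultures — with a synthetic
ground-truth generator that makes the entire pipeline verifiable.

## What this is for

Developing neural networks self-organize from sporadic single-cell firing
into *network events*: brief, network-wide bursts of activity separated by
quiet intervals. Characterizing this transition — and how GABA, GABA_A
blockade, and gap-junction blockade modulate it — requires analysing the
same culture at two scales: single-cell calcium imaging (2 Hz movies of a
Fluo-4-loaded monolayer) and extracellular voltage on a 60-electrode MEA
(8×8 grid, 200 µm pitch). This package provides the full analysis chain
for both modalities, for researchers working with cultured-network
recordings or building analysis methods against ground truth:

* **`synth`** — paired fluorescence movies and MEA recordings with known
  cell positions, event times, spike times and per-cell drug-response
  classes, in three network modes (synchronous / loosely synchronous /
  asynchronous);
* **`mea`** — median referencing, 200–3000 Hz zero-phase bandpass,
  threshold spike detection with the robust noise estimate
  σ = median(|x|)/0.6745 and a 5σ threshold (1.5 ms dead time, stored
  cut-outs), 2-s rate rasters and a sliding-window network firing rate;
* **`ca_seg`** — soma segmentation by foreground/background
  marker-controlled watershed on the Sobel gradient;
* **`ca_track`** — gated Munkres (Hungarian) centroid tracking and
  extraction of per-cell fluorescence traces normalized to [0, 1];
* **`traces`** — trace quality control, network activity traces, peak
  detection by topographic prominence (criterion 0.025), per-epoch
  pharmacology metrics, excitatory-GABA scoring, response histograms;
* **`netstats`** — activity-pattern classification with explicit
  diagnostics, Wilcoxon signed-rank and Pearson statistics, and report
  tables.

The quantities at the core: a trace's activity peaks are local maxima with
topographic prominence `p = h − max(min_left, min_right)` above the higher
flanking minimum separating them from higher terrain; a network trace is
`minmax(Σ_i minmax(BP_{0.005–0.2 Hz}(F_i)))` over cells `i`; spikes are
crossings of `|v| > 5σ̂` with `σ̂ = median(|v|)/0.6745` per 30-s window.
Pharmacological effects are summarized as change and relative change of
median peak prominence and inter-peak interval versus baseline, and the
per-cell excitatory GABA response is the difference of the 0.024-Hz
low-passed trace summed over the GABA epoch versus baseline.

See `docs/methods.md` for the full model description, parameter defaults,
and numerical choices.

## Worked example

Simulate a synchronously active 50-cell culture (540-s baseline, then a
high-K⁺ viability pulse), run the full imaging pipeline, and classify it:

```python
import numpy as np
from neurosync import synth, ca_track, traces, netstats
from neurosync.protocol import qc_protocol

protocol = qc_protocol()  # 540 s baseline, high-K+ at 560-620 s
movie, truth = synth.simulate_recording(
    "synchronous", duration_s=640.0, n_cells=50,
    width_px=320, height_px=288, protocol=protocol, seed=11,
)

trace_df, tracks, segmentations = ca_track.track_movie(movie)
kept, removed = traces.qc_filter(trace_df, protocol)
print(f"cells placed: {truth.n_cells}, tracks kept: {len(tracks)}, "
      f"traces after QC: {kept.shape[1]} ({len(removed)} removed)")

net = traces.network_trace(kept.iloc[:1080])  # baseline segment
peaks = traces.find_peaks(net, min_prominence=0.025)
intervals = np.diff(traces.peak_times(peaks))
print(f"network peaks: {len(peaks)}, median inter-peak interval: "
      f"{np.median(intervals):.1f} s (generator events every "
      f"{truth.schedule.median_interval_s():.1f} s)")

label = netstats.classify_network(kept, protocol=protocol)
print(f"classification: {label.label} "
      f"(participation {label.mean_participation:.2f}, "
      f"in/out activity ratio {label.activity_ratio:.1f})")
```

Output:

```
cells placed: 50, tracks kept: 50, traces after QC: 50 (0 removed)
network peaks: 16, median inter-peak interval: 36.5 s (generator events every 38.0 s)
classification: synchronous (participation 0.82, in/out activity ratio 5.3)
```

All 50 somata are segmented and tracked, both quality-control filters pass
every responsive neuron, the 16 detected network peaks recover the
generator's event pacing to within a couple of seconds, and the recording
is classified synchronous with its diagnostics (82 % of cells participate
in the average network event; single-cell activity is 5× higher inside
events than between them).

The same stages are available from the shell:

```bash
neurosync simulate --mode sync --duration 640 --n-cells 50 --seed 11 --out-dir sim/
neurosync track --in sim/movie.tif --out traces.csv
neurosync classify --traces traces.csv --protocol sim/protocol.yml
neurosync analyze-mea --in sim/recording.h5 --out-dir mea_out/   # with --with-mea
```

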