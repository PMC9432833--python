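# socalim

Social-behavior-tuned neural ensemble analysis for head-mounted two-photon
calcium imaging, exercised end-to-end on synthetic sessions with known
ground truth.

The pipeline covers:

- **behavior** — trajectory smoothing (running median), distance-threshold
  exploration-epoch detection, nearest-timestamp alignment of 30 Hz behavior
  onto the 9.76 Hz imaging clock, exploration-time ratios.
- **extraction** — soma segmentation from fluorescence video (temporal
  activity image + LoG blobs + adaptive threshold + SNR/area filters),
  annular-ring-subtraction ΔF/F (`F_ROI = F_raw − F_b`,
  `F_sig = F_ROI − α·F_con`, `ΔF/F = F_sig / mean(F_ROI)`), and cross-day
  neuron matching (centroid < 3 μm AND Jaccard overlap > 0.75).
- **classify** — the permutation-null similarity test
  `S = B·C / (|B|² + |C|²)` against k = 1000 full shuffles of the social
  vector, with SAN / SIN / Other labels at the 99.17 / 0.83 percentiles;
  peri-event (±4 s) average traces; high-pass (50-order FIR, 1 Hz) noise
  estimation; event-engagement statistics.
- **tuning** — event-associated neuron flags per event type
  (`c_E − c_NE > β·noise_NE`, stage-specific NE), NewPN/OldPN preference by
  set difference, behavioral correlation matrices.
- **kinetics** — socially activated epoch detection (peak within 4 s after
  onset), activation probability P_up, rise time and amplitude.
- **network** — state-spliced Pearson correlation networks and signed
  weighted clustering coefficients (Zhang–Horvath on cube-rooted weights;
  Onnela optional).
- **synthetic** — deterministic generators for behavior sessions, ΔF/F
  matrices with planted tuning classes (double-exponential GCaMP6s-like
  kernel), and rendered uint16 videos (somata + shared neuropil field) with
  full ground truth.

## CLI

```sh
socalim simulate --seed 1 --outdir sim        # synthetic session + ΔF/F
socalim extract video.tif --outdir ex         # segment + ARS ΔF/F from TIFF
socalim classify sim/dff.h5 sim --out labels.csv
socalim tune     sim/dff.h5 sim --out tuning.csv
socalim kinetics sim/dff.h5 sim --out kinetics.csv
socalim network  sim/dff.h5 sim --state social --out nodes.csv
socalim run-all --config cfg.yaml --seed 1 --outdir run
```

`run-all` executes behavior → classify → tuning → kinetics → network and
writes per-neuron tables, ensemble ratio tables and a manifest
(`manifest.json`) with the seed fan-out and config hash; identical
config + seed reproduces all CSVs bit-identically. A YAML config mirrors
`socalim.pipeline.RunConfig` (simulation parameters plus α, β, k,
percentiles, windows, seed).

## Layout

```
src/socalim/
  core.py        shared types (sessions, epochs, ΔF/F matrices)
  behavior.py    smoothing, epoching, clock alignment
  extraction.py  segmentation, rings, ARS ΔF/F, cross-day matching
  classify.py    permutation-null SAN/SIN, event averages, engagement
  tuning.py      EAN flags, NewPN/OldPN set logic, correlation matrices
  kinetics.py    activated epochs, P_up, rise time, amplitude
  network.py     spliced correlations, signed clustering
  synthetic.py   synthetic sessions / ΔF/F / rendered video + ground truth
  pipeline.py    config-driven end-to-end runs
  cli.py         click CLI (`socalim`)
  io.py          CSV / HDF5 / TIFF readers and writers
```
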