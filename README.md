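# ecogmap

Motor-cortex mapping from electrocorticography (ECoG). The package scores
each electrode two ways:

- **Temporal map (ETAM)** — trials are band-passed to the slow-potential
  range (0.05–3 Hz), epoched around EMG onset, and each trial's 0–500 ms
  task component and −2000…−1500 ms rest component are Pearson-correlated
  with a 500 ms movement-potential template. The two correlation sets are
  compared with a signed between-over-total sum-of-squares statistic
  (positive when the cortical potential is negative-going) and a balanced
  one-way ANOVA, Bonferroni-corrected across channels at α = 0.01.
- **Spectral map (EFAM)** — per trial, a 1 s post-onset task segment and a
  −3500…−2500 ms rest segment are Hanning-tapered, Fourier-transformed at
  1 Hz resolution, log-normalized by the ensemble mean per frequency, and
  summed over a low (8–32 Hz) and high (66–90 Hz) band. Band sums are
  compared with a signed squared point-biserial weight and the same ANOVA
  scheme; a channel is positive if either band is significant.

Both maps are evaluated against electrical-stimulation ground truth
(electrodes within 6 mm of a stimulation-positive site): confusion tables,
sensitivity/specificity, Yates-corrected chi-square, a convinced/high-risk
site triage, and Gaussian-kernel topographic activation rasters.

A seeded simulator generates multichannel ECoG + EMG with known
movement-potential, band-power-drop, and band-power-boost channels
(power-law background, optional 50 Hz line noise, 2,000 Hz sampling,
4×8 / 6×8 grids at 10 mm pitch), so the whole pipeline is testable without
patient data.

## Layout

| Module              | Contents                                                                 |
| ------------------- | ------------------------------------------------------------------------ |
| `ecogmap.preproc`   | `Recording`/`EventSet`/`TrialSet`, common average reference, Butterworth band-pass (zero-phase), EMG onset detection, epoching, robust trial rejection |
| `ecogmap.etam`      | grand averages, template building (incl. leave-one-subject-out), trial correlations, signed R², significance |
| `ecogmap.efam`      | spectral segments, tapered periodograms, ensemble log-normalization, band sums, activation weights |
| `ecogmap.evaluate`  | electrode grids, stimulation-positive sets, confusion statistics, chi-square, activation rasters, risk partition |
| `ecogmap.simulate`  | synthetic recordings + ground truth, text/EDF fixture writer             |
| `ecogmap.pipeline`  | end-to-end wrappers (`run_etam`, `run_efam`, `run_both`)                 |
| `ecogmap.io`        | minimal EDF reader/writer (16-bit, 1 s records), events/geometry/site CSVs |
| `ecogmap.cli`       | `ecogmap` command-line front end                                         |

## CLI

```sh
# generate a synthetic fixture (EDF + events/geometry CSV + ground truth)
ecogmap simulate --out fixture/ --seed 1

# temporal and spectral maps
ecogmap etam --data fixture/ --out out/etam/
ecogmap efam --data fixture/ --out out/efam/

# evaluate against stimulation sites
ecogmap eval --etam-scores out/etam/channel_scores.csv \
             --efam-scores out/efam/band_activations.csv \
             --geometry fixture/geometry.csv \
             --stim-sites sites.csv --out out/eval/

# standalone activation raster
ecogmap map --scores out/etam/channel_scores.csv \
            --geometry fixture/geometry.csv --out out/raster.png
```

Parameters default to the published protocol and can be overridden by a
YAML/JSON config (`--config`) or flags (flags win). Every run writes a
`manifest.json` (parameters, version, input digests) for reproducibility.
Exit codes: 0 success, 2 validation error, 3 I/O error, 4 empty result.

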