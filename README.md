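# chorusspace

Calibrated bioacoustic analysis of anuran advertisement calls under road
noise, built as a tested, reusable pipeline:

* **`synthetic_data`** — forward simulation with known ground truth: sites
  whose ambient noise follows a linear model in `1/distance²`, frog
  populations whose call parameters follow linear mixed models in
  temperature and noise, and calibrated audio scenes (two-syllable
  harmonic-stack calls attenuated by spherical spreading + excess
  attenuation, mixed over low-frequency road noise).
* **`calibration`** — digital audio → pascals (microphone sensitivity,
  gain, ADC full scale) → band-limited windowed RMS SPL (dB re 20 µPa);
  zero-phase Butterworth band-pass; 16-bit PCM WAV I/O.
* **`soundscape`** — per site-night ambient-noise profiles (median band
  SPL over 15-min windows inside a pre-chorus evaluation interval,
  default 16:00–17:00) and the inverse-square-law regression of site
  medians on `A = 1/distance²`.
* **`call_features`** — per-call measurements from selection-table
  annotations (Raven-style TSV): annotation-bounded duration with a
  0.05-s energy buffer, 4,096-point-FFT spectral centroid restricted to
  1.0–4.5 kHz, band-limited received SPL, source level back-calculated to
  1 m, call rate, and per-frog aggregation with overlap/SNR screening.
  Analysis runs at 11,025 Hz by default (polyphase downsampling).
* **`commspace`** — the communication-space model: received level
  `RL(r) = s − 20·log10(r) − A_e·r`, masking radius solved in closed form
  (Lambert W) at `RL = n`, hemispherical volume `(2/3)πr³`, the
  time–volume statistic `d · rate · (2/3)πr³` per minute, and
  noise-barrier insertion-loss scenarios.
* **`stats_pipeline`** — REML linear mixed models (fixed effects: site
  median noise + nightly temperature; random intercepts: site and date
  nested within site) for call rate, centroid frequency, log duration,
  source level, and masking radius; percent-change back-transforms;
  replicate parameter-recovery experiments; end-to-end orchestration.

## Command line

```sh
chorusspace simulate --seed 1 --out out/ --scene        # tables + WAV scene
chorusspace profile-noise rec.wav --gain 36 --site S01  # ambient median SPL
chorusspace measure-calls rec.wav sel.txt --distance 5 --ambient 45
chorusspace commspace -s 90 -n 50 --barrier-loss 5      # radius/volume table
chorusspace fit frogs.csv --response centroid_frequency
chorusspace run-all --seed 1 --out report/              # full synthetic run
```

All tables are CSV (selection tables TSV); configs are YAML
(`chorusspace.synthetic_data.config_from_yaml`). Progress and timings go
to stderr.

## Conventions

* SPLs are dB re 20 µPa; source levels are referenced to 1 m.
* Digital sample units and pascals are tracked with an explicit flag on
  `AudioClip`; calibration cannot be applied twice.
* All generators are pure functions of `(config, seed)`; per-stage random
  streams are derived from the single top-level seed.
* Received-level energy of a call is integrated over the buffered
  analysis window but normalized by the annotated call duration, so
  source levels round-trip through the synthesis chain.
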