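# nirsbci

An fNIRS brain–computer-interface classification pipeline for three-class
(rest / right-hand / left-hand motor execution) decoding of hemodynamic
signals, with a synthetic-data simulator so the entire method can be
exercised end to end without human recordings.

Stages:

1. **simulate** — continuous multichannel sessions: block-design motor
   tasks (10-s blocks; 10 experiments × 5 sessions of rest, right, rest,
   left), contralateral activation (channels 1–17 over C4, 18–34 over C3),
   HbO increase / HbR decrease via a difference-of-gamma response kernel,
   plus sinusoidal physiological noise (cardiac 0.8 Hz, respiration 0.2 Hz,
   Mayer 0.1 Hz, very-low-frequency 0.03 Hz), low-frequency drift, and
   white noise. Fully seeded.
2. **mbll** — modified Beer–Lambert law conversion between per-wavelength
   optical-density changes and ΔHbO/ΔHbR (2-wavelength direct solve or
   least squares for ≥3 wavelengths; forward model included for round-trip
   testing).
3. **denoise** — wavelet multiresolution analysis (db5, 10 levels,
   periodized boundary; the Daubechies filters and the DWT are implemented
   in NumPy), reconstruction from detail levels d8+d9 (≈0.025–0.1 Hz at
   25.7 Hz), then per-channel scaling into [0, 1].
4. **features** — six statistics (mean, variance, kurtosis, skewness, peak,
   OLS slope) per chromophore per channel: 408 dimensions for 34 channels;
   min–max normalization fitted on training folds only.
5. **models** — PCA + one-vs-rest linear SVM; fully connected ANNs
   (named structures ANN1-a … ANN2-c); 1-D CNNs over time with full channel
   width (kernel 3, same padding, max-pool 2, dropout 0.5,
   256 → 128 → 3 softmax head; named structures CNN1-a/b, CNN2-a/b). The
   neural networks and Adam optimizer are implemented in NumPy with fully
   seeded, bit-reproducible training.
6. **evaluate** — stratified k-fold cross validation, exhaustive
   hyperparameter grid search, and sample-size learning curves, all
   leakage-safe (scaling/PCA/weights fitted per training fold).
7. **interpret** — PCA scatter of raw signals / feature vectors /
   first-layer feature maps, and convolutional-filter channel attribution
   (kernel-averaged filter weights → argmax channel → per-trial traces).

## CLI

```bash
nirsbci simulate --seed 1 --out-dir out/sim
nirsbci denoise  --in out/sim/record.csv --wavelet db5 --levels 10 --keep 8,9 \
                 --out out/filtered.csv
nirsbci features --in out/filtered.csv --events out/sim/events.csv \
                 --out out/features.csv
nirsbci crossval --family svm --features out/features.csv --k 10 \
                 --out out/cv.json
nirsbci run --seed 1 --out-dir out/run   # end-to-end demo with manifest
```

Other subcommands: `mbll`, `train`, `gridsearch`, `learncurve`,
`interpret`. All accept `--help`. Records are plain CSV matrices
(`hbo_ch<k>` / `hbr_ch<k>` or `od_ch<k>_<λ>nm` columns) with a JSON sidecar
holding the sampling rate and channel layout.

Note on Adam: the default second-moment decay is `beta2 = 0.999`; a
`--paper-adam` switch restores 0.1 (see `models.PAPER_ADAM_BETA2`), which
effectively disables second-moment smoothing and is documented as a likely
typo in the source the configuration mirrors.

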