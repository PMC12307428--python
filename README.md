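# neurofeat

Multi-domain feature pipeline for epoched 19-channel EEG (1 s @ 1000 Hz,
six classes: five motor-imagery tasks plus an idle baseline):

* **Feature extraction** — 1102 features per segment across four domains:
  * `TD` time domain: 24 descriptors per channel (456 total; catalog in
    `neurofeat/timedomain.py`),
  * `FD` Fourier bands: energy, sample variance and normalized spectral
    entropy of the delta/theta/alpha/beta/gamma bands (285),
  * `TF` wavelet packets: the same three statistics on a 9-level Haar
    wavelet-packet decomposition with frequency-ordered (Gray-code) nodes
    mapped to the five bands (285),
  * `ND` nonlinear: Poincare-plot SD1, SD2, SD1·SD2 and SD1/SD2 at lag 1
    (76).
* **Selection** — per-feature one-way ANOVA across the six classes at
  alpha = 0.05 (raw p-values by default, optional Benjamini–Hochberg), with
  reduced feature tables and feature-type × channel significance
  distribution maps (binary for pooled/subject-independent runs, 0..n
  counts for per-subject runs).
* **Classification** — eight classifier families (decision tree,
  discriminant, naive Bayes, SVM, kNN, ensembles, neural nets, kernel
  approximation) with toolbox-style variants, benchmarked by seeded
  stratified 5-fold cross-validation on both the full and the
  ANOVA-reduced tables.
* **Synthetic generator** — seeded 1/f-background EEG with class-dependent
  band-power modulation on a configurable channel subset and per-subject
  log-normal gains, used to exercise the whole pipeline end to end.

Feature columns are named `<domain>:<code>:ch<channel>` (e.g.
`FD:FD3:ch11`) in channel-major order; the repository's fixed code layouts
(TD1..TD24, FD/TF 1–5 energy, 6–10 variance, 11–15 entropy, ND1..ND4) and
the 10–20 channel order are documented in the module docstrings.

## CLI

```sh
neurofeat synth    --n-subjects 2 --n-per-class 10 --out data/ --seed 1
neurofeat extract  --collection data/S1 --domains TD+FD+TF+ND --out table.csv
neurofeat select   --table table.csv --alpha 0.05 --out mask.json
neurofeat map      --mask mask.json --domain FD --out map.csv
neurofeat classify --table table.csv --family svm --out results.csv
neurofeat run      --config configs/example.yaml --seed 1
neurofeat fixtures --out fixtures/
```

`neurofeat run` executes the full pipeline (generate → extract → select →
map → classify, with and without the ANOVA branch) and writes all tables,
masks, maps, results and a reproducibility manifest under the configured
output directory. CLI flags override config keys.

## Data formats

* collections: `<stem>_meta.csv` + `<stem>_data.csv` (+ channel names),
  plain CSV;
* feature tables: CSV with `subject`, `label` and one column per feature id;
* masks and maps: JSON with a schema version; maps also export as CSV grids
  with row/column/grand totals;
* an optional reader for the public motor-imagery `.mat` recordings lives in
  `neurofeat.reader` (import-isolated; not needed by the tests).
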