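# amdetect

Analysis pipeline for amplitude-modulation (AM) detection under
developmental hearing loss: psychometric d′/TMTF fitting, single-unit and
classifier-based neurometrics, linear population decoding, choice
probability, envelope-following-response (EFR) and ABR threshold
analysis, and bootstrap group statistics. A synthetic-data module
generates Go-Nogo behavioral sessions, cortical spike trains, and
brainstem waveforms with the statistical structure the analyses assume,
so every stage is testable without any external data.

## Layout

| module | contents |
|---|---|
| `amdetect.stimuli` | AM stimulus parameterization, dB↔fraction depth conversion, envelope synthesis with power-equalizing gain |
| `amdetect.synthetic` | cohort generator: sessions (30% Nogo, 5-depth bracket), gamma-gain × inhomogeneous-Poisson units, EFR/ABR waveforms, Ctl/HL presets |
| `amdetect.psychometrics` | session filters, d′ with 0.05/0.95 clamp, cumulative-Gaussian fits, threshold at d′ = 1, lapse rate, exponential TMTF `y(m) = A·exp(b·m)` |
| `amdetect.unit_metrics` | spontaneous/driven FR with 25–1000 ms best-window search, d′_FR, monotonicity index, vector strength + Rayleigh test, unit CV, neurometric threshold interpolation, ROC choice probability |
| `amdetect.pattern_classifier` | template classifier over FR / van Rossum / K-means / Rcorr metrics, tau optimization over 2–512 ms |
| `amdetect.population_decoder` | 1-ms-binned pseudo-population tensors, absolute-z-score normalization, linear SVM (cost 1) 80/20 readout, unit-count and monotonic-subpopulation resampling, population CV |
| `amdetect.efr` | FFT peak within ±3 Hz of the AM rate, 2×-noise-floor depth thresholds, ABR peak amplitude/latency/threshold |
| `amdetect.group_stats` | per-animal subsampling bootstrap (98.75% CI) and Holm-Bonferroni correction |
| `amdetect.pipeline` / `amdetect.cli` | cohort orchestration and the `amdetect` command line |

## CLI

Every subcommand accepts `--seed`, `--config` (cohort YAML, optional) and
`--out`:

```sh
amdetect generate --seed 1 --out out/cohort      # sessions CSV, units HDF5, manifest
amdetect psychometrics --seed 1 --out out/psy
amdetect run-all --seed 1 --out out/run          # all stages + summary triptych
```

`run-all` writes per-stage TSV tables, a combined summary
(behavioral/EFR/decoder thresholds per group × rate), a `summary.png`
figure, and a `manifest.json` with artifact checksums; identical
config + seed reproduces identical tables.

## Notes on modeling choices

- Trial-to-trial response variability uses a gamma-distributed
  multiplicative gain (mean 1) on an inhomogeneous Poisson process — the
  minimal mechanism that lets firing-rate CV exceed the Poisson bound;
  the hearing-loss preset uses a larger gain CV than control.
- Phase locking scales with linear modulation depth, so the unmodulated
  Nogo signal is unmodulated in the spike trains too.
- Behavioral choice and spike generation are independent by default
  (choice probability is 0.5 under this null); `CohortConfig.choice_coupling`
  couples them for power analyses.
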