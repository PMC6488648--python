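# coralwatch

Quantifying cold-water coral behaviour from a fixed underwater observatory.

A cabled observatory camera photographs a *Lophelia pertusa* reef once per
hour, alongside hydrography and current sensors. `coralwatch` turns that
image stream into two behavioural time series and analyses them against the
environment:

- **Coral colour** `xi_t` — the CIELab a* (green–red) component averaged over
  the live-coral region of each frame, segmented by Gabor-texture features
  and a self-organising-map pixel labeller. Rising `xi_t` means redder
  tissue (e.g. from feeding on pigmented copepods).
- **Polyp activity** `gamma_t` — the fraction of polyp-mask pixels that a
  LeNet-5-layout patch classifier marks as an extended (feeding) polyp:

  `gamma_t = |{p_(x,y) : C(p_(x,y)) = 1}| / |M = 1|`

  where `M` is the polyp mask built from expert point annotations and
  `C(p)` the classifier output for the 46×46 patch centred at each pixel.
- **Multivariate analysis** — irregular, gappy series are joined by
  bracketed linear interpolation onto hourly grids; daily averages and
  Pearson/Spearman correlations; Morlet continuous wavelet transforms with
  bias-corrected power (`|W|²/s`), chi-square significance against AR(1)
  red noise, and wavelet coherence with phase and Monte Carlo significance —
  resolving tidal (12.4 h), diel (24 h) and lunar (~707 h) structure in time
  as well as scale.

A first-class synthetic-data module renders reef-like image sequences,
annotations and sensor records with known ground truth, so every stage of
the chain is testable end to end without any observatory data. See
`docs/methods.md` for the full model description and assumptions.

## Worked example

Run the full chain on a synthetic sequence with an injected tissue-redness
ramp (a* 0 → 15) and a polyp-activity ramp (0.1 → 0.9):

```python
from coralwatch import pipeline as pp

cfg = pp.recovery_benchmark_config(seed=1, output_dir="runs/demo")
report = pp.run_pipeline(cfg)
print(report.accuracies)
print(report.ground_truth_recovery)
```

which prints (seed 1):

```
{'train': 1.0, 'val': 1.0, 'test': 1.0}
{'xi_vs_truth_pearson': {'r': 0.9999923633517784, 'n': 95},
 'gamma_vs_truth_spearman': {'r': 0.9869188798368617, 'n': 95}}
```

Reading: the patch classifier separates active polyps, inactive polyps and
background perfectly on the synthetic patch set (train/val/test accuracy
1.0); the recovered colour series tracks the injected redness ramp with
Pearson r ≈ 1.0 over the 95 retained frames (5 of 100 were dropped as
simulated camera malfunctions); and the recovered activity series ranks the
injected activity trajectory with Spearman ρ ≈ 0.99. The run directory
contains every intermediate: rendered frames, annotation and sensor tables,
`color/xi.csv`, `polyps/gamma.csv`, the aligned hourly grids, the
correlation table, global wavelet spectra and a JSON run report.

The same stages are available from the shell:

```bash
coralwatch run-all --config config.yaml --seed 1 --out runs/demo
coralwatch synth  --config config.yaml --out runs/demo   # single stages
coralwatch report --out runs/demo
```

`config.yaml` needs exactly one of a `synth:` block (generate data) or an
`inputs:` block (real frames + sensor CSVs, or pre-extracted
`timestamp,value` series tables for an analysis-only run).

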