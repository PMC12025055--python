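# hurstwave

Single-channel EEG seizure classification from 23.6 s segments, built around
two complementary signal descriptions:

* **Rescaled-range (R/S) Hurst analysis.** For a window of *n* samples the
  statistic R(n)/S(n) — the range of cumulative mean-deviations rescaled by
  the window SD — grows as E[R(n)/S(n)] = C·nᴴ. The log–log slope H (the
  Hurst exponent, `hurstex`) and the constant C (`hurstc`) quantify the
  signal's long-range dependence: H > 0.5 marks the persistent,
  trend-reinforcing dynamics typical of resting EEG.
* **Daubechies-4 wavelet sub-band statistics.** A level-4 db4 pyramid splits
  a 173.61 Hz signal into five bands (cA4 ≈ 0–5.4 Hz … cD1 ≈ 43–87 Hz);
  per band the 5th/25th/75th/95th percentiles, median, mean, SD, variance
  and RMS are computed. Epileptic spike-and-wave discharges reshape exactly
  these coefficient distributions.

Together they form a 47-feature vector per segment, classified by a linear
SVM (balanced class weights), a 100-tree depth-5 random forest (the default
and best performer) or a compact 50-unit LSTM, and evaluated with stratified
10-fold cross-validation, bootstrap 95 % confidence intervals and Cohen's d.

The package is for researchers working with Bonn-style single-channel
epilepsy corpora or CHB-MIT-style EDF recordings, and ships a synthetic
generator (exact fractional Gaussian noise background + 3 Hz spike-and-wave
bursts) so the entire pipeline runs and is tested without any data download.

## Worked example

```python
from hurstwave import SyntheticSpec, gen_dataset, load_config, run_pipeline

report = run_pipeline(load_config({"data": {"n_per_class": 30}}), "run_out")
print(report["cv"]["metrics_avg"])
```

Running `python examples/full_pipeline.py` prints:

```
run id        : run_6855683975187b48_0
features used : 47
CV accuracy   : 1.000  (mean of 10 folds)
sensitivity   : 1.000   specificity: 1.000
```

On the default synthetic conditions (burst amplitude 4× the background SD)
the classes are cleanly separable, so the random forest reaches perfect
cross-validated accuracy; sensitivity is the recall of the seizure class,
specificity the recall of the non-seizure class. `run_out/` holds the
feature table (`features.csv`), the fitted model with a JSON sidecar, a full
JSON report (fold metrics, bootstrap CIs, effect size, stage timings) and a
run log. The `examples/` scripts walk through each capability one at a
time; the `hurstwave` CLI exposes the same stages
(`generate`, `extract`, `select`, `train`, `evaluate`, `run-all`).

Estimating a Hurst exponent directly:

```python
from hurstwave import estimate_hurst, gen_fgn

fit = estimate_hurst(gen_fgn(h=0.8, n=4096, seed=0))
print(f"H={fit.H:.3f} C={fit.C:.3f} R2={fit.r_squared:.4f}")
# H=0.742 C=0.656 R2=0.9958
```

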