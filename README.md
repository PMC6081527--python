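# stenoflow

Quantitative stenosis grading from color-coded fluoroscopy, rebuilt as a
tested simulation-and-analysis pipeline. In peripheral artery disease,
interventionalists grade a stenosis during the procedure by watching how
a contrast bolus traverses it: the mean gray value inside a region of
interest over time (the time-density curve, TDC), the area under that
curve over a fixed window after bolus arrival (AUC), and the
time-to-peak (TTP) are the working surrogates for flow. `stenoflow`
emulates the corresponding bench experiment — stenotic tube phantoms
(0/40/60/80 % diameter reduction) under square-wave pulsatile flow
(800 ms valve cycle, 500 ms open at 25 ml/s), a 20 ml contrast bolus
injected over 1 s, flat-detector imaging at 30 frames/s — and provides
the complete quantification and statistics chain on top of it.

The package has five layers:

- `stenoflow.transport` / `stenoflow.imaging` — 1D advection–dispersion
  bolus transport with stenosis-resistance, poststenotic jet and
  recirculation closures, projected into 16-bit fluoroscopy-like frame
  stacks with detector noise (the synthetic stand-in for the
  angiography suite);
- `stenoflow.tdc` — protocol ROI placement (reference 5 cm proximal,
  shoulder-abutting, 5 cm distal), baseline-zeroed TDC extraction, the
  5 % bolus-arrival trigger, Gaussian curve smoothing (emulating
  clinical postprocessing), frame decimation;
- `stenoflow.quantify` — windowed trapezoidal AUC, percentage deviation
  from the reference ROI, TTP, ROI-size sensitivity sweep;
- `stenoflow.stats` / `stenoflow.tables` — one-way ANOVA and
  Tukey–Kramer post hoc computed directly from summary statistics
  (mean, SD, n), Spearman correlation, RMSD/CV reproducibility, plus
  the published bench summary tables as CSV fixtures and a report that
  recomputes every printed p-value from its own row;
- `stenoflow.pipeline` / `stenoflow.cli` — the end-to-end experiment
  (4 grades × 3 replicates), deterministic per seed, with a run
  manifest, CSV outputs, a text report and figures.

The summary-statistics ANOVA is

    SS_b = Σ nᵢ(mᵢ − m̄)²,  SS_w = Σ (nᵢ−1)sᵢ²,
    F = (SS_b/(k−1)) / (SS_w/Σ(nᵢ−1)),

with the Tukey–Kramer comparison qᵢⱼ = |mᵢ−mⱼ| / √(MSE·(1/nᵢ+1/nⱼ)/2)
referred to the studentized range with k groups — algebraically
identical to raw-data ANOVA on any samples with those moments.

## Worked example

Reproduce a published ANOVA row from its summary statistics (distal ROI,
5 s integration window; per-grade AUC deviations in % with n = 3):

```python
from stenoflow import SummaryStats, anova_from_summary, tukey_kramer_from_summary

row = SummaryStats(
    group_labels=["0", "40", "60", "80"],
    means=[46.78, 25.94, 9.89, -5.64],
    sds=[8.27, 15.81, 6.81, 6.1],
    ns=[3, 3, 3, 3],
)
print(anova_from_summary(row))
print(tukey_kramer_from_summary(row, ("40", "80")))
```

prints

```
ANOVAResult(f_statistic=15.025097086569447, df_between=3, df_within=8, p_value=0.0011910949175778138)
TukeyResult(pair=('40', '80'), mean_difference=31.580000000000002, q_statistic=np.float64(5.4566334608051), adjusted_p=0.020156808577595497)
```

i.e. the four stenosis grades differ strongly (p ≈ 0.0012, the printed
value), and the low- vs high-grade pairwise comparison survives the
Tukey–Kramer adjustment at p ≈ 0.0202.

Run the full simulated experiment (about a minute on one core):

```python
from stenoflow import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=1))
cell = result.deviation_cell("IV", 7.0)
print(cell.groupby("grade_pct")["deviation_pct"].mean().round(1))
```

```
grade_pct
0     21.9
40     4.6
60   -10.4
80   -68.4
Name: deviation_pct, dtype: float64
```

The distal 7 s AUC deviation decreases strictly with stenosis grade:
positive for the nonstenotic tube (the bolus clears the proximal
reference ROI quickly during the injector-driven surge) and negative for
the high-grade stenosis (flow reduction and poststenotic recirculation
hold part of the bolus past the integration window). The accompanying
Spearman correlation between stenotic lumen diameter and deviation
(`result.spearman`) is ρ ≈ 0.97 at the 5 s window.

The same pipeline is scriptable from the shell:

```
stenoflow simulate --stenosis 80 --replicates 3 --seed 1 --out runs/
stenoflow extract --images runs/ --out tdcs.csv
stenoflow quantify --tdcs tdcs.csv --windows 1,3,5,7 --out results.csv
stenoflow reproduce --out reproduced_pvalues.csv
stenoflow run-experiment --seed 1 --out experiment/
```

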