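# lakemwat

Gaussian-Process surrogate projection of summer thermal stress in lakes.

A warming climate raises lake water temperatures, threatening cold-water
fish whose chronic heat tolerance is indexed by **MWAT** — the maximum
weekly average temperature, the highest annual mean of seven consecutive
daily maxima (7DADMax) — evaluated in the layer just above the thermocline,
the cool refuge at the base of the oxygenated mixed zone. Running a
process-based thermal model for every lake in a national survey is
impractical; `lakemwat` instead trains a cheap statistical emulator on a
designed set of simulations and applies it to a whole lake population.

The package is a complete, synthetic, end-to-end re-creation of that
workflow for limnologists and climate-impact analysts:

1. **Design** — a Sobol quasi-random sample of lake morphometry
   (depth 2–30 m, area 0.1–100 km² log-uniform, light extinction
   0.2–4 m⁻¹ log-uniform) crossed factorially with climate locations and
   warming scenarios (shipped direction numbers, Antonov–Saleev update).
2. **Teacher** — a two-layer daily energy-balance lake simulator driven by
   synthetic daily weather (seasonal cycles, AR(1) noise, additive monthly
   warming deltas), reproducing stratification, ice capping, evaporative
   cooling and the cool metalimnetic layer of small deep lakes.
3. **Response** — MWAT above the thermocline per run (thermocline located
   at the maximum vertical gradient below 1 m; 7-day trailing windows
   within calendar years).
4. **Predictors** — July–August and January mean air temperature, annual
   FAO-56 Penman–Monteith reference evapotranspiration, extinction
   coefficient, and lake geometry, summarized by the geometry ratio
   GR = Area^0.25 / H_max (area in m²; GR < 10 marks small, deep,
   strongly stratifying lakes).
5. **Surrogate** — exact GP regression of normalized MWAT,
   Y_i = (X_i − X̄)/σ, with ARD kernels; hyperparameters maximize the log
   marginal likelihood by multi-restart L-BFGS-B; seven candidate kernels
   (SE, RQ, Matérn 3/2 and 5/2, linear, SE+RQ, SE×RQ) ranked by
   AIC = 2k − 2 ln L̂; reliability checked by bootstrap out-of-bag
   cross-validation.
6. **Projection** — per-lake baseline/future MWAT for a synthetic national
   lake table under a six-member warming ensemble (median monthly series or
   per-member), with 95 % predictive limits, 30 °C exceedance fractions,
   empirical CDFs and a summary of lakes whose MWAT declines.

## Worked example

```python
from lakemwat.cli_io import PipelineConfig, run_end_to_end

config = PipelineConfig(master_seed=1, outdir="output")
run_end_to_end(config)
print(open("output/summary.txt").read())
```

which prints (numbers from this exact run):

```
lakemwat 0.1.0 run summary
master_seed: 1  config_hash: c9c2ad5bcf64
training runs: 243
surrogate kernel: se_plus_rq  logL: 413.42  AIC: -794.85
training R^2: 1.0000  RMSE: 0.015 C  MAE: 0.008 C
projected lakes: 898  ensemble: late_century
mean delta MWAT: +2.32 C  max: +3.08 C
exceedance >30 C: baseline 14.6%  future 29.6%
decreasing lakes: 0.0%
```

Reading: the sum-kernel GP reproduces the 243 training MWATs almost
exactly (R² 1.00, RMSE 0.015 °C); across the 898 synthetic lakes the
late-century ensemble raises MWAT by 2.3 °C on average, and the share of
lakes whose MWAT exceeds the 30 °C cold-water-fishery threshold roughly
doubles, from 15 % to 30 %.

The same pipeline is scriptable from the shell
(`lakemwat run-all --seed 1 --outdir output`, or the stage-wise
subcommands `simulate-training`, `compute-mwat`, `build-features`,
`fit-surrogate`, `project`).

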