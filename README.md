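# empisim

Empirical-similarity predictive models for small datasets with categorical
or ordinal covariates, with a Monte Carlo sensitivity-analysis protocol and
an ordinary-linear-regression benchmark.

## The problem

In many biological studies the covariates are categories — a dose level, a
delivery method, a strain — and the scientific question is predictive: what
response should a new combination of levels produce?  Empirical-similarity
models answer without assuming any functional form.  The prediction for a
target observation is a weighted average of the observed responses,

    Ŷ_t = Σ_{i≠t} s(x_i, x_t) y_i / Σ_{i≠t} s(x_i, x_t),

where the similarity s(x_i, x_t) = K(d_w(x_i, x_t)) decreases with a
weighted covariate distance d_w.  The weights w ≥ 0 — one per covariate
(strategy **M1**) or one per level of each covariate after one-hot encoding
(strategy **M2**) — are estimated from the data by least squares on
leave-one-out residuals (**OLS**) or by a sequential Gaussian likelihood
(**ML**).  Distances are the weighted binary (WBD), squared-Euclidean (WED)
and Minkowski (WMD) families with flexibility exponents δ and γ; kernels are
the exponential inverse e^{−d} (EX) and fractional inverse 1/(1+d) (FR).

Because the choice of distance, kernel and estimator has been largely
subjective, the package's centrepiece is a sensitivity protocol: repeat a
random 70/30 train/test split, re-estimate every scenario in the
model × method × kernel × distance × exponent grid, and summarize each
weight estimator's coefficient of variation (CV = sd/|mean|) and each
scenario's test MSE across iterations.  Low CV means the estimator is
stable against the accidents of sampling — the property a practitioner
choosing a configuration should care about.

The demo dataset is the classic 60-observation guinea-pig tooth-growth
table (tooth length in μm under vitamin C doses 0.5/1/2 mg, delivered as
ascorbic acid or orange juice), bundled as a small CSV.

## Worked example

```python
import empisim as es

data = es.load_tooth_growth()                      # n=60, covariates (dose, supp)
scenario = es.ScenarioSpec("m1", "ml", es.SimilaritySpec("ex"),
                           es.DistanceSpec("wbd", delta=4))

# one protocol iteration: split with seed 1, five-start ML fit, test MSE
rec = es.run_iteration(data, scenario, seed=1)
print(rec.weights, rec.test_mse, rec.start_index)
# [10.215 17.814] 8.636 1

# the full sensitivity summary for this scenario and the linear benchmark
summaries, _ = es.run_sensitivity(
    data, [scenario, es.ScenarioSpec("lm")], R=30, base_seed=0)
for s in summaries:
    print(s.scenario.label, s.cv_per_weight.round(3), round(s.mean_mse, 2))
# m1-ml-ex-wbd-delta=4 [0.066 0.059] 15.54
# lm [0.062 0.077 0.041 0.213] 15.94
```

Reading the output: the single iteration estimates the dose weight at 10.2
and the supplement weight at 17.8 (the fit selected the first of the five
data-driven starts) with a test MSE of 8.6 μm².  Across 30 splits the two
M1 weight estimators vary by about 6.6% and 5.9% of their means — the
stability the protocol measures — and the similarity model's mean test MSE
(15.5 μm²) is comparable to the 4-parameter linear benchmark's (15.9 μm²),
with half the parameters.

The same run from the shell:

```sh
empisim run --config run.yaml --out results/
empisim fit --data tooth.csv --model m1 --method ml --similarity ex \
            --distance wbd --delta 4 --seed 1
empisim simulate --preset toothlike --seed 7 --out synth.csv
```

`empisim run` writes `cv_summary.csv` (scenario × parameter × CV),
`mse_summary.csv`, `iterations.csv` (every fitted weight vector, seed and
test MSE) and a JSON manifest with the config echo and all seeds; a rerun
with the same config is byte-identical.  A minimal `run.yaml`:

```yaml
data: toothgrowth      # bundled demo table, or a CSV path, or "toothlike"
R: 30
base_seed: 0
scenarios: {}          # full 57-scenario grid; subset with models/methods/...
out: results
```

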