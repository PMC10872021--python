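# rockpool

Quantitative-genetic analysis of thermal adaptation in clonal rock-pool
metapopulations — built for biologists asking whether fine-scale (metres,
not degrees of latitude) variation in water temperature predicts the
evolutionary and plastic potential of a population, using *Daphnia*-style
clonal designs.

The pipeline covers, end to end:

* **Pool climate metrics** — each pool's daily-maximum series is fitted by
  maximum likelihood as a quadratic seasonal trend with Gaussian-variogram
  residual correlation, corr(h) = exp(−(h/φ)²); it yields the mean daily
  mean, the hottest-month mean daily maximum, the daily SD of detrended
  residuals, the predictability φ (days), and the seasonal range.
* **Fitness** — each female's intrinsic rate of natural increase r (per
  day) solves the Lotka–Euler equation Σ mₖ e^(−r·xₖ) = 1 over her first
  two broods (survivorship 1, all offspring counted — clonal reproduction);
  inclusion requires at least one brood and ≥ 15 days of monitoring.
* **Twelve hierarchical variance models** (M1-0…M1-4, M2-0…M2-3,
  M3-0…M3-3) for either CTmax or fitness: Gaussian mixed models
  y = Xβ + clone + pool + trial + ε with clone variance optionally grouped
  by pool or by developmental temperature, fitted by a Gibbs sampler under
  Normal(0, 1000) coefficient priors and Uniform(0, 100) SD priors.
* **Model comparison** by PSIS-LOO (Pareto-smoothed importance-sampling
  leave-one-out ELPD) with the 2·SE support rule, split-chain R̂, and
  posterior predictive checks of means and variances.
* **Broad-sense heritability** per developmental temperature,
  H² = σ²_clone/(σ²_clone + σ²_ε), with draw-wise 20 °C-vs-25 °C contrasts.
* **Synthetic studies** with known ground truth (including life-history
  records produced by inverting the Euler map) and a coefficient-CI
  power/design-sensitivity harness.

See `docs/methods.md` for the models, priors, estimators and their
numerical details.

## Worked example

```python
import rockpool as rp

# a complete synthetic study at the field design scale:
# 10 pools, 13 clones/pool, 2-3 individuals per clone per temperature
study = rp.generate_phenotypes(rp.SyntheticConfig(), seed=42)

# fitness from the life-history records
table, excluded = rp.fitness_table(study.records)
print(len(table), table["r"].mean().round(3))
# 642 0.245

# does developmental temperature change the genetic variance of CTmax?
model = rp.CloneVarianceModel.from_registry("M3-3", "ctmax", study.ctmax_obs)
res = model.fit(rp.MCMCSettings(6000, 2000, thin=2, n_chains=3, seed=1))
print(res.summary().loc[["sigma_clone[20]", "sigma_clone[25]"]].round(3))
#                   mean     sd  median  ci_2.5  ci_97.5   rhat
# parameter
# sigma_clone[20]  0.400  0.043   0.399   0.317    0.484  1.002
# sigma_clone[25]  0.277  0.044   0.278   0.190    0.360  1.002

h20, h25 = res.heritability("20"), res.heritability("25")
print(round(h20.h2[0], 3), round(h25.h2[0], 3))
# 0.419 0.26
contrast = res.temperature_contrast()
print(round(contrast.v_g_pct_change, 1))
# -51.6
```

The clone-SD posteriors bracket the generating values (0.4 and 0.2 °C);
heritability drops with warming because genetic variance does, and the
contrast quantifies that drop (the generating decrease is −75%; a single
study of this size recovers it with the posterior spread shown by the CIs).

A model-comparison run looks like:

```python
loos = {m: rp.CloneVarianceModel.from_registry(m, "ctmax", study.ctmax_obs)
            .fit(rp.MCMCSettings(4000, 1500, thin=2, n_chains=3, seed=2))
            .loo()
        for m in ("M1-0", "M1-1")}
for row in rp.compare(list(loos.items())):
    print(row.model_id, round(row.delta_elpd, 1), round(row.se_delta, 2),
          row.supported)
# M1-1 0.0 0.0 True
# M1-0 -31.0 8.55 False
```

— the no-genetic-variation model loses by far more than twice the SE of the
ELPD difference, so it receives no support.

There is also a CLI mirroring the pipeline stages
(`rockpool metrics | fitness | fit | compare | h2 | simulate | power | run`);
`rockpool run --config study.toml --out results/` executes everything and
writes a JSON manifest with input digests, seeds and timings.

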