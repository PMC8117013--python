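# dendrobai

Basal-area-increment (BAI) chronologies and Bayesian attribution of
boreal tree growth to stand composition, climate and insect epidemics.

The package is aimed at dendroecologists studying how stand species
mixture modulates growth responses: it takes per-tree ring-width series
for black spruce (*Picea mariana*) and trembling aspen (*Populus
tremuloides*) sampled across pure-spruce (PBS), mixed (M) and
pure-aspen (PTA) stands, builds mean BAI chronologies per species ×
composition group, relates them to monthly climate through bootstrapped
correlation functions, and fits a Bayesian linear model that separates
the influences of a stand baseline, a long-term trend, growing-season
length, summer heat stress, and epidemics of the spruce budworm (a
spruce defoliator) and the forest tent caterpillar (an aspen
defoliator). A synthetic-data generator with known ground truth stands
in for non-public field data, so the whole chain is testable.

## The model

For chronology group `y` and year `t` ∈ 1950–2005,

```
BAI_t,y = α_Baseline,y + Trend_t·α_Tr,y + SeasonLength_t·α_SL,y
        + SummerHeat_t·α_SH,y + Budworm_t·α_SB,y + Caterpillar_t·α_TC,y + ε_t
ε_t ~ N(0, σ_y²)
```

with `Trend_t = t − 1977` (−27 … +28), `SeasonLength` the mean
April+September temperature anomaly, `SummerHeat` the June–August mean
anomaly, `Budworm` a 9-year triangular pulse (peak 1 in 1974) and
`Caterpillar` point intensities (1 in 1980 and 2001, 0.5 in 2000).
Priors are uniform on each α and Jeffreys on σ; the posterior is
sampled by component-wise random-walk Metropolis–Hastings (60,000
iterations, 10,000 burn-in). Parameters are compared across groups with
the overlapping coefficient (OVL) of their posteriors; OVL < 10% flags
a significant difference. See `docs/methods.md` for the full account.

## Worked example

```python
import dendrobai as db

# a synthetic study with known generating truth
ds = db.simulate_dataset(seed=7)

# mean BAI chronology for black spruce in mixed stands
chron = db.build_mean_chronology(ds.trees["BS_M"], span=(1950, 2005))

# fit the growth model
model = db.BaiLinearModel.from_chronology(chron, ds.covariates.loc[1950:2005])
res = model.fit(seed=7)
print(res.summary())
```

prints

```
Bayesian linear BAI model — group BS_M
  years: 1950–2005 (n = 56)
  retained draws: 50000 (of 60000, burn-in 10000)
  R² = 0.851   mean acceptance = 0.33

  parameter                   mean        sd      2.5%     97.5%
  alpha_baseline            3.0070    0.0433    2.9212    3.0928
  alpha_trend              -0.0240    0.0026   -0.0292   -0.0189
  alpha_season_length       0.4169    0.0342    0.3502    0.4844
  alpha_summer_heat        -0.2810    0.0611   -0.4022   -0.1612
  alpha_budworm            -0.6743    0.1747   -1.0133   -0.3308
  alpha_caterpillar         0.8913    0.2295    0.4437    1.3414
  sigma                     0.2961    0.0304    0.2436    0.3643
```

Read: mixed-stand spruce grows ≈3 cm²/yr at baseline with a small
negative long-term trend; it gains ≈0.42 cm² per °C of
growing-season-length anomaly, loses ≈0.28 cm² per °C of summer-heat
anomaly, loses ≈0.67 cm² at the budworm epidemic peak and gains ≈0.89
cm² in caterpillar-epidemic years (the non-host release effect). The
generating truth for this group was (3.0, −0.02, 0.4, −0.2, −0.8, 0.5)
with σ = 0.3 — every 95% credible interval above covers it. Posteriors
of two groups are compared with
`db.posterior_overlap(draws_a, draws_b)`.

The same chain runs end to end from the command line:

```
dendrobai run-all                 # default synthetic config
dendrobai simulate --out sim/     # just the generator
dendrobai fit --config cfg.yaml --out fits/
```

`run-all` writes chronology, covariate, correlation, ranking, posterior
and overlap CSVs plus a manifest with checksums; rerunning the same
config is byte-identical.

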