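# pulsetrace

**¹³C/¹⁵N pulse-chase tracer accounting for grassland plant–soil food webs.**

`pulsetrace` is for ecosystem ecologists running (or re-analysing) dual
isotope pulse-chase experiments: shoots labelled with ¹³C-CO₂, soil with
¹⁵N-nitrate, and the tracers chased over days through plants, soil microbes
(via PLFA biomarkers), mesofauna trophic groups and CO₂/N₂O effluxes. It
turns raw δ¹³C/δ¹⁵N measurements into tracer budgets and drought effect
sizes, and ships a compartmental simulator that generates fully
ground-truthed factorial datasets so every stage of the analysis is testable.

## What it computes

Given δ values (‰ vs VPDB or atmospheric N₂), the heavy-isotope atom
fraction is

> atom % = 100·R/(1+R),  R = R_std·(δ/1000 + 1)

and the enrichment of each sample is its **atom % excess** over matched
unlabelled controls (4 baseline cores per field). PLFA δ¹³C values are first
corrected for the methanol carbon added during derivatization,

> δ¹³C_PLFA = (C_FAME·δ¹³C_FAME − C_MeOH·δ¹³C_MeOH) / C_PLFA,

with methanol δ¹³C = −29.3‰, and multi-biomarker groups are pooled
carbon-weighted: atom %¹³C_group = Σ(Cᵢ·atom %¹³Cᵢ)/ΣCᵢ. Biomarker amounts
convert to biomass carbon with the published factors (11.8 nmol 18:2ω6,9 =
1 mg fungal C; 363.6 nmol total bacterial PLFA = 1 mg bacterial C).
Mesofauna counts become biomass through length–mass power laws and aggregate
into seven trophic groups. Tracer incorporation follows

> ¹³C pool size = C pool × atom %¹³C excess / 100,

with relative ¹³C excess expressed against each subplot's initial (day-0)
shoot enrichment, and recovery fractions taken at day 1 (plants, microbes)
and day 5 (fauna). Chamber CO₂/N₂O fluxes are OLS slopes of the
0/10/20/30-min headspace series converted by slope·(V/A)·P/(RT). Statistics
cover paired drought log response ratios with REML mixed-model intervals,
management models with per-time residual variances, and a from-scratch
permutation suite (Hellinger, Bray–Curtis, PCoA, PERMANOVA, PERMDISP,
vector fitting) using the (1+B)/(1+N) p estimator with 999 permutations.

The simulator solves a linear first-order compartment model x′(t) = M·x(t)
exactly (matrix exponential) over the factorial design — 3 sites × 2
managements × 2 drought treatments × 3 replicates = 36 plots, sampled at
days 0, 1, 2, 5, 10, 20 — and back-computes observed δ values from the true
tracer excess plus configurable lognormal/Gaussian noise.

## Worked example

```python
from pulsetrace.pipeline import RunConfig, run_pipeline

cfg = RunConfig(output_dir="demo_out", seed=42)
res = run_pipeline(cfg)          # simulates, budgets, tests, writes CSVs

rec = res["recovery"].query("element == '13C'")
print(rec.groupby("pool")["recovery_fraction"].mean().round(4).dropna())
```

```
pool
fungi                       0.0037
root                        0.2326
shoot                       0.2572
total_bacteria              0.0046
...
```

At day 1 about 26 % of the fixed ¹³C is still in shoots and 23 % has moved
to roots; bacteria and fungi hold a few tenths of a percent each — small
pools turning over recently fixed carbon. The drought effect on bacterial
¹³C enrichment:

```python
print(res["effects"].query("pool == 'total_bacteria'")
      [["management", "logRR", "ci_low", "ci_high", "significant"]].round(3))
```

```
management  logRR  ci_low  ci_high  significant
 extensive -0.521  -0.648   -0.393         True
 intensive -0.457  -0.585   -0.330         True
```

Negative logRR with intervals excluding zero: the simulated drought (which
scales plant-to-microbe carbon transfer down) measurably reduces the flow of
recent plant carbon into bacteria, under both managements.

A CLI wraps the same steps:

```bash
pulsetrace simulate --seed 3 --out data/
pulsetrace budget --inputs data/ --out results/
pulsetrace all --seed 3 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `pulsetrace.isotope` | δ ↔ atom % conversions, excess, derivatization correction, carbon-weighted pooling |
| `pulsetrace.plfa` | biomarker classification, biomass conversion, group enrichment |
| `pulsetrace.mesofauna` | length–mass allometry, trophic aggregation, community matrix |
| `pulsetrace.budget` | tracer pool sizes, relative excess, recovery fractions |
| `pulsetrace.gasflux` | chamber fluxes and efflux enrichment |
| `pulsetrace.stats` | logRR, REML mixed models, PCoA/PERMANOVA/PERMDISP |
| `pulsetrace.simulate` | compartment model, exact tracer solution, dataset generator |
| `pulsetrace.pipeline` / `pulsetrace.cli` | orchestration, config, CLI |

See `docs/methods.md` for the model assumptions, calibration choices and
known limitations.
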