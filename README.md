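# ssdbench

Species sensitivity distribution (SSD) fitting, AICc model averaging, and
subsampling benchmarks for hazardous-concentration estimation.

## The problem

Ecological risk assessment derives "safe" concentrations of a chemical from
the **hazardous concentration for 5% of species (HC5)** — the 5% quantile
of a species sensitivity distribution fitted to per-species acute toxicity
values (EC50/LC50). In practice toxicity data exist for only a handful of
species, a parametric distribution must be assumed, and no single family is
right for every chemical. **Model averaging** sidesteps the choice: fit
several candidate families, weight each by its small-sample-corrected
Akaike information criterion (AICc), and average the HC5 estimates. Whether
that actually beats just using a log-normal SSD is an empirical question.

`ssdbench` answers it by benchmark: for a chemical with a large dataset
(> 50 species from ≥ 3 of the 4 taxonomic groups — algae, invertebrates,
amphibians, fish), the empirical 5th percentile of the species values is a
trustworthy nonparametric **reference HC5**. Repeatedly subsampling 5–15
species (the realistic data situation), fitting SSDs, and comparing each
estimate against the reference quantifies how far — in
`log10(HC5_est) − log10(HC5_ref)` units — each approach strays.

## What it implements

- **Five candidate families** on (0, ∞) with closed-form CDF, quantile and
  log-density: log-normal, log-logistic (a logistic in ln x), Burr type III
  `F(x) = (1 + (x/λ)^(−b))^(−c)`, Weibull, and gamma (shape/scale).
- **Maximum-likelihood fitting** per family with AICc
  `−2ℓ + 2k + 2k(k+1)/(n−k−1)`; Burr III convergence failures are flagged
  and excluded downstream, never raised mid-benchmark.
- **Akaike weights** `w_i = exp(−ΔAICc_i/2) / Σ_k exp(−ΔAICc_k/2)` and the
  model-averaged HC (arithmetic weighted mean by default; geometric and
  mixture-CDF variants available).
- **Data ingest**: CSV records → unit normalization (µg/L), 5× water-
  solubility screen, geometric-mean collapse per species, chemical
  selection (≥ 51 species, ≥ 3 groups), nonparametric reference percentile
  (linear type-7 interpolation).
- **The benchmark**: 1,000 constrained subsamples (≥ 3 taxonomic groups,
  uniform by rejection) per chemical and size ∈ {5, 10, 15}; per-iteration
  deviations; 2.5/50/97.5 percentile summaries; cross-chemical aggregates.
- **Bimodality screen**: BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) on
  log10 species means with bias-corrected moments; BC > 0.555 flags bi- or
  multimodal SSDs (e.g. a hypersensitive taxon), compared between groups by
  Welch's t-test with Holm adjustment.
- **A synthetic-data generator** (log-normal or two-component mixture
  species sensitivities, multinomial taxonomic groups, replicate records
  with log-normal noise) with analytic ground-truth quantiles, so the whole
  pipeline is testable offline.

## Worked example

```python
import numpy as np
from ssdbench import (
    SyntheticStudyConfig, generate_chemical, collapse_to_species,
    fit_all, build_ensemble, model_averaged_hc, hc, reference_hc,
)

config = SyntheticStudyConfig(n_chemicals=1, n_species=60, seed=42)
records, truth = generate_chemical(config, np.random.default_rng(42))
dataset = collapse_to_species(records, "chem_001")
print(f"reference HC5 (empirical 5th percentile): {reference_hc(dataset, 0.05):.2f} ug/L")

fits = fit_all(dataset)
ensemble = build_ensemble(fits)
for fit, w in zip(ensemble.fits, ensemble.weights):
    print(f"{fit.family.value:8s} AICc={fit.aicc:7.2f} weight={w:.3f} "
          f"HC5={hc(fit, 0.05).value:7.2f}")
print(f"model-averaged HC5: {model_averaged_hc(ensemble, p=0.05).value:.2f} ug/L")
```

prints

```
reference HC5 (empirical 5th percentile): 3.70 ug/L
lnorm    AICc= 650.22 weight=0.517 HC5=   2.98
llogis   AICc= 651.01 weight=0.349 HC5=   2.92
burr3    AICc= 653.03 weight=0.128 HC5=   2.56
weibull  AICc= 659.26 weight=0.006 HC5=   0.86
gamma    AICc= 668.92 weight=0.000 HC5=   0.71
model-averaged HC5: 2.89 ug/L
```

The log-normal and log-logistic fits carry most of the weight and agree
with the nonparametric reference; the Weibull and gamma fits produce the
characteristically lower (more conservative) HC5 values, but their small
weights keep the model average close to the better-fitting families.

The same pipeline runs from the shell:

```bash
ssdbench run --seed 1 --outdir out            # synthetic study end to end
ssdbench simulate --seed 1 --outdir data      # just generate CSVs
ssdbench ingest data/*.csv --outdir tables    # validate + collapse
ssdbench benchmark tables/species_table.csv --seed 1 --outdir bench
```

`ssdbench run` writes `deviations.csv`, `summary.csv`, `aggregate.csv`,
`bimodality.csv`, optionally `comparison.csv`, and a `manifest.json` with a
content hash per artifact; the same config and seed reproduce every file
byte for byte.

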