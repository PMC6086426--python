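# ecothresh

Biodiversity-threshold analysis of community count data along a
habitat-cover gradient.

## The problem

When forest is cleared from a landscape, do forest-dependent communities
decline in proportion to the habitat lost, or is there an *extinction
(biodiversity) threshold* — a critical cover value below which abundance
and richness collapse abruptly?  `ecothresh` implements the full analysis
pipeline used to ask this question of plot-level community samples (the
motivating system is dung beetles pitfall-trapped in forest and
pasture-matrix plots across ten Atlantic Forest landscapes spanning 5–55%
forest cover):

1. **Habitat-use classification** — each species gets a literature label
   and, when ≥ 20 individuals were captured, an empirical label from an
   indicator-species analysis (IndVal: specificity × fidelity × 100 with a
   permutation test over habitat labels); the two are reconciled into
   forest specialist (FS), generalist (G), open-area specialist (OS), or
   unclassified.
2. **Response series** — per landscape and subgroup: total abundance,
   mean per-plot alpha diversity (with a t-based 95% CI over plots), and
   pooled gamma diversity, all observed counts (no richness estimators).
3. **Model fitting** — four candidate mean responses to percent forest
   cover *x*, fitted by numerical maximum likelihood (Poisson errors for
   abundance, normal errors for diversity):
   - NULL: `y = m`
   - GLM: `y = β₀ + β₁x`
   - LOG: `y = d + a / (1 + exp((b − x)/c))` — the threshold shape
   - BELL: `y = a·exp(−(b(x − d))²) + c` — the generalist inverted-U
4. **Model selection** — AICc ranking, Akaike weights
   `wᵢ = exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2)`, the ΔAICc ≤ 2 best set, plus
   diagnostics (residual–predictor correlation for model insufficiency,
   Pearson χ²/df overdispersion, Shapiro residual normality).
5. **Threshold estimation** — whenever LOG is in the best set, a
   piecewise (segmented) regression
   `y = β₀ + β₁x + β₂(x − ψ)·1[x > ψ]` estimates the breakpoint ψ by
   Muggeo-style linearization with a grid-search fallback, reporting the
   Wald SE and 95% CI.

A synthetic-data module generates landscape-community tables with known
generating truth (logistic FS decline, bell-shaped G response, flat OS
response, near-zero matrix spillover) so every stage is testable end to
end and supports power and parameter-recovery experiments.

## Worked example

```python
from ecothresh import (FitConfig, alpha_mean_series, fit_all, select,
                       threshold_report)
from ecothresh.selection import selection_to_frame
from ecothresh.simulate import ScenarioConfig, generate

table, truth = generate(ScenarioConfig(seed=42))
series = alpha_mean_series(table, "FS", "forest")
fits = fit_all(series, FitConfig(seed=42))
sel = select(fits, series_id=series.label)
print(selection_to_frame(sel).round(3).to_string(index=False))
log_b = next(f for f in fits if f.model == "LOG").params.values["b"]
est = threshold_report(sel, series, logistic_midpoint=log_b)
print(f"threshold: {est.breakpoint:.1f}% cover, "
      f"95% CI [{est.ci_low:.1f}, {est.ci_high:.1f}]")
```

prints

```
              series model  delta_aicc  K  weight  converged  in_best_set
FS_alpha_mean_forest  BELL       0.000  4   0.517       True         True
FS_alpha_mean_forest   LOG       0.201  4   0.468       True         True
FS_alpha_mean_forest   GLM       7.136  3   0.015       True        False
FS_alpha_mean_forest  NULL      20.109  2   0.000       True        False
threshold: 33.1% cover, 95% CI [25.7, 40.6]
```

Mean forest-specialist alpha diversity rises from ~2 to ~7 species per
plot across the gradient; the logistic (threshold) model is among the
best-supported shapes (ΔAICc ≤ 2), so a segmented regression estimates
where diversity starts to drop — here 33% cover, consistent with the
generating logistic (midpoint 25%, rate 3%), whose upper plateau ends
near midpoint + 2·rate.  The BELL fit ties because on a monotone series
it collapses to a half-bell.

The same analysis runs from the shell over CSV inputs:

```bash
ecothresh simulate --scenario scenario.yaml --out data/
ecothresh classify --counts data/counts.csv --covariates data/covariates.csv \
                   --literature data/literature.csv
ecothresh run --config run.yaml
```

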