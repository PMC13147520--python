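# biochromtox

Biomimetic-chromatography lipophilicity indices and their relation to
membrane-driven baseline toxicity, for small compound panels.

Bisphenol A and its structural analogues are widespread contaminants whose
toxicity is, to a substantial degree, governed by partitioning into cell
membranes (baseline toxicity, narcosis). Chromatographic retention on
phospholipid-functionalised stationary phases — immobilized artificial
membrane (IAM) and sphingomyelin columns — measures that membrane affinity
directly, unlike computed log *P* / log *D* descriptors. This package
implements the complete analysis chain for such a study:

* **Chromatographic indices** — gradient retention times are mapped onto
  the chromatographic hydrophobicity index (CHI) scale through an OLS
  calibration line `CHI = a·t_R + b` fitted to a standards mixture;
  isocratic sphingomyelin affinity is reported as
  `log k = log10((t_R − t_0)/t_0)`.
* **Potency transforms** — cytotoxic IC50 (µM) and aquatic EC50 (mg L⁻¹,
  converted to molar via molecular weight) become pIC50/pEC50 =
  −log₁₀(C/M), with three right-censoring treatments for values reported
  only as "> 100 µM": substitute 100 µM, substitute 200 µM (default), or
  exclude.
* **Correlation matrix** — Pearson *r* and Spearman ρ (midranks for ties)
  between every endpoint and every descriptor, with pairwise deletion,
  per-cell *n*, and the exact t-test p-value
  `t = r√(n−2)/√(1−r²)`, df = n−2.
* **Two-regime modelling** — the tissue-level vasodilation endpoint rises
  with membrane affinity up to a breakpoint and declines beyond it.
  Linear, quadratic and continuous segmented (hinge) models
  `y = β₀ + β₁x + β₂(x − ψ)₊` are fitted and compared by adjusted R²,
  AIC, BIC, RSE and a nested F-test; the breakpoint ψ is estimated by a
  deterministic exhaustive profile search; Cook's distance (threshold
  4/n) screens for influential compounds.
* **Tanimoto similarity** — pairwise `|A∩B|/|A∪B|` over ECFP4-style
  fingerprint bit vectors.
* **Synthetic panels** — a seeded generator producing descriptor/endpoint
  tables with the same statistical structure (correlated descriptors,
  lipophilicity-driven censored potency, hinge-shaped tissue response)
  for testing and parameter-recovery studies.

The printed descriptor and endpoint tables of the 18-bisphenol reference
panel ship as packaged fixtures, so the whole analysis runs out of the box.

## Worked example

```python
import pandas as pd
import biochromtox as bct

descriptors = bct.load_descriptors()             # 18 compounds x 9 descriptors
endpoints   = bct.apply_scenario(bct.load_endpoints(),
                                 bct.CensoringScenario.truncate200)

xy = pd.concat([descriptors.descriptors["chi_iam"],
                endpoints.values["vasodilation_pct"]], axis=1).dropna()
seg = bct.SegmentedModel(xy.iloc[:, 1], xy.iloc[:, 0]).fit()
print(seg.summary())
```

prints

```
segmented model  (n=13, k=4)
  coefficients: -64.83, 2.934, -10.34
  RSS=1334  R2=0.8055  R2_adj=0.7407
  AIC=107.09  BIC=109.92  RSE=12.17
  breakpoint psi=47.21  left slope=2.934  right slope=-7.407  (R2_adj at fixed psi: 0.7666)
```

i.e. vasodilation increases by about 2.9 percentage points per CHI_IAM
unit up to a breakpoint at CHI_IAM ≈ 47.2 and falls by about 7.4 points
per unit beyond it — compounds with very high membrane affinity are
*less* vasoactive, consistent with sequestration in the lipid bilayer.
`bct.compare_models([...])` ranks this segmented fit best by AIC against
the linear and quadratic alternatives, and
`bct.cooks_distance(seg, index=xy.index)` reports per-compound influence
against the 4/13 = 0.308 threshold.

The same analysis is available from the shell:

```sh
biochromtox run --out results/           # full pipeline on the packaged panel
biochromtox correlate --out matrix.csv   # Pearson/Spearman matrix only
biochromtox simulate --n 18 --seed 7 --out synth/
```

`run` writes `correlation_matrix.csv`, `model_comparison.json`,
`influence.csv` and `run_log.txt`; outputs are byte-identical across
repeated runs with the same inputs and configuration.

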