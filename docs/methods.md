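# Methods

## Scope and data model

The package analyses a small compound panel (here 18 bisphenol
analogues) characterised by nine lipophilicity descriptors — six computed
(ACD log *P* classic / consensus / GALAS, ACD log *D*, Chemicalize
log *P* / log *D*) and three chromatographic (CHI on a C18 phase, CHI on
a phosphatidylcholine IAM phase, isocratic sphingomyelin log *k*) — and
six toxicity endpoints: pIC50 in four mammalian cell lines (3T3-L1,
MCF-7, C6, HeLa), *ex vivo* vasodilation (% of maximal relaxation) and
pEC50 for *Daphnia* immobilisation. Tables are wide, one compound per
row; missing cells are explicit (blank / `N.D` / `N.A.` on input) and
every statistic carries its own pairwise-complete *n*.

## Chromatographic indices

Gradient CHI values are obtained by calibration: an unweighted OLS line
`chi_ref = slope·t_R + intercept` is fitted to ≥3 standards and applied
to analyte retention times. The calibration is deliberately
user-supplied — reference CHI values for the usual standards mixture
(acetanilide … octanophenone) are laboratory constants, and the shipped
`standards_synthetic.csv` is a synthetic, clearly non-authoritative
example generated from a stated linear model. Predictions outside the
standards' retention range are flagged and warned about unless
extrapolation is explicitly enabled. The regression direction (CHI on
t_R, not the reverse) matches the gradient-calibration protocol in which
CHI is the predicted quantity.

Isocratic sphingomyelin affinity uses the universal retention-factor
convention `k = (t_R − t_0)/t_0`, `log k = log10 k`, with the column dead
time t_0 supplied as configuration (how dead time is measured is a
laboratory choice, not inferred here). Triplicates are aggregated by
arithmetic mean; a relative spread above 3 % of the mean warns but does
not abort. The result is invariant under rescaling the time unit applied
to both t_R and t_0.

## Potency and censoring

pIC50 = −log10(IC50/M) with IC50 in µM; pEC50 converts mg L⁻¹ to molar
through the molecular weight first. Values reported only as
"IC50 > 100 µM" are right-censored; three substitution scenarios are
implemented (100 µM, 200 µM, exclusion), with 200 µM the default because
the packaged endpoint table is expressed on it. For any censored cell the
identity pIC50(200) = pIC50(100) − log10 2 holds exactly. No
survival-style censoring likelihood is used — the scenarios are simple
substitutions by design. Molecular weights live in the compound table;
the structure adapter can compute them but fixtures store them
explicitly, so the conversion never silently depends on an external
toolkit. Computation is full precision; two-decimal rounding (half away
from zero) is applied only when printing.

## Correlation matrix

Each (endpoint, descriptor) cell restricts to the endpoint's compound
subset (only vasodilation is restricted by default — see below), drops
pairs with a missing value in either variable, and requires n ≥ 3 and
non-zero variance; otherwise the cell is missing with a logged reason.
Spearman ρ is computed as the Pearson coefficient of midranks rather
than the 6Σd² shortcut because the panel contains tied potency values
(three identical censored cells in MCF-7), and the shortcut is biased
under ties. Significance of r uses the exact t reference distribution.
No multiple-testing correction is applied, matching the descriptive
intent of a 54-cell screening matrix. The largest |r| per endpoint row is
flagged.

The vasodilation endpoint is correlated on the n = 8 low-to-moderate
membrane-affinity subset for all descriptor columns: the five compounds
with CHI_IAM above ≈50 (BPZ, BPG, BPP, BPPH, BPBP) form a distinct
high-affinity regime in which the response declines, so a straight-line
correlation over all 13 compounds would mix two regimes. The subset can
equivalently be specified as a numeric CHI_IAM threshold; at 50 both
rules select the same compounds.

A caution is written to the run log for the *Daphnia* row: the published
reference coefficients for that endpoint are not reproducible from the
packaged panel by direct recomputation (our computation gives r ≈ 0.83
against CHI_IAM where ≈0.97 has been reported), so that row should be
interpreted with care. The pipeline still computes and emits it.

## Two-regime modelling

Three models of vasodilation on CHI_IAM are fitted by OLS: linear,
quadratic, and the continuous hinge
`y = β₀ + β₁x + β₂(x − ψ)₊`, in which β₁ is the low-regime slope and
β₁+β₂ the high-regime slope. The breakpoint is estimated by exhaustive
profile search rather than iterative linearisation: RSS(ψ) is profiled
on a coarse grid (1st–99th percentile of x, step = range/400), refined
on an exact 0.01-resolution grid around the coarse optimum, and finally
polished with candidates at 0.001 resolution plus points immediately
beside the data values. The polish step exists because RSS(ψ) is
continuous but can fall steeply toward the admissibility boundary next
to a data point, where fixed grids cannot land; with it, the search
matches flat 0.001-resolution enumeration on small datasets. A candidate
ψ is admissible when at least two distinct x values lie strictly on each
side; RSS ties resolve to the smallest candidate. The search is
deterministic and global over the grid. One breakpoint only; no
confidence interval for ψ is produced.

Conventions, stated because only differences matter for ranking:

* AIC = n·ln(2π·RSS/n) + n + 2(k+1) and BIC with ln(n)(k+1), counting
  the error variance as a parameter — the convention of the R `AIC()`
  generic, so rankings are comparable with analyses done there. Hence
  BIC − AIC = (ln n − 2)(k+1) for every fit.
* The segmented model counts k = 4 mean parameters (intercept, slope,
  slope change, breakpoint) in adjusted R², AIC, BIC and RSE. Whether ψ
  should consume a degree of freedom is genuinely convention-dependent,
  so the 3-parameter alternative is also reported
  (`r2_adj_fixed_psi`). On the packaged panel the two conventions give
  0.741 and 0.767 respectively.
* The quadratic model is tested against the linear one by the nested
  F-test `F = ((RSS₁−RSS₂)/(df₁−df₂))/(RSS₂/df₂)`.

Cook's distance is computed on the segmented fit with the hinge column
held fixed at the estimated ψ (an OLS design with p = 3 columns):
`D_i = e_i²h_ii/(p·s²(1−h_ii)²)`, `s² = RSS/(n−p)`, threshold 4/n
(0.308 at n = 13). This equals the leave-one-out refit definition, which
the test suite verifies directly. On the packaged panel one compound
(BPPH) exceeds the threshold under this convention; the segmented result
itself is obtained on all 13 observations with nothing removed.

## Tanimoto similarity

Similarity operates on fixed-length binary fingerprints
(`|A∩B|/|A∪B|`); generation from SMILES is an optional RDKit adapter
(Morgan radius 2, 2048 bits) because hashed bit patterns are
toolkit-version-dependent — persisted bit vectors, not structures, are
the stable interchange format. Two all-zero vectors yield 0 with a
warning. A known limitation of hashed circular fingerprints is visible
in the packaged panel: BPA and BPP share every radius-2 atom
environment and therefore have identical fingerprints (similarity
exactly 1) despite being different molecules.

## Synthetic panels

The generator's defaults mirror the packaged panel's scale: a one-factor
latent lipophilicity model with inter-descriptor correlation 0.85,
CHI_IAM mean 44 and SD 7; potency pIC50 = 0.5 + 0.07·CHI_IAM + ε with
ε ~ N(0, 0.25²) and right-censoring at 100 µM; a hinge-shaped tissue
response with breakpoint 47, slopes +3.3 / −8 % per CHI_IAM unit, height
80 % at the breakpoint, noise SD 6, clipped to [0, 100]; missing cells
injected completely at random. Potency is parameterised on the pIC50
scale (linear in CHI_IAM) because that is the scale of the analysis.
The analytic censoring fraction Φ((pIC50_ceiling − m)/s), with m and s
the marginal mean and SD of pIC50, is exposed for convergence checks.

What the generator does *not* emulate: chromatographic peak shapes or
gradient dynamics (indices are drawn directly), structure-driven
fingerprints, correlated missingness, inter-laboratory variation, or
heteroscedastic assay noise. Passing recovery tests therefore
demonstrates the estimators' correctness under the stated statistical
structure, not robustness to every feature of real laboratory data.

Parameter recovery at n = 100 with tissue-response noise SD 3 recovers
the breakpoint within ±1 CHI_IAM unit in well over 90 % of seeded
replicates; the test suite runs 200 replicates at that size, a scale
chosen to exercise the estimator densely while keeping the default test
run fast.

## Degenerate inputs and numerical choices

Duplicate compound ids, non-numeric cells, vasodilation outside
[0, 100], non-positive concentrations, unit mismatches (µM vs mg L⁻¹)
and degenerate designs are hard errors; small-n or zero-variance
correlation cells, empty regime sides, replicate-spread violations and
calibration extrapolation degrade to missing values or warnings, because
they are expected states of a sparse panel. Outputs are deterministic:
fixed file names, sorted JSON keys, no timestamps, and a single seeded
random stream for anything synthetic.
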