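# vakgbm

Volume–Age–KPS (VAK) prognostic classification for glioblastoma, with the
downstream molecular analysis it anchors: MGMT/VAKM stratification, two-class
marker selection, cognate microRNA–gene network ranking, and a 25-molecule
prognostic signature — plus a synthetic radiogenomic cohort generator so the
whole pipeline is testable without any data download.

## Who this is for

Researchers working with radiogenomic GBM cohorts (TCGA/TCIA/REMBRANDT-style
exports: a clinical table, a log2 expression matrix of genes and microRNAs,
and a microRNA→gene binding-prediction table) who want a reproducible,
oracle-tested implementation of the VAK scoring rules and the signature
construction, or a simulator with known ground truth for method evaluation.

## The model

**VAK score.** Each patient receives one point per adverse factor:

- tumor volume ≥ 30,000 mm³ *or* mean of the two largest orthogonal lesion
  diameters ≥ 40 mm,
- age ≥ 60 years,
- KPS < 100.

0–1 points → **VAK-A** (favorable), 2–3 points → **VAK-B** (unfavorable).
MGMT promoter methylation is called by a median cutoff on the per-patient
mean probe beta-value, refining the classes into VAK±M groups.

**Survival statistics.** Kaplan–Meier product-limit curves
S(t) = Π (1 − dᵢ/nᵢ), first-crossing medians, the two-group log-rank test
with hypergeometric variance, and Cox proportional-hazards fits by
Newton–Raphson on the partial likelihood (Efron or Breslow ties) with
likelihood-ratio tests — all implemented from the defining formulas and
cross-checked against independent oracles and `lifelines` in the test suite.

**Marker selection.** Per feature, the signal-to-noise ratio
(μ_A − μ_B)/(σ_A′ + σ_B′) with σ floored at max(0.2·|μ|, ε), a two-sided
permutation p-value (1 + #{|s*| ≥ |s|})/(B + 1), and the signed linear fold
regulation ±2^|μ_A−μ_B|. Genes and microRNAs are ranked in separate pools.

**Cognate networks and rank score.** Within each class, predicted
miRNA→gene pairs with opposite fold signs form a bipartite module; every
connected molecule is scored by the product
(−log₁₀ p) · |fold| · binding strength · #inverse partners, negative for
microRNAs and positive for mRNAs. The top 12 (A) + 13 (B) molecules form the
25-molecule signature; a patient's signature score is the ratio of mean
linear expression of A-molecules to B-molecules, and the cohort median splits
patients into signature-high (VAK-A-like) and signature-low groups.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_vak_classification.py` (seed 7, 142 synthetic patients):

```
VAK-A: n=75, KM median = 20.9 months
VAK-B: n=67, KM median = 11.2 months
log-rank: chi2 = 6.06, p = 0.0138
```

The classes separate by roughly the planted 20-vs-12-month medians and the
log-rank test rejects equality. `python examples/03_marker_to_signature.py`
continues to the molecular stage:

```
VAK-A module: 12 connected molecules, 27 edges
VAK-B module: 13 connected molecules, 40 edges
signature: 12 VAK-A + 13 VAK-B molecules
signature-high: n=71, KM median = 21.2 months
signature-low: n=71, KM median = 12.5 months
signature log-rank p = 0.0133
planted molecules recovered: 25/25
```

All 25 planted signature molecules are recovered, and the signature-derived
groups reproduce the survival separation without using any imaging variable.

The same pipeline is scriptable from the shell:

```bash
vak simulate --preset paper-like --seed 7 --outdir sim/
vak classify --clinical sim/clinical.tsv --out vak.tsv
vak run --config pipeline.yaml        # full pipeline from a YAML config
```

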