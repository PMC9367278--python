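# tcoxnet

Correlation-guided penalized Cox survival models for gene-signature
selection in tumor/normal expression cohorts, with a repeated
stability-selection protocol, Kaplan–Meier / log-rank risk stratification,
differential-expression ranking and a pre-ranked GSEA core.

## The problem

In bulk RNA-seq cancer cohorts the number of genes (p ≈ 20,000) dwarfs the
number of patients (n ≈ 500), so penalized Cox proportional-hazards models
are the standard route to prognostic gene signatures — but plain
ℓ1-penalized selection is unstable on correlated expression data. This
package implements two remedies used together:

1. **A correlation-dissimilarity penalty (TCox weighting).** For each gene
   *j*, compare its correlation profile σⱼ (the *j*-th column of the
   gene–gene Pearson correlation matrix) between tumor (T) and normal (N)
   tissue through the angle

       dⱼ = arccos( ⟨σⱼᵀ, σⱼᴺ⟩ / (‖σⱼᵀ‖‖σⱼᴺ‖) ),   wⱼ = dⱼ / max_k d_k,

   and penalize each coefficient with the factor qⱼ = 1/wⱼ inside the
   elastic-net Cox objective

       −ℓ(β)/n + λ [ α‖q∘β‖₁ + (1−α)‖q∘β‖₂² ],

   where ℓ is Cox's partial log-likelihood (Breslow ties). Genes whose
   co-expression pattern changes most between tumor and normal tissue get
   the smallest penalty and are favored for selection. q ≡ 1 recovers the
   plain elastic net (EN).

2. **Stability selection.** The model is refit many times (default 100):
   each run tunes λ by 10-fold cross-validated partial-likelihood deviance
   on a censoring-stratified 70% subsample, refits on the full cohort,
   splits patients at the median fitted relative risk exp(xᵢᵀβ) and records
   the log-rank p-value of the split. Genes selected in at least 50% of
   runs form the signature.

The solver (cyclic coordinate descent inside a proximal-Newton loop, with a
KKT certificate) is implemented here; Kaplan–Meier/log-rank go through
lifelines, BH-FDR through statsmodels. A synthetic-cohort generator with
block-correlated expression, planted differential-correlation genes and an
exponential-baseline Cox survival simulator (≈67% censoring) makes every
stage testable without any external data.

## Worked example

```python
from tcoxnet.syndata import SyntheticConfig, generate_dataset
from tcoxnet.netweights import penalty_weights
from tcoxnet.evalprotocol import run_protocol, stability_selection, summarize_runs

cfg = SyntheticConfig(seed=11)          # 200 genes, 300 tumor / 300 normal
ds = generate_dataset(cfg)
X_tumor = ds.expression[ds.tumor_samples()]
X_normal = ds.expression[ds.normal_samples()]
print(f"censored fraction: {ds.survival.censored_fraction():.3f}")

pw = penalty_weights(X_tumor, X_normal)   # correlation-dissimilarity factors
records = run_protocol(X_tumor, ds.survival, alpha=0.1, q=pw.q,
                       n_runs=10, base_seed=0)
summary = summarize_runs(records)
print(f"mean log-rank p: {summary['mean_p_value']:.2e}, "
      f"mean genes selected: {summary['mean_n_genes']:.1f}")
stab = stability_selection(records, threshold=0.5)
print("top stable genes:")
print(stab.frequency.head(8).to_string())
```

prints

```
censored fraction: 0.673
mean log-rank p: 1.37e-10, mean genes selected: 21.5
top stable genes:
gene
G000    1.0
G003    1.0
G008    1.0
G100    1.0
G150    1.0
G001    0.9
G004    0.9
G050    0.9
```

The generator planted prognostic effects on G000, G025, G050, G100 and
G150; four of the five sit at the top of the stability ranking (G000, G100,
G150 always selected), the censoring level matches the ≈67% target, and the
tiny mean log-rank p reflects both the real signal and the deliberate
in-sample optimism of the published evaluation scheme (the risk split is
fitted and evaluated on the whole cohort; see `docs/methods.md`). Genes
like G003/G008 ride along because they share a correlation block with G000
— the instability that motivates stability selection in the first place.

A command-line interface mirrors the library
(`tcoxnet simulate | prep | de | weights | fit | evaluate | gsea | run`);
`tcoxnet run --config pipeline.yaml` executes the full EN + TCox workflow
and writes per-stage manifests.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the reportable cohort quantities: hazard ratios exp(β) for the
published ridge-regression coefficients of the consensus gene panels
(targets t1–t4) and the percentage of censored samples among the 537
cohort samples with follow-up (t5), after a small synthetic end-to-end
smoke run of the pipeline. Values are written as JSON, one entry per
target.
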