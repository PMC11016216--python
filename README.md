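# pqtlmr

Proteome-wide causal screening with two-sample Mendelian randomization
(MR), Bayesian colocalization and two-step mediation MR.

Circulating proteins are a major source of drug targets, but
observational protein–disease associations are confounded.  `pqtlmr`
implements the genetic-epidemiology workflow that screens plasma
proteins for putatively causal effects on quantitative imaging
outcomes (e.g. visceral adipose tissue volume, liver fat) using
protein quantitative trait loci (pQTLs) as instrumental variables, and
then stress-tests each hit:

1. **Instrument selection** — per protein, keep genome-wide-significant
   pQTLs (p ≤ 5×10⁻⁸), drop the MHC region (chr6:26–34 Mb), LD-clump
   at r² < 0.001 preferring the smallest p, drop variants associated
   with ≥ 5 proteins, and drop weak instruments
   (F = R²(N−2)/(1−R²) < 10 with R² = 2·maf·(1−maf)·β²).
2. **MR estimation** — a single instrument gives the Wald ratio
   β̂ = β_GY/β_GX; multiple instruments give the inverse-variance
   weighted estimate β̂_IVW = Σwβ_GXβ_GY / Σwβ_GX² (w = 1/se_GY²),
   with MR-Egger (slope + pleiotropy intercept), weighted median,
   weighted mode and Cochran's Q when ≥ 3 instruments are available.
   Exposure/outcome tables are harmonized to a common effect allele;
   palindromic (A/T, C/G) variants are excluded, and missing variants
   may be replaced by proxies in high LD (r² > 0.8).
3. **Colocalization** — Wakefield approximate Bayes factors per
   variant in a ±1 Mb window (MAF > 0.01) combine into posterior
   probabilities PPH0–PPH4 of the five single-causal-variant
   hypotheses; PPH4 > 0.8 calls a shared causal variant (PPH4 > 0.6
   suggestive).  This separates true protein→outcome effects from
   LD-confounded ones (distinct causal variants, high PPH3).
4. **Mediation** — for proteins that also affect a screened risk
   factor (Step-2 MR) which itself affects the outcome (Step-1 MR),
   the indirect effect is the product β₁β₂ with Delta-method SE
   √(β₁²se₂² + β₂²se₁²), and the proportion mediated is β₁β₂/β₃ of
   the total effect β₃.  A reverse MR flags bidirectional
   mediator–protein relationships.

Family-wise error is controlled by Bonferroni correction per test
family (α/m; e.g. 0.05/1002 proteins → 4.99×10⁻⁵).

Because the underlying cohort GWAS cannot be redistributed, the
package ships a synthetic-GWAS generator (`pqtlmr.simulate`) that
produces summary statistics with known causal structure — true causal
effects θ, directional pleiotropy α, exponential-decay LD, palindromic
variants — so every stage can be validated against ground truth.

## Worked example

Simulate a small screen — 6 null proteins, 2 truly causal proteins
(shared causal variant with the outcome, θ = 0.4), and 1 LD-confounded
protein (the outcome signal sits on a *different* variant in LD with
the pQTL) — then run the full pipeline:

```python
import pqtlmr as pq

study = pq.simulate_screen_study(n_null=6, n_causal=2, n_confounded=1, seed=42)
report = pq.run_full_screen(study.protein_tables,
                            {study.outcome_id: study.outcome_table},
                            study.panel, config=pq.ScreenConfig(seed=42))

prim = report.primary
print(prim.loc[prim["primary"] & prim["significant"],
               ["exposure", "outcome", "method", "nsnp", "beta", "se", "pval"]])
print(report.coloc[["exposure", "pph3", "pph4", "call", "prioritized"]])
```

```
 exposure    outcome method  nsnp     beta       se         pval
prot_0000 vat_volume   wald     1 0.439679 0.043012 1.578128e-24
prot_0004 vat_volume   wald     1 0.417136 0.038564 2.869496e-27
prot_0008 vat_volume   wald     1 0.440252 0.041064 8.110692e-27

 exposure         pph3         pph4            call  prioritized
prot_0000 1.000000e+00 3.681671e-24 not_colocalized        False
prot_0004 1.447255e-07 9.999999e-01     colocalized         True
prot_0008 4.600950e-07 9.999995e-01     colocalized         True
```

All three non-null proteins clear the Bonferroni threshold in the MR
screen with effect sizes near the true θ ≈ 0.4 (dense LD collapses
each region to its lead pQTL, so the Wald ratio is the primary
estimator).  Colocalization then separates them: the two causal
proteins share their causal variant with the outcome (PPH4 ≈ 1,
prioritized), while the confounded protein's signal resolves to a
distinct variant (PPH3 ≈ 1) and is excluded — exactly the failure
mode colocalization exists to catch.  In this run `prot_0000` is the
confounded protein, `prot_0004` and `prot_0008` the causal ones.

The same stages are available from the shell: `pqtlmr simulate`,
`pqtlmr instruments`, `pqtlmr mr`, `pqtlmr coloc`, `pqtlmr mediate`
and `pqtlmr screen` (see `pqtlmr --help`).

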