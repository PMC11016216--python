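# Methods

This note documents the statistical models implemented in `pqtlmr`,
the defaults chosen where the methodology literature leaves room, and
what the synthetic-data validation does and does not demonstrate.

## Two-sample MR model

Each genetic instrument *j* contributes a pair of summary estimates:
its effect on the exposure (β_GX,j, se_GX,j) from one GWAS and on the
outcome (β_GY,j, se_GY,j) from a non-overlapping GWAS.  Under the
instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction) each ratio β_GY,j/β_GX,j estimates
the same causal effect θ.

- **Wald ratio** (1 instrument): β̂ = β_GY/β_GX, se = se_GY/|β_GX|.
  First-order only — exposure-side noise is ignored (see
  *Weak-instrument behaviour* below).
- **IVW** (≥ 2): zero-intercept weighted regression of β_GY on β_GX
  with weights 1/se_GY².  Default mode is multiplicative
  random-effects: the analytic SE is scaled by the residual standard
  deviation of the weighted fit, floored at 1, so heterogeneity widens
  but never narrows intervals.  Fixed-effect is available via
  `mode="fixed"`.
- **MR-Egger** (≥ 3): same regression with a free intercept, after
  orienting every instrument so β_GX ≥ 0.  The intercept estimates the
  average directional pleiotropy under the InSIDE assumption; its
  two-sided p is the pleiotropy test.  SEs are inflated by the
  residual scale, floored at 1.
- **Weighted median** (≥ 3): the 50% point of the
  inverse-variance-weighted empirical distribution of per-SNP ratios
  (weights (β_GX/se_GY)², cumulative weights S_j = Σ_{i≤j}w_i − w_j/2,
  linear interpolation).  Consistent when ≥ 50% of weight comes from
  valid instruments.  SE from a seeded parametric bootstrap (per-SNP
  effects resampled from their normal sampling distributions; 1000
  replicates by default).
- **Weighted mode** (≥ 3): argmax of the weighted normal-kernel
  density of ratios.  Bandwidth = 0.9·min(sd, MAD/Φ⁻¹(0.75))·n^(−1/5)
  times a user factor; the argmax is searched on a 512-point grid over
  the ratio range.  Bootstrap SE as above.
- **Cochran's Q**: Q = Σ w_j(ratio_j − β̂_IVW,fixed)² with
  w_j = (β_GX,j/se_GY,j)², referred to χ²(nsnp − 1).

All p-values are two-sided normal (not t) and CIs use ±1.96 se; that
convention reproduces printed CI arithmetic in the published tables
this package's consistency checks target.  Dispatch
(`mr_auto`): 1 instrument → Wald only; 2 → IVW + Q; ≥ 3 → all methods.

### Weak-instrument behaviour

IVW's first-order SE ignores exposure-side sampling error (the NOME
approximation), so its 95% CI attains nominal coverage only when
instruments are strong.  Measured with the package's own generator
(10 instruments, θ = 0.3): coverage is 0.947 at per-instrument
F ≈ 10⁴ (lead-pQTL scale, n_exposure = 5×10⁵, R² = 0.02 per variant)
but degrades to ≈ 0.81 at F ≈ 200.  Under the null (θ = 0) the NOME
term vanishes and the type-I error is calibrated (0.0515 at nominal
0.05 over 2000 replicates) for any instrument strength.  The
calibration tests therefore probe the null at default strength and
coverage in the strong-instrument regime.

## Instrument selection

Selection order is significance (p ≤ 5×10⁻⁸) → MHC exclusion
(chromosome 6, 26–34 Mb, GRCh37, 1-based inclusive) → greedy clumping
(sort by ascending p, tie-break by variant id; keep a variant iff its
r² with every already-kept variant is < 0.001) → cross-protein
pleiotropy exclusion (≥ 5 proteins, counted at p ≤ 5×10⁻⁸ pooled over
all supplied protein GWAS) → weak-instrument removal (F < 10).  Each
removal is recorded with its rule in a provenance map, so the
attrition from candidate pQTLs to instruments is auditable.

R² defaults to the standardized-trait approximation
2·maf·(1−maf)·β²; the z²/(z² + n) form is available via
`SelectionParams(r2_formula="z2")` for per-allele effects on
unstandardized traits.

Harmonization expresses outcome effects on the exposure's effect
allele (sign-flip for swapped labels, strand complement where needed),
drops palindromic variants unconditionally (no frequency-based
rescue) and drops irreconcilable allele sets.  Instruments absent
from the outcome GWAS are replaced by the best available proxy with
r² > 0.8 (ties: smaller distance, then lexicographic id); the proxy's
own outcome association is used unscaled.

## Colocalization

For a quantitative trait, the per-variant Wakefield log approximate
Bayes factor is log ABF = ½[log(1 − r) + r·z²] with r = W/(V + W),
V = se², and effect prior W = (0.15·sd_trait)².  Hypothesis evidence
(H0 none, H1/H2 one trait, H3 two distinct causal variants, H4 one
shared) accumulates in log space; H3's sum over distinct variant
pairs uses a direct double sum for regions of ≤ 64 variants and a
guarded log-space complement above that.  Priors default to
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the conventional single-variant
colocalization defaults — the analysis this package systematizes
states none).  Calls: PPH4 > 0.8 colocalized, > 0.6 suggestive.
Single-variant regions cannot support H3; PPH3 is set to 0 with a
recorded note.  Case-control ABFs are out of scope (all primary
outcomes here are quantitative).  Where a gene has several pQTL
regions, per-region posteriors are reported and a per-gene maximum
may be taken downstream; the package itself reports per region.

## Mediation

Indirect effect by the product method (β₁β₂) with first-order
Delta-method SE omitting covariance terms — appropriate for the
three estimates coming from non-overlapping samples.  The proportion
mediated β₁β₂/β₃ gets a first-order ratio-Delta CI; proportions
outside [0, 1] and sign-inconsistent decompositions are reported with
warnings rather than truncated, and a significant reverse MR
(mediator → protein, strict inequality at the protein-family
threshold) annotates rather than removes the result.  The identity
direct + indirect = total holds to machine precision by construction.

## Screening pipeline

Bonferroni thresholds are per family: α divided by the number of
*distinct proteins* tested (1002 in the motivating analysis — not the
number of protein×outcome tests) and by the number of risk factors
(18 → 0.0028).  One published abstract rounds the latter to 0.0024;
the Methods-consistent 0.05/18 is implemented.  Both family sizes and
the resulting thresholds are recorded in the run manifest, along with
a config hash and seed, and report tables are written
deterministically (same inputs → byte-identical files).  Proteins
with zero surviving instruments appear as `untestable` rows rather
than disappearing.

## Synthetic-data generator

Traits are simulated in standardized (SD) units, making instrument
strength closed-form: a variant explaining R² of the exposure has
per-allele effect √(R²/(2·maf·(1−maf))) and SE 1/√(2·maf·(1−maf)·N).
Outcome effects at instruments are θ·β_GX,true + α·sign(β_GX,true) + ε
with ε ~ N(0, 1/N_outcome); pleiotropy α is injected on the
exposure-increasing allele orientation, the convention under which a
constant α is directional pleiotropy recoverable by the Egger
intercept.  Exposure and outcome noise are independent (two-sample
design); an overlap fraction can correlate them.

LD is a one-parameter exponential kernel, r(i,j) = exp(−decay·d_ij).
Within colocalization regions, sampling noise is drawn *LD-correlated*
(noise vector = L·z with L a factor of the correlation matrix),
matching the large-sample covariance of marginal GWAS z-scores.  This
matters: with independent per-variant noise the two traits' observed
peaks land on different variants inside a tight LD block and PPH3
spuriously rivals PPH4 even under a shared causal variant.

Default study conditions: maf ~ U(0.05, 0.5), per-variant
R² ∈ [0.005, 0.05] (a modelling choice — the variance-explained
distribution of real pQTLs is not published), exposure N = 10⁴,
outcome N = 3×10⁴ (imaging-cohort scale), 10% palindromic variants to
exercise harmonization.  The end-to-end scenario gives each protein
its own 40-variant region (decay 2×10⁻⁵, 5 kb spacing) with the pQTL
at the centre; an LD-confounded protein places the outcome's causal
variant at the region position whose r² with the pQTL is closest to
0.4, scaled so the apparent MR effect matches θ — strong enough for MR
to flag, distinct enough for colocalization to reject.

What the generator does *not* emulate: realistic genome-wide LD
panels, allele-frequency spectra, individual-level genotypes, sample
overlap between the five source proteomic GWAS, winner's-curse in
instrument discovery, or binary outcomes.  Passing tests therefore
demonstrate correctness of the estimators and decision logic under
the stated model, not robustness to every artefact of real cohort
data.

## Problem sizes in the validation suite

Calibration experiments use 2000 replicates (type-I error, coverage,
null p-value uniformity), 500 replicates (Egger intercept recovery,
F-statistic calibration), 200 replicates per colocalization scenario
at 50 variants, and 20 seeds of a 25-protein screen for end-to-end
recovery; the brute-force colocalization oracle covers regions of 2–6
variants in linear probability space, and the clumping oracle
enumerates candidate sets of up to 12 variants.
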