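"""Synthetic GWAS summary statistics with known causal structure.

Every downstream stage of the screening pipeline (instrument selection,
MR estimation, colocalization, mediation) is exercised against data
generated here, so the generators carry explicit ground truth: the true
causal effect of each protein on each outcome (``theta``), per-variant
horizontal pleiotropy (``alpha``), and the identity of causal variants
inside LD-structured regions.

Traits are simulated in standardized (SD) units throughout, which makes
the instrument-strength arithmetic closed form: a variant explaining a
fraction ``r2`` of a standardized exposure has per-allele effect
``beta = sqrt(r2 / (2 * maf * (1 - maf)))`` and sampling standard error
``1 / sqrt(2 * maf * (1 - maf) * n)``.  LD is an exponential-decay
kernel in base-pair distance: ``r(i, j) = exp(-decay * |pos_i - pos_j|)``,
a single-parameter model that yields dense, realistic r² for clumping,
proxy lookup and colocalization without individual-level genotypes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SUMSTATS_COLUMNS

# Non-palindromic effect/other allele pairs (effect allele is always the
# alternate allele); palindromic pairs injected to exercise harmonization.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                 ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _derive_seed(seed: int, *labels) -> int:
    """Stable sub-stream seed from a base seed and string labels."""
    h = zlib.crc32("|".join(str(x) for x in labels).encode())
    return (int(seed) * 1_000_003 + h) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TruthConfig:
    """Ground-truth configuration for a simulated two-sample MR study.

    Parameters
    ----------
    n_proteins : int
        Number of simulated protein exposures.
    n_variants_per_protein : int
        Candidate instruments generated per protein.
    n_exposure, n_outcome : int
        GWAS sample sizes for the exposure and outcome studies.
    theta : mapping protein id -> (mapping trait id -> float)
        True causal effect of each protein on each downstream trait,
        in SD units of the trait per SD of protein level.
    alpha : float
        Per-variant horizontal-pleiotropy effect on downstream traits
        (SD units); a non-zero value injects directional pleiotropy
        detectable by the MR-Egger intercept.
    maf_range : (float, float)
        Uniform sampling range for effect-allele frequencies.
    instrument_r2 : float or (float, float)
        Variance of the exposure explained per instrument; a pair is a
        uniform sampling range.
    palindromic_rate : float
        Fraction of variants given A/T or C/G allele codes, to exercise
        harmonization filters.
    sample_overlap : float
        Correlation between exposure and outcome sampling noise; 0 is
        the two-sample (non-overlapping) design.
    """

    n_proteins: int = 1
    n_variants_per_protein: int = 10
    n_exposure: int = 10_000
    n_outcome: int = 30_000
    theta: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    alpha: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_r2: float | tuple[float, float] = (0.005, 0.05)
    palindromic_rate: float = 0.1
    sample_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_exposure < 10 or self.n_outcome < 10:
            raise ValueError("sample sizes must be >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        r2 = self.instrument_r2
        if np.isscalar(r2):
            r2 = (float(r2), float(r2))
            object.__setattr__(self, "instrument_r2", r2)
        if not (0 <= r2[0] <= r2[1] < 1):
            raise ValueError("instrument_r2 must lie in [0, 1)")
        for trait_map in self.theta.values():
            for v in trait_map.values():
                if not np.isfinite(v):
                    raise ValueError("theta entries must be finite")
        if not 0 <= self.sample_overlap <= 1:
            raise ValueError("sample_overlap must lie in [0, 1]")

    def r2_bounds(self) -> tuple[float, float]:
        r2 = self.instrument_r2
        return (r2, r2) if np.isscalar(r2) else tuple(r2)


@dataclass
class SimulatedStudy:
    """One simulated GWAS: a trait id, its summary table, and its truth.

    ``true_beta`` holds the noise-free per-allele effects underlying the
    observed ``table`` so downstream generators can propagate signal
    without re-estimating it.
    """

    trait_id: str
    table: pd.DataFrame
    truth: TruthConfig
    true_beta: np.ndarray | None = None

    def __post_init__(self):
        t = self.table
        if not np.isfinite(t[["beta", "se"]].to_numpy()).all():
            raise ValueError("non-finite effect estimates in simulated study")
        if (t["se"] <= 0).any():
            raise ValueError("non-positive standard errors in simulated study")
        if ((t["pval"] <= 0) | (t["pval"] > 1)).any():
            raise ValueError("p-values outside (0, 1] in simulated study")
        if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
            raise ValueError("allele frequencies outside (0, 1)")


@dataclass
class LDReference:
    """Pairwise squared-correlation matrix for one chromosome's variants."""

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray
    chromosome: str

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match variant count")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < 0).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def index_of(self, snp: str) -> int:
        return self._index[snp]

    def pairwise_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def position_of(self, snp: str) -> int:
        return int(self.positions[self._index[snp]])


class LDPanel:
    """A collection of per-chromosome LD references.

    Variants on different chromosomes are unlinked (r² = 0); a lookup
    for a variant missing from its own chromosome's reference raises
    ``MissingLDError`` so silent mis-clumping cannot occur.
    """

    def __init__(self, references: Mapping[str, LDReference] | list[LDReference]):
        if isinstance(references, Mapping):
            refs = dict(references)
        else:
            refs = {ref.chromosome: ref for ref in references}
        self.references = refs
        self._chrom_of = {}
        for chrom, ref in refs.items():
            for v in ref.variant_ids:
                self._chrom_of[v] = chrom

    def __contains__(self, snp: str) -> bool:
        return snp in self._chrom_of

    def reference_for(self, chrom: str) -> LDReference | None:
        return self.references.get(chrom)

    def pairwise_r2(self, a: str, chrom_a: str, b: str, chrom_b: str) -> float:
        from .instruments import MissingLDError

        if chrom_a != chrom_b:
            return 0.0
        ref = self.references.get(chrom_a)
        if ref is None or a not in ref or b not in ref:
            raise MissingLDError(
                f"no LD entry for pair ({a}, {b}) on chromosome {chrom_a}"
            )
        return ref.pairwise_r2(a, b)


# ---------------------------------------------------------------------------
# LD reference simulation
# ---------------------------------------------------------------------------

def simulate_ld_reference(
    n_variants: int,
    decay: float = 1e-5,
    chromosome: str = "1",
    start: int = 1_000_000,
    spacing: int = 10_000,
    seed: int = 0,
) -> LDReference:
    """Exponential-decay LD reference on an evenly spaced variant grid.

    The pairwise correlation is ``r = exp(-decay * distance)`` and the
    stored squared correlation is its square, so ``decay = 0`` gives
    complete LD and large ``decay`` gives independence.  Deterministic:
    the seed only names the variant ids.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if decay < 0:
        raise ValueError("decay must be >= 0")
    positions = start + spacing * np.arange(n_variants, dtype=np.int64)
    dist = np.abs(positions[:, None] - positions[None, :]).astype(float)
    r = np.exp(-decay * dist)
    ids = [f"rs{chromosome}_{seed}_{i}" for i in range(n_variants)]
    return LDReference(variant_ids=ids, r2=r**2, positions=positions,
                       chromosome=str(chromosome))


def ld_correlation(ld: LDReference) -> np.ndarray:
    """Signed correlation matrix implied by the exponential kernel.

    The generator's kernel is positive, so ``r = sqrt(r2)`` recovers it
    exactly; used when propagating causal effects to marginal ones.
    """
    return np.sqrt(ld.r2)


# ---------------------------------------------------------------------------
# Protein (exposure) GWAS
# ---------------------------------------------------------------------------

def _draw_alleles(rng: np.random.Generator, n: int, palindromic_rate: float,
                  protect: np.ndarray | None = None):
    """Effect/other allele codes; ``protect`` marks indices kept non-palindromic."""
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal = rng.random(n) < palindromic_rate
    if protect is not None:
        pal &= ~protect
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _ALLELE_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(np.asarray(beta) / np.asarray(se))
    p = 2 * stats.norm.sf(z)
    # p of exactly 0 underflows only for |z| > 38; clip into (0, 1]
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_protein_gwas(truth: TruthConfig, ld: LDReference | None = None
                          ) -> list[SimulatedStudy]:
    """Simulate one exposure GWAS per protein.

    Each protein gets ``n_variants_per_protein`` candidate pQTLs whose
    true per-allele effects are sized so that each variant explains the
    configured ``instrument_r2`` of the standardized protein level.
    When an LD reference is supplied its variants are partitioned into
    consecutive per-protein blocks and reused as variant identities;
    otherwise each protein receives its own synthetic block.
    """
    studies = []
    r2_lo, r2_hi = truth.r2_bounds()
    m = truth.n_variants_per_protein
    for k in range(truth.n_proteins):
        protein = f"prot_{k:04d}"
        rng = np.random.default_rng(_derive_seed(truth.seed, "exposure", protein))
        if ld is not None:
            lo = k * m
            if lo + m > len(ld.variant_ids):
                raise ValueError("LD reference too small for requested proteins")
            snps = ld.variant_ids[lo:lo + m]
            chrom = ld.chromosome
            pos = ld.positions[lo:lo + m]
        else:
            snps = [f"rs{k}_{j}" for j in range(m)]
            chrom = str(100 + k)
            pos = 1_000_000 + 10_000 * np.arange(m, dtype=np.int64)
        maf = rng.uniform(*truth.maf_range, size=m)
        r2 = rng.uniform(r2_lo, r2_hi, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        denom = 2 * maf * (1 - maf)
        true_beta = sign * np.sqrt(r2 / denom)
        se = 1.0 / np.sqrt(denom * truth.n_exposure)
        beta = true_beta + se * rng.standard_normal(m)
        ea, oa = _draw_alleles(rng, m, truth.palindromic_rate)
        table = pd.DataFrame({
            "snp": snps, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
            "eaf": maf, "beta": beta, "se": se,
            "pval": _two_sided_p(beta, se),
            "n": truth.n_exposure,
        })[SUMSTATS_COLUMNS]
        studies.append(SimulatedStudy(trait_id=protein, table=table,
                                      truth=truth, true_beta=true_beta))
    return studies


def simulate_downstream_gwas(truth: TruthConfig, exposure_study: SimulatedStudy,
                             trait_id: str) -> SimulatedStudy:
    """Simulate a downstream (outcome or risk-factor) GWAS at the
    exposure's instruments under the two-sample design.

    The outcome effect at instrument *j* is
    ``theta * true_beta_j + alpha_j + e_j`` with independent sampling
    noise ``e_j ~ N(0, se_out^2)``, ``se_out = 1 / sqrt(n_outcome)`` for
    a standardized outcome.  The pleiotropy term ``alpha_j`` is oriented
    with the exposure-increasing allele (``alpha * sign(true_beta_j)``),
    which is the orientation under which a constant ``alpha`` is
    directional pleiotropy recoverable by the MR-Egger intercept.  A
    non-zero ``sample_overlap`` correlates the outcome noise with the
    realized exposure noise.
    """
    protein = exposure_study.trait_id
    trait_map = truth.theta.get(protein, {})
    if trait_id not in trait_map:
        raise ValueError(f"no true effect configured for {protein} -> {trait_id}")
    theta = trait_map[trait_id]
    if exposure_study.true_beta is None:
        raise ValueError("exposure study lacks true effects; "
                         "generate it with simulate_protein_gwas")
    rng = np.random.default_rng(_derive_seed(truth.seed, "outcome", protein, trait_id))
    tab = exposure_study.table
    m = len(tab)
    se_out = np.full(m, 1.0 / np.sqrt(truth.n_outcome))
    z_ind = rng.standard_normal(m)
    if truth.sample_overlap > 0:
        z_exp = (tab["beta"].to_numpy() - exposure_study.true_beta) / tab["se"].to_numpy()
        rho = truth.sample_overlap
        noise = rho * z_exp + np.sqrt(1 - rho**2) * z_ind
    else:
        noise = z_ind
    orient = np.where(exposure_study.true_beta >= 0, 1.0, -1.0)
    true_by = theta * exposure_study.true_beta + truth.alpha * orient
    beta = true_by + se_out * noise
    table = tab.copy()
    table["beta"] = beta
    table["se"] = se_out
    table["pval"] = _two_sided_p(beta, se_out)
    table["n"] = truth.n_outcome
    return SimulatedStudy(trait_id=trait_id, table=table, truth=truth,
                          true_beta=true_by)


# ---------------------------------------------------------------------------
# Colocalization regions
# ---------------------------------------------------------------------------

COLOC_SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


def _ld_noise_factor(corr: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of an LD correlation matrix for drawing
    LD-correlated sampling noise (z-scores of marginal associations
    covary as the LD correlation).  Jittered for rank deficiency."""
    m = corr.shape[0]
    try:
        return np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, 0, None)
        return vecs * np.sqrt(vals)


def simulate_coloc_region(
    scenario: str,
    ld: LDReference,
    n1: int = 20_000,
    n2: int = 20_000,
    effect_sd: float = 0.09,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Paired regional association tables under one coloc hypothesis.

    H4 places a single shared causal variant at the region's centre; H3
    places two distinct causal variants as far apart (lowest r²) as the
    region allows; H1/H2 give only one trait a signal; H0 is pure
    noise.  Causal effects (``effect_sd``, SD units of a standardized
    trait) propagate to marginal per-allele effects through the signed
    LD correlation: ``beta_marginal = r_vec * beta_causal``.
    """
    if scenario not in COLOC_SCENARIOS:
        raise ValueError(f"scenario must be one of {COLOC_SCENARIOS}")
    m = len(ld.variant_ids)
    if scenario == "H3" and m < 2:
        raise ValueError("H3 requires at least 2 variants")
    rng = np.random.default_rng(_derive_seed(seed, "coloc", scenario))
    maf = rng.uniform(*maf_range, size=m)
    corr = ld_correlation(ld)
    chol = _ld_noise_factor(corr)
    denom = 2 * maf * (1 - maf)
    # standardized-genotype causal effect; convert marginals to per-allele scale
    causal1 = np.zeros(m)
    causal2 = np.zeros(m)
    centre = m // 2
    if scenario in ("H1", "H4"):
        causal1[centre] = effect_sd
    if scenario in ("H2", "H4"):
        causal2[centre] = effect_sd
    if scenario == "H3":
        causal1[m // 4] = effect_sd
        causal2[(3 * m) // 4] = effect_sd

    def _table(causal, n, tag):
        marginal_std = corr @ causal
        beta_true = marginal_std / np.sqrt(denom)
        se = 1.0 / np.sqrt(denom * n)
        beta = beta_true + se * (chol @ rng.standard_normal(m))
        ea, oa = _draw_alleles(rng, m, palindromic_rate=0.0)
        return pd.DataFrame({
            "snp": ld.variant_ids, "chr": ld.chromosome, "pos": ld.positions,
            "ea": ea, "oa": oa, "eaf": maf, "beta": beta, "se": se,
            "pval": _two_sided_p(beta, se), "n": n,
        })[SUMSTATS_COLUMNS]

    return _table(causal1, n1, "t1"), _table(causal2, n2, "t2"), scenario


# ---------------------------------------------------------------------------
# End-to-end screening scenario
# ---------------------------------------------------------------------------

@dataclass
class ScreenStudy:
    """A full synthetic screening data set with per-protein truth labels.

    ``protein_tables`` maps protein id to its regional exposure GWAS;
    ``outcome_table`` is one outcome GWAS covering all regions;
    ``panel`` holds per-region LD; ``labels`` maps protein id to
    ``"null"``, ``"causal"`` (shared causal variant with the outcome)
    or ``"confounded"`` (outcome driven by a distinct variant in LD
    with the pQTL); ``pqtl`` maps protein id to its lead variant.
    """

    protein_tables: dict[str, pd.DataFrame]
    outcome_table: pd.DataFrame
    outcome_id: str
    panel: LDPanel
    labels: dict[str, str]
    pqtl: dict[str, str]
    theta: dict[str, float]


def simulate_screen_study(
    n_null: int = 20,
    n_causal: int = 3,
    n_confounded: int = 2,
    n_variants_per_region: int = 40,
    n_exposure: int = 10_000,
    n_outcome: int = 30_000,
    instrument_r2: float = 0.02,
    theta: float = 0.4,
    confound_r2: float = 0.4,
    decay: float = 2e-5,
    spacing: int = 5_000,
    outcome_id: str = "vat_volume",
    seed: int = 0,
) -> ScreenStudy:
    """Multi-protein screening scenario with nulls, true causal proteins
    and LD-confounded proteins.

    Each protein occupies its own LD region (one synthetic chromosome
    per protein) with the pQTL at the centre.  For a causal protein the
    outcome shares that causal variant with effect ``theta`` (SD per
    SD); for a confounded protein the outcome's causal variant is a
    different variant whose r² with the pQTL is closest to
    ``confound_r2`` — strong enough for MR to flag the protein, while
    colocalization resolves the two signals as distinct.
    """
    rng = np.random.default_rng(_derive_seed(seed, "screen"))
    labels = (["null"] * n_null + ["causal"] * n_causal
              + ["confounded"] * n_confounded)
    rng.shuffle(labels)
    protein_tables, refs, label_map, pqtl_map, theta_map = {}, {}, {}, {}, {}
    outcome_parts = []
    m = n_variants_per_region
    centre = m // 2
    for k, label in enumerate(labels):
        protein = f"prot_{k:04d}"
        chrom = str(101 + k)
        ld = simulate_ld_reference(m, decay=decay, chromosome=chrom,
                                   start=1_000_000, spacing=spacing, seed=seed)
        corr = ld_correlation(ld)
        chol = _ld_noise_factor(corr)
        maf = rng.uniform(0.1, 0.5, size=m)
        denom = 2 * maf * (1 - maf)
        b_causal_std = np.sqrt(instrument_r2)  # standardized-genotype scale
        exp_causal = np.zeros(m)
        exp_causal[centre] = b_causal_std
        exp_true = (corr @ exp_causal) / np.sqrt(denom)
        se_exp = 1.0 / np.sqrt(denom * n_exposure)
        beta_exp = exp_true + se_exp * (chol @ rng.standard_normal(m))
        protect = np.zeros(m, dtype=bool)
        protect[centre] = True
        ea, oa = _draw_alleles(rng, m, palindromic_rate=0.05, protect=protect)
        prot_tab = pd.DataFrame({
            "snp": ld.variant_ids, "chr": chrom, "pos": ld.positions,
            "ea": ea, "oa": oa, "eaf": maf, "beta": beta_exp, "se": se_exp,
            "pval": _two_sided_p(beta_exp, se_exp), "n": n_exposure,
        })[SUMSTATS_COLUMNS]

        out_causal = np.zeros(m)
        th = 0.0
        if label == "causal":
            th = theta
            out_causal[centre] = th * b_causal_std
        elif label == "confounded":
            r2_to_centre = ld.r2[centre].copy()
            r2_to_centre[centre] = np.inf  # exclude the pQTL itself
            j = int(np.argmin(np.abs(r2_to_centre - confound_r2)))
            # size the distinct signal so the apparent MR effect is ~theta
            r_cj = corr[centre, j]
            out_causal[j] = theta * b_causal_std / r_cj
        out_true = (corr @ out_causal) / np.sqrt(denom)
        se_out = 1.0 / np.sqrt(denom * n_outcome)
        beta_out = out_true + se_out * (chol @ rng.standard_normal(m))
        out_tab = prot_tab.copy()
        out_tab["beta"] = beta_out
        out_tab["se"] = se_out
        out_tab["pval"] = _two_sided_p(beta_out, se_out)
        out_tab["n"] = n_outcome

        protein_tables[protein] = prot_tab
        refs[chrom] = ld
        label_map[protein] = label
        pqtl_map[protein] = ld.variant_ids[centre]
        theta_map[protein] = th
        outcome_parts.append(out_tab)

    return ScreenStudy(
        protein_tables=protein_tables,
        outcome_table=pd.concat(outcome_parts, ignore_index=True),
        outcome_id=outcome_id,
        panel=LDPanel(refs),
        labels=label_map,
        pqtl=pqtl_map,
        theta=theta_map,
    )


def identity_ld_panel(tables: "list[pd.DataFrame]") -> LDPanel:
    """LD panel declaring every variant independent of every other.

    Convenience for instrument sets that were generated without LD
    structure; one identity reference per chromosome found in the
    supplied summary tables.
    """
    refs = {}
    merged = pd.concat(tables, ignore_index=True)[["snp", "chr", "pos"]]
    merged = merged.drop_duplicates("snp")
    for chrom, grp in merged.groupby("chr"):
        grp = grp.sort_values("pos")
        m = len(grp)
        refs[str(chrom)] = LDReference(
            variant_ids=list(grp["snp"]), r2=np.eye(m),
            positions=grp["pos"].to_numpy(), chromosome=str(chrom))
    return LDPanel(refs)


# ---------------------------------------------------------------------------
# Mediation chain
# ---------------------------------------------------------------------------

@dataclass
class MediationChainStudy:
    """Summary tables for a protein -> mediator -> outcome causal chain.

    The protein and the mediator have disjoint instrument sets;
    ``mediator_table`` and ``outcome_table`` cover both sets so that the
    primary MR (protein -> outcome), Step-1 (mediator -> outcome) and
    Step-2 (protein -> mediator) analyses can all be run from the same
    simulated world.  True effects: ``theta1`` (protein -> mediator),
    ``theta2`` (mediator -> outcome), ``direct`` (protein -> outcome not
    through the mediator); the true total protein effect is
    ``theta1 * theta2 + direct``.
    """

    protein_table: pd.DataFrame
    mediator_own_table: pd.DataFrame
    mediator_table: pd.DataFrame
    outcome_table: pd.DataFrame
    protein_snps: list[str]
    mediator_snps: list[str]
    theta1: float
    theta2: float
    direct: float

    @property
    def true_total(self) -> float:
        return self.theta1 * self.theta2 + self.direct

    @property
    def true_proportion(self) -> float:
        return self.theta1 * self.theta2 / self.true_total


def simulate_mediation_chain(
    theta1: float = 0.4,
    theta2: float = 0.3,
    direct: float = 0.1,
    n_instruments: int = 10,
    n_exposure: int = 50_000,
    n_mediator: int = 50_000,
    n_outcome: int = 50_000,
    instrument_r2: float = 0.01,
    seed: int = 0,
) -> MediationChainStudy:
    """Simulate the three GWAS needed for a two-step mediation analysis."""
    rng = np.random.default_rng(_derive_seed(seed, "chain"))

    def _instruments(tag, chrom, n_trait):
        snps = [f"rs_{tag}_{j}" for j in range(n_instruments)]
        maf = rng.uniform(0.1, 0.5, size=n_instruments)
        denom = 2 * maf * (1 - maf)
        true_beta = rng.choice([-1.0, 1.0], n_instruments) * np.sqrt(instrument_r2 / denom)
        se = 1.0 / np.sqrt(denom * n_trait)
        beta = true_beta + se * rng.standard_normal(n_instruments)
        ea, oa = _draw_alleles(rng, n_instruments, palindromic_rate=0.0)
        tab = pd.DataFrame({
            "snp": snps, "chr": chrom,
            "pos": 1_000_000 + 10_000 * np.arange(n_instruments, dtype=np.int64),
            "ea": ea, "oa": oa, "eaf": maf, "beta": beta, "se": se,
            "pval": _two_sided_p(beta, se), "n": n_trait,
        })[SUMSTATS_COLUMNS]
        return snps, maf, true_beta, tab

    p_snps, p_maf, p_true, protein_tab = _instruments("p", "201", n_exposure)
    m_snps, m_maf, m_true, mediator_own_tab = _instruments("m", "202", n_mediator)

    def _downstream(snps, maf, true_effects, n_trait, base_tabs):
        parts = []
        for tab, true_b in zip(base_tabs, true_effects):
            t = tab.copy()
            denom = 2 * t["eaf"].to_numpy() * (1 - t["eaf"].to_numpy())
            se = 1.0 / np.sqrt(denom * n_trait)
            beta = true_b + se * rng.standard_normal(len(t))
            t["beta"], t["se"] = beta, se
            t["pval"] = _two_sided_p(beta, se)
            t["n"] = n_trait
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    # mediator GWAS: protein instruments act via theta1; own instruments direct
    mediator_tab = _downstream(
        None, None, [theta1 * p_true, m_true], n_mediator,
        [protein_tab, mediator_own_tab])
    # outcome GWAS: protein instruments act via total effect; mediator's via theta2
    total = theta1 * theta2 + direct
    outcome_tab = _downstream(
        None, None, [total * p_true, theta2 * m_true], n_outcome,
        [protein_tab, mediator_own_tab])

    return MediationChainStudy(
        protein_table=protein_tab,
        mediator_own_table=mediator_own_tab,
        mediator_table=mediator_tab,
        outcome_table=outcome_tab,
        protein_snps=p_snps,
        mediator_snps=m_snps,
        theta1=theta1, theta2=theta2, direct=direct,
    )
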