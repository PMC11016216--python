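"""Bayesian colocalization of a pQTL region with an outcome region.

Given per-variant summary associations for two traits over a shared
set of regional variants, computes approximate Bayes factors for each
variant (Wakefield's quantitative-trait ABF) and combines them into
posterior probabilities of the five colocalization hypotheses:

    H0 - no association with either trait in the region
    H1 - association with trait 1 only
    H2 - association with trait 2 only
    H3 - both traits associated, distinct causal variants
    H4 - both traits associated, one shared causal variant

Each hypothesis assumes at most one causal variant per trait.  A
region is called colocalized when PPH4 exceeds 0.8, and suggestive
when it exceeds 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class RegionalSummary:
    """Per-variant associations of one trait across a regional window."""

    trait_id: str
    variants: list[str]
    beta: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    n: int
    sd_trait: float = 1.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if not (len(self.variants) == len(self.beta) == len(self.se)
                == len(self.maf)):
            raise ValueError("regional arrays must share one length")
        if (self.se <= 0).any():
            raise ValueError("regional standard errors must be > 0")
        if ((self.maf <= 0) | (self.maf > 0.5)).any():
            raise ValueError("regional MAF must lie in (0, 0.5]")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class ColocPriors:
    """Per-variant prior probabilities of association.

    ``p1``/``p2``: a variant is causal for trait 1/2 alone; ``p12``:
    causal for both.  Defaults are the conventional single-variant
    colocalization priors.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum to < 1")


@dataclass
class ColocPosteriors:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_variants: int
    call: str = ""
    notes: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


class EmptyRegionError(ValueError):
    """No variants survive the regional intersection and MAF filter."""


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_region(
    pqtl_snp: str,
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    trait1_id: str = "trait1",
    trait2_id: str = "trait2",
    window: int = 1_000_000,
    maf_min: float = 0.01,
) -> tuple[RegionalSummary, RegionalSummary]:
    """Paired regional summaries around a pQTL.

    Keeps variants present in both tables, on the pQTL's chromosome
    within +/- ``window`` bp of its position, with minor-allele
    frequency strictly above ``maf_min`` in both studies; position
    order is preserved.
    """
    hit = table1.loc[table1["snp"] == pqtl_snp]
    if hit.empty:
        raise ValueError(f"pQTL {pqtl_snp} absent from trait-1 table")
    chrom = str(hit["chr"].iloc[0])
    pos = int(hit["pos"].iloc[0])

    def _windowed(tab):
        t = tab.loc[(tab["chr"].astype(str) == chrom)
                    & (tab["pos"] >= pos - window)
                    & (tab["pos"] <= pos + window)].copy()
        t["maf"] = np.minimum(t["eaf"], 1 - t["eaf"])
        return t.loc[t["maf"] > maf_min].set_index("snp")

    t1 = _windowed(table1)
    t2 = _windowed(table2)
    shared = [s for s in t1.sort_values("pos").index if s in t2.index]
    if not shared:
        raise EmptyRegionError(
            f"no shared variants around {pqtl_snp} (window {window}, "
            f"maf > {maf_min})")
    t1 = t1.loc[shared]
    t2 = t2.loc[shared]

    def _summary(t, trait_id):
        return RegionalSummary(
            trait_id=trait_id, variants=list(t.index),
            beta=t["beta"].to_numpy(), se=t["se"].to_numpy(),
            maf=t["maf"].to_numpy(), n=int(t["n"].iloc[0]),
        )

    return _summary(t1, trait1_id), _summary(t2, trait2_id)


# ---------------------------------------------------------------------------
# Approximate Bayes factors and posteriors
# ---------------------------------------------------------------------------

def log_abf(beta, se, prior_sd: float = 0.15):
    """Log approximate Bayes factor for a single-variant quantitative
    association: with V = se², W = prior_sd², z = beta/se and
    r = W/(V+W), ``log ABF = 0.5 * (log(1 - r) + r z²)``."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def coloc_posteriors(
    region1: RegionalSummary,
    region2: RegionalSummary,
    priors: ColocPriors | None = None,
    prior_sd_scale: float = 0.15,
) -> ColocPosteriors:
    """Posterior probabilities of H0-H4 from per-variant log-ABFs.

    Hypothesis evidence is accumulated in log space: H1/H2 sum the
    single-trait ABFs, H4 sums the products at the same variant, and
    H3 sums products at distinct variants — computed stably as the
    complement of the H4 sum within the full cross product, with a
    direct double sum for small regions where cancellation could bite.
    """
    priors = priors or ColocPriors()
    if region1.variants != region2.variants:
        raise ValueError("regions must share an identical variant list")
    m = region1.n_variants
    l1 = log_abf(region1.beta, region1.se, prior_sd_scale * region1.sd_trait)
    l2 = log_abf(region2.beta, region2.se, prior_sd_scale * region2.sd_trait)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    notes = []
    s0 = 0.0
    s1 = np.log(priors.p1) + lse1
    s2 = np.log(priors.p2) + lse2
    s4 = np.log(priors.p12) + lse12
    if m == 1:
        s3 = -np.inf  # two distinct variants are impossible
        notes.append("single-variant region: PPH3 set to 0")
    elif m <= 64:
        # direct double sum over distinct pairs; no cancellation
        cross = l1[:, None] + l2[None, :]
        np.fill_diagonal(cross, -np.inf)
        s3 = np.log(priors.p1) + np.log(priors.p2) + logsumexp(cross)
    else:
        # log(exp(lse1 + lse2) - exp(lse12)) via the stable complement
        diff = lse12 - (lse1 + lse2)
        comp = np.log1p(-np.exp(min(diff, -1e-300))) if diff < 0 else -np.inf
        if not np.isfinite(comp):
            notes.append("H3 complement underflow: PPH3 set to 0")
            s3 = -np.inf
        else:
            s3 = np.log(priors.p1) + np.log(priors.p2) + lse1 + lse2 + comp

    s = np.array([s0, s1, s2, s3, s4])
    post = np.exp(s - logsumexp(s))
    post /= post.sum()
    result = ColocPosteriors(
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]), n_variants=m, notes=notes,
    )
    result.call = call_colocalization(result)
    return result


def call_colocalization(post: ColocPosteriors, strong: float = 0.8,
                        suggestive: float = 0.6) -> str:
    """Evidence tier from PPH4: > ``strong`` is colocalized, between
    ``suggestive`` and ``strong`` is suggestive, else not colocalized."""
    if post.pph4 > strong:
        return "colocalized"
    if post.pph4 > suggestive:
        return "suggestive"
    return "not_colocalized"


def region_from_table(table: pd.DataFrame, trait_id: str) -> RegionalSummary:
    """Build a regional summary directly from a summary-statistics table
    (all variants, no windowing) — convenience for simulated regions."""
    maf = np.minimum(table["eaf"].to_numpy(), 1 - table["eaf"].to_numpy())
    return RegionalSummary(
        trait_id=trait_id, variants=list(table["snp"]),
        beta=table["beta"].to_numpy(), se=table["se"].to_numpy(),
        maf=maf, n=int(table["n"].iloc[0]),
    )
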