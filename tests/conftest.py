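import numpy as np
import pandas as pd
import pytest

from pqtlmr import (
    HarmonizedDataset,
    SimulatedStudy,
    TruthConfig,
    simulate_downstream_gwas,
    simulate_protein_gwas,
)


def make_harmonized(bx, by, bxse=None, byse=None, exposure="exp", outcome="out"):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    bxse = np.full_like(bx, 0.01) if bxse is None else np.asarray(bxse, float)
    byse = np.full_like(by, 0.1) if byse is None else np.asarray(byse, float)
    snps = [f"rs{i}" for i in range(len(bx))]
    return HarmonizedDataset(exposure_id=exposure, outcome_id=outcome,
                             snp=snps, bx=bx, bxse=bxse, by=by, byse=byse)


def harmonized_from_truth(seed, theta=0.3, alpha=0.0, n_variants=10,
                          n_exposure=10_000, n_outcome=30_000,
                          instrument_r2=0.02) -> HarmonizedDataset:
    """Exposure/outcome pairs straight from the generator (alleles are
    already aligned by construction, so harmonization is a passthrough)."""
    truth = TruthConfig(
        n_proteins=1, n_variants_per_protein=n_variants,
        n_exposure=n_exposure, n_outcome=n_outcome,
        theta={"prot_0000": {"o": theta}}, alpha=alpha,
        instrument_r2=instrument_r2, palindromic_rate=0.0, seed=seed)
    exp = simulate_protein_gwas(truth)[0]
    out = simulate_downstream_gwas(truth, exp, "o")
    return HarmonizedDataset(
        exposure_id="prot_0000", outcome_id="o", snp=list(exp.table["snp"]),
        bx=exp.table["beta"].to_numpy(), bxse=exp.table["se"].to_numpy(),
        by=out.table["beta"].to_numpy(), byse=out.table["se"].to_numpy())


def make_table(snps, chrom="1", pos=None, ea="A", oa="G", eaf=0.3,
               beta=0.1, se=0.01, pval=None, n=10_000) -> pd.DataFrame:
    """Small summary-statistics table with broadcastable columns."""
    m = len(snps)

    def col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * m

    beta_l, se_l = col(beta), col(se)
    if pval is None:
        from scipy import stats
        pval = [float(2 * stats.norm.sf(abs(b / s))) or 1e-300
                for b, s in zip(beta_l, se_l)]
    return pd.DataFrame({
        "snp": list(snps), "chr": col(chrom),
        "pos": col(pos if pos is not None else
                   [1_000_000 + 10_000 * i for i in range(m)]),
        "ea": col(ea), "oa": col(oa), "eaf": col(eaf),
        "beta": beta_l, "se": se_l,
        "pval": [min(max(p, 1e-300), 1.0) for p in col(pval)],
        "n": col(n),
    })


@pytest.fixture
def proportional_data():
    """Every per-SNP ratio equals 0.5 exactly."""
    bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
    return make_harmonized(bx, 0.5 * bx, byse=np.full(5, 0.05))
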