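"""Orchestration of the four-step proteome-wide screening design.

Step 1: primary MR screen of every protein against every outcome, with
Bonferroni control at ``alpha / n_protein_tests`` (the number of
distinct proteins tested).  Step 2: colocalization verification of the
flagged protein-outcome pairs; only pairs with PPH4 > 0.8 earn the
"prioritized" label.  Step 3: two-step MR — risk factors against
outcomes (Step-1, Bonferroni at ``alpha / n_risk_factor_tests``) and
proteins against the flagged risk factors (Step-2, protein-family
threshold).  Step 4: mediation decomposition for every
protein/mediator/outcome triple that passes all three screens.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .estimators import mr_auto
from .instruments import (
    SelectionParams,
    associations_from_table,
    cross_protein_counts,
    harmonize,
    select_instruments,
)
from .mediation import MediationInput, mediate
from .simulate import LDPanel, LDReference

RESULT_COLUMNS = [
    "exposure", "outcome", "method", "primary", "nsnp", "beta", "se",
    "ci_low", "ci_high", "pval", "q", "q_df", "q_pval",
    "egger_intercept", "egger_intercept_p", "pqtl", "threshold",
    "significant", "note",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m`` for ``m`` tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass
class ScreenConfig:
    """Settings shared by every stage of the screen."""

    alpha: float = 0.05
    n_protein_tests: int | None = None   # default: number of proteins supplied
    n_risk_factor_tests: int | None = None
    selection: SelectionParams = field(default_factory=SelectionParams)
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 200
    coloc_priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    coloc_strong: float = 0.8
    coloc_suggestive: float = 0.6
    coloc_window: int = 1_000_000
    coloc_maf_min: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_protein_tests": self.n_protein_tests,
            "n_risk_factor_tests": self.n_risk_factor_tests,
            "selection": vars(self.selection),
            "ivw_mode": self.ivw_mode,
            "n_boot": self.n_boot,
            "coloc_priors": vars(self.coloc_priors),
            "coloc_strong": self.coloc_strong,
            "coloc_suggestive": self.coloc_suggestive,
            "coloc_window": self.coloc_window,
            "coloc_maf_min": self.coloc_maf_min,
            "seed": self.seed,
        }


@dataclass
class ScreenReport:
    """All tables produced by one pipeline run, plus its manifest."""

    primary: pd.DataFrame
    coloc: pd.DataFrame | None = None
    step1: pd.DataFrame | None = None
    step2: pd.DataFrame | None = None
    mediation: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MR screening
# ---------------------------------------------------------------------------

def _mr_rows(exposure_id, outcome_id, result, pqtl, threshold):
    rows = []
    q = result.q
    for name, est in result.estimates.items():
        is_primary = est is result.primary
        rows.append({
            "exposure": exposure_id, "outcome": outcome_id, "method": name,
            "primary": is_primary, "nsnp": est.nsnp, "beta": est.beta,
            "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval,
            "q": q.q if (q and is_primary) else np.nan,
            "q_df": q.df if (q and is_primary) else np.nan,
            "q_pval": q.pval if (q and is_primary) else np.nan,
            "egger_intercept": est.extra.get("intercept", np.nan),
            "egger_intercept_p": est.extra.get("intercept_p", np.nan),
            "pqtl": pqtl, "threshold": threshold,
            "significant": bool(is_primary and est.pval < threshold),
            "note": "",
        })
    return rows


def _untestable_row(exposure_id, outcome_id, threshold, note):
    return {
        "exposure": exposure_id, "outcome": outcome_id, "method": "untestable",
        "primary": True, "nsnp": 0, "beta": np.nan, "se": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "pval": np.nan,
        "q": np.nan, "q_df": np.nan, "q_pval": np.nan,
        "egger_intercept": np.nan, "egger_intercept_p": np.nan,
        "pqtl": "", "threshold": threshold, "significant": False,
        "note": note,
    }


def _screen(exposure_tables: Mapping[str, pd.DataFrame],
            outcome_tables: Mapping[str, pd.DataFrame],
            ld: LDPanel | LDReference,
            config: ScreenConfig,
            counts: Mapping[str, int],
            threshold: float) -> pd.DataFrame:
    rows = []
    for exposure_id in sorted(exposure_tables):
        assocs = associations_from_table(exposure_tables[exposure_id])
        iset = select_instruments(assocs, counts, ld, config.selection,
                                  exposure_id=exposure_id)
        if iset.nsnp == 0:
            for outcome_id in sorted(outcome_tables):
                rows.append(_untestable_row(
                    exposure_id, outcome_id, threshold,
                    "no instruments survived selection"))
            continue
        lead = min(iset.instruments, key=lambda a: (a.pval, a.snp)).snp
        for outcome_id in sorted(outcome_tables):
            data = harmonize(iset, outcome_tables[outcome_id],
                             outcome_id=outcome_id, ld=ld,
                             params=config.selection)
            if data.nsnp == 0:
                rows.append(_untestable_row(
                    exposure_id, outcome_id, threshold,
                    "no instruments survived harmonization"))
                continue
            result = mr_auto(data, ivw_mode=config.ivw_mode,
                             n_boot=config.n_boot, seed=config.seed)
            rows.extend(_mr_rows(exposure_id, outcome_id, result, lead,
                                 threshold))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    flagged = df.loc[df["significant"]]
    assert (flagged["pval"] < flagged["threshold"]).all()
    return df


def run_primary_screen(protein_tables: Mapping[str, pd.DataFrame],
                       outcome_tables: Mapping[str, pd.DataFrame],
                       ld: LDPanel | LDReference,
                       config: ScreenConfig | None = None) -> pd.DataFrame:
    """Proteome-wide MR of every protein against every outcome.

    Instruments are selected per protein (with pleiotropy counts pooled
    across all supplied protein GWAS), harmonized against each outcome,
    and estimated with :func:`~pqtlmr.estimators.mr_auto`; the primary
    estimate is flagged at ``alpha / n_protein_tests``.
    """
    config = config or ScreenConfig()
    if not protein_tables:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    m = config.n_protein_tests or len(protein_tables)
    threshold = bonferroni_threshold(config.alpha, m)
    counts = cross_protein_counts(protein_tables, config.selection.p_threshold)
    return _screen(protein_tables, outcome_tables, ld, config, counts, threshold)


def run_two_step_screen(protein_tables: Mapping[str, pd.DataFrame],
                        risk_factor_tables: Mapping[str, pd.DataFrame],
                        outcome_tables: Mapping[str, pd.DataFrame],
                        ld: LDPanel | LDReference,
                        config: ScreenConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step MR: risk factors -> outcomes (Step-1, risk-factor
    Bonferroni family), then proteins -> the Step-1-flagged risk
    factors (Step-2, protein family threshold)."""
    config = config or ScreenConfig()
    m_rf = config.n_risk_factor_tests or max(len(risk_factor_tables), 1)
    rf_threshold = bonferroni_threshold(config.alpha, m_rf)
    step1 = _screen(risk_factor_tables, outcome_tables, ld, config,
                    {}, rf_threshold)
    flagged_rf = sorted(step1.loc[step1["significant"], "exposure"].unique())
    if not flagged_rf:
        return step1, pd.DataFrame(columns=RESULT_COLUMNS)
    m_prot = config.n_protein_tests or len(protein_tables)
    prot_threshold = bonferroni_threshold(config.alpha, m_prot)
    counts = cross_protein_counts(protein_tables, config.selection.p_threshold)
    mediator_tables = {rf: risk_factor_tables[rf] for rf in flagged_rf}
    step2 = _screen(protein_tables, mediator_tables, ld, config, counts,
                    prot_threshold)
    return step1, step2


# ---------------------------------------------------------------------------
# Mediation candidates
# ---------------------------------------------------------------------------

def _primary_hits(df: pd.DataFrame) -> pd.DataFrame:
    return df.loc[df["primary"] & df["significant"]]


def select_mediation_candidates(primary: pd.DataFrame,
                                step1: pd.DataFrame,
                                step2: pd.DataFrame) -> list[MediationInput]:
    """Triples passing all three screens.

    A (protein, mediator, outcome) candidate requires: the protein
    passes the primary screen for the outcome; the mediator passes
    Step-1 for that outcome; the protein passes Step-2 for that
    mediator.  beta1 = Step-2 effect, beta2 = Step-1 effect, beta3 =
    primary (total) effect.
    """
    out = []
    p_hits = _primary_hits(primary)
    s1_hits = _primary_hits(step1)
    s2_hits = _primary_hits(step2)
    for p_row in p_hits.itertuples(index=False):
        s1_for_outcome = s1_hits.loc[s1_hits["outcome"] == p_row.outcome]
        for s1_row in s1_for_outcome.itertuples(index=False):
            s2_match = s2_hits.loc[(s2_hits["exposure"] == p_row.exposure)
                                   & (s2_hits["outcome"] == s1_row.exposure)]
            for s2_row in s2_match.itertuples(index=False):
                out.append(MediationInput(
                    exposure_id=p_row.exposure,
                    mediator_id=s1_row.exposure,
                    outcome_id=p_row.outcome,
                    beta1=s2_row.beta, se1=s2_row.se,
                    beta2=s1_row.beta, se2=s1_row.se,
                    beta3=p_row.beta, se3=p_row.se,
                ))
    return out


def run_mediation(candidates: list[MediationInput],
                  reverse_estimates: Mapping[tuple[str, str], object] | None = None,
                  reverse_alpha: float = 4.99e-5) -> pd.DataFrame:
    """Mediation decomposition for every candidate triple.

    ``reverse_estimates`` optionally maps (mediator, protein) to the
    reverse-MR estimate used for the bidirectionality flag.
    """
    rows = []
    for inp in candidates:
        rev = None
        if reverse_estimates:
            rev = reverse_estimates.get((inp.mediator_id, inp.exposure_id))
        res = mediate(inp, reverse_estimate=rev, reverse_alpha=reverse_alpha)
        sign_consistent = np.sign(inp.beta1 * inp.beta2) == np.sign(inp.beta3)
        rows.append({
            "exposure": inp.exposure_id, "mediator": inp.mediator_id,
            "outcome": inp.outcome_id,
            "beta1": inp.beta1, "se1": inp.se1,
            "beta2": inp.beta2, "se2": inp.se2,
            "beta3": inp.beta3, "se3": inp.se3,
            "indirect": res.indirect, "indirect_se": res.indirect_se,
            "indirect_ci_low": res.indirect_ci[0],
            "indirect_ci_high": res.indirect_ci[1],
            "direct": res.direct,
            "proportion_pct": res.proportion_pct,
            "proportion_ci_low": (None if res.proportion_ci is None
                                  else 100 * res.proportion_ci[0]),
            "proportion_ci_high": (None if res.proportion_ci is None
                                   else 100 * res.proportion_ci[1]),
            "sign_consistent": bool(sign_consistent),
            "valid": res.valid,
            "note": "; ".join(res.notes),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Colocalization verification
# ---------------------------------------------------------------------------

def run_coloc_verification(primary: pd.DataFrame,
                           protein_tables: Mapping[str, pd.DataFrame],
                           outcome_tables: Mapping[str, pd.DataFrame],
                           config: ScreenConfig | None = None) -> pd.DataFrame:
    """Colocalize every flagged protein-outcome pair around its pQTL.

    Only pairs whose PPH4 exceeds the strong threshold carry the
    ``prioritized`` label; pairs with an empty regional intersection
    are annotated rather than failed.
    """
    config = config or ScreenConfig()
    rows = []
    for row in _primary_hits(primary).itertuples(index=False):
        base = {"exposure": row.exposure, "outcome": row.outcome,
                "pqtl": row.pqtl}
        try:
            r1, r2 = coloc_mod.extract_region(
                row.pqtl, protein_tables[row.exposure],
                outcome_tables[row.outcome],
                trait1_id=row.exposure, trait2_id=row.outcome,
                window=config.coloc_window, maf_min=config.coloc_maf_min)
        except coloc_mod.EmptyRegionError as exc:
            rows.append({**base, "n_variants": 0, "pph0": np.nan,
                         "pph1": np.nan, "pph2": np.nan, "pph3": np.nan,
                         "pph4": np.nan, "call": "empty_region",
                         "prioritized": False, "note": str(exc)})
            continue
        post = coloc_mod.coloc_posteriors(r1, r2, config.coloc_priors)
        call = coloc_mod.call_colocalization(post, config.coloc_strong,
                                             config.coloc_suggestive)
        rows.append({**base, "n_variants": post.n_variants,
                     "pph0": post.pph0, "pph1": post.pph1, "pph2": post.pph2,
                     "pph3": post.pph3, "pph4": post.pph4, "call": call,
                     "prioritized": call == "colocalized",
                     "note": "; ".join(post.notes)})
    return pd.DataFrame(rows, columns=[
        "exposure", "outcome", "pqtl", "n_variants", "pph0", "pph1", "pph2",
        "pph3", "pph4", "call", "prioritized", "note"])


# ---------------------------------------------------------------------------
# Full pipeline and reporting
# ---------------------------------------------------------------------------

def run_full_screen(protein_tables: Mapping[str, pd.DataFrame],
                    outcome_tables: Mapping[str, pd.DataFrame],
                    ld: LDPanel | LDReference,
                    risk_factor_tables: Mapping[str, pd.DataFrame] | None = None,
                    config: ScreenConfig | None = None) -> ScreenReport:
    """Run every stage and assemble the report with its manifest."""
    config = config or ScreenConfig()
    primary = run_primary_screen(protein_tables, outcome_tables, ld, config)
    coloc_df = run_coloc_verification(primary, protein_tables, outcome_tables,
                                      config)
    step1 = step2 = mediation_df = None
    if risk_factor_tables:
        step1, step2 = run_two_step_screen(protein_tables, risk_factor_tables,
                                           outcome_tables, ld, config)
        candidates = select_mediation_candidates(primary, step1, step2)
        mediation_df = run_mediation(candidates)
    m_prot = config.n_protein_tests or max(len(protein_tables), 1)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_proteins_supplied": len(protein_tables),
        "n_proteins_testable": int(
            primary.loc[primary["primary"], "exposure"]
            .loc[primary["method"] != "untestable"].nunique()
        ) if len(primary) else 0,
        "protein_threshold": bonferroni_threshold(config.alpha, m_prot),
        "risk_factor_threshold": (
            bonferroni_threshold(
                config.alpha,
                config.n_risk_factor_tests or max(len(risk_factor_tables), 1))
            if risk_factor_tables else None),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    return ScreenReport(primary=primary, coloc=coloc_df, step1=step1,
                        step2=step2, mediation=mediation_df,
                        manifest=manifest)


def write_report(report: ScreenReport, out_dir: str | os.PathLike) -> list[str]:
    """Write all result tables (tab-delimited) plus the run manifest.

    Deterministic: the same report writes byte-identical files.
    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    tables = {"primary": report.primary, "coloc": report.coloc,
              "step1": report.step1, "step2": report.step2,
              "mediation": report.mediation}
    for name, df in tables.items():
        if df is None:
            continue
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=True)
    written.append(manifest_path)
    return written
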