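"""Instrument selection, strength filtering, proxy lookup and harmonization.

Candidate pQTLs become MR instruments through a four-rule procedure:
(1) genome-wide significance (p <= 5e-8); (2) exclusion of the MHC
region (chr6:26-34 Mb, GRCh37, 1-based inclusive); (3) greedy LD
clumping at r² < 0.001, preferring the smallest p-value; (4) exclusion
of variants associated with five or more proteins.  Surviving variants
are additionally required to have F-statistic >= 10 (weak-instrument
filter).  Instruments absent from the outcome GWAS may be replaced by a
proxy in high LD (r² > 0.8), and exposure/outcome effects are aligned
to a common effect allele with palindromic (A/T, C/G) and
irreconcilable variants removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import LDPanel, LDReference


class MissingLDError(KeyError):
    """A candidate variant has no LD entry on its own chromosome."""


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    """Reverse-complement of a (possibly multi-base) allele string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError:
        raise ValueError(f"cannot complement allele {allele!r}") from None


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants, whose strand is unresolvable."""
    return ea.upper() == complement_allele(oa)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantAssociation:
    """One variant's summary association with one trait."""

    snp: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp}: se must be > 0")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp}: pval must lie in (0, 1]")
        if not self.effect_allele or not self.other_allele:
            raise ValueError(f"{self.snp}: alleles must be non-empty")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp}: alleles must be distinct")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp}: eaf must lie in (0, 1)")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1 - self.eaf)


def associations_from_table(table: pd.DataFrame) -> list[VariantAssociation]:
    """Convert a summary-statistics DataFrame into association records."""
    return [
        VariantAssociation(
            snp=row.snp, chromosome=str(row.chr), position=int(row.pos),
            effect_allele=row.ea, other_allele=row.oa, eaf=float(row.eaf),
            beta=float(row.beta), se=float(row.se), pval=float(row.pval),
            n=int(row.n),
        )
        for row in table.itertuples(index=False)
    ]


@dataclass
class SelectionParams:
    """Thresholds of the instrument-selection procedure."""

    p_threshold: float = 5e-8
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000
    mhc_end: int = 34_000_000
    clump_r2: float = 0.001
    max_proteins_per_snp: int = 4  # >= 5 proteins -> excluded
    min_f: float = 10.0
    proxy_r2: float = 0.8
    r2_formula: str = "standardized"  # or "z2"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.mhc_start >= self.mhc_end:
            raise ValueError("mhc_start must be < mhc_end")
        if not 0 <= self.clump_r2 < 1:
            raise ValueError("clump_r2 must lie in [0, 1)")
        if not 0 < self.proxy_r2 <= 1:
            raise ValueError("proxy_r2 must lie in (0, 1]")
        if self.r2_formula not in ("standardized", "z2"):
            raise ValueError("r2_formula must be 'standardized' or 'z2'")


@dataclass
class InstrumentSet:
    """Filtered, clumped, strength-validated instruments for one exposure."""

    exposure_id: str
    instruments: list[VariantAssociation]
    r2_explained: list[float]
    f_stat: list[float]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def nsnp(self) -> int:
        return len(self.instruments)


@dataclass
class HarmonizedDataset:
    """Per-variant aligned exposure/outcome effect pairs ready for MR.

    Outcome effects are expressed on the exposure's effect allele;
    palindromic and irreconcilable variants have been removed.
    """

    exposure_id: str
    outcome_id: str
    snp: list[str]
    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)
        self.bxse = np.asarray(self.bxse, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.byse = np.asarray(self.byse, dtype=float)
        if not (len(self.snp) == len(self.bx) == len(self.bxse)
                == len(self.by) == len(self.byse)):
            raise ValueError("harmonized arrays must share one length")
        if (self.bxse <= 0).any() or (self.byse <= 0).any():
            raise ValueError("standard errors must be > 0")

    @property
    def nsnp(self) -> int:
        return len(self.snp)


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

def compute_instrument_strength(assoc: VariantAssociation,
                                formula: str = "standardized"
                                ) -> tuple[float, float]:
    """Variance explained (R²) and F-statistic of one instrument.

    The default is the standardized-trait approximation
    ``R² = 2 * maf * (1 - maf) * beta²``; the alternative ``z2`` form
    ``R² = z² / (z² + n)`` is available for per-allele effects on
    unstandardized traits.  ``F = R² * (n - 2) / (1 - R²)``.
    """
    if assoc.n < 3:
        raise ValueError("sample size must be >= 3 to compute an F-statistic")
    if formula == "standardized":
        r2 = 2 * assoc.maf * (1 - assoc.maf) * assoc.beta**2
    elif formula == "z2":
        z2 = (assoc.beta / assoc.se) ** 2
        r2 = z2 / (z2 + assoc.n)
    else:
        raise ValueError("formula must be 'standardized' or 'z2'")
    r2 = min(r2, 1 - 1e-12)
    f = r2 * (assoc.n - 2) / (1 - r2)
    return float(r2), float(f)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _pair_r2(a: VariantAssociation, b: VariantAssociation,
             ld: LDReference | LDPanel) -> float:
    if isinstance(ld, LDPanel):
        return ld.pairwise_r2(a.snp, a.chromosome, b.snp, b.chromosome)
    if a.chromosome != b.chromosome:
        return 0.0
    if a.snp not in ld or b.snp not in ld:
        raise MissingLDError(f"no LD entry for pair ({a.snp}, {b.snp})")
    return ld.pairwise_r2(a.snp, b.snp)


def select_instruments(
    assocs: Iterable[VariantAssociation],
    cross_protein_counts: Mapping[str, int],
    ld: LDReference | LDPanel,
    params: SelectionParams | None = None,
    exposure_id: str = "exposure",
) -> InstrumentSet:
    """Apply the four selection rules plus the weak-instrument filter.

    Rules are applied in order — significance, MHC exclusion, greedy
    clumping (ascending p; a variant is kept iff its r² with every
    already-kept variant is below ``clump_r2``), cross-protein
    pleiotropy exclusion — followed by removal of instruments with
    F < ``min_f``.  Every dropped variant is recorded in the provenance
    map with the rule that removed it.
    """
    params = params or SelectionParams()
    provenance: dict[str, list[str]] = {}

    def note(snp, msg):
        provenance.setdefault(snp, []).append(msg)

    candidates = list(assocs)
    seen = set()
    for a in candidates:
        if a.snp in seen:
            raise ValueError(f"duplicate snp id {a.snp} in candidate table")
        seen.add(a.snp)

    # rule 1: genome-wide significance
    kept = []
    for a in candidates:
        if a.pval <= params.p_threshold:
            kept.append(a)
        else:
            note(a.snp, f"rule1_significance p={a.pval:.3g}")
    # rule 2: MHC exclusion
    survivors = []
    for a in kept:
        if (a.chromosome == params.mhc_chrom
                and params.mhc_start <= a.position <= params.mhc_end):
            note(a.snp, "rule2_mhc")
        else:
            survivors.append(a)
    # rule 3: greedy clumping, ascending p (ties by snp id for determinism)
    survivors.sort(key=lambda a: (a.pval, a.snp))
    clumped: list[VariantAssociation] = []
    for a in survivors:
        conflict = None
        for b in clumped:
            if _pair_r2(a, b, ld) >= params.clump_r2:
                conflict = b
                break
        if conflict is None:
            clumped.append(a)
        else:
            note(a.snp, f"rule3_clump r2>= {params.clump_r2} with {conflict.snp}")
    # rule 4: cross-protein pleiotropy
    after_pleio = []
    for a in clumped:
        count = cross_protein_counts.get(a.snp, 1)
        if count > params.max_proteins_per_snp:
            note(a.snp, f"rule4_pleiotropy proteins={count}")
        else:
            after_pleio.append(a)
    # weak-instrument filter
    final, r2s, fs = [], [], []
    for a in after_pleio:
        r2, f = compute_instrument_strength(a, params.r2_formula)
        if f < params.min_f:
            note(a.snp, f"weak_instrument F={f:.3g}")
        else:
            final.append(a)
            r2s.append(r2)
            fs.append(f)
            note(a.snp, "kept")
    final_sorted = sorted(range(len(final)), key=lambda i: final[i].position)
    return InstrumentSet(
        exposure_id=exposure_id,
        instruments=[final[i] for i in final_sorted],
        r2_explained=[r2s[i] for i in final_sorted],
        f_stat=[fs[i] for i in final_sorted],
        provenance=provenance,
        params=params,
    )


def cross_protein_counts(protein_tables: Mapping[str, pd.DataFrame],
                         p_threshold: float = 5e-8) -> dict[str, int]:
    """Number of proteins each SNP is associated with at ``p_threshold``,
    pooled across all supplied protein GWAS."""
    counts: dict[str, int] = {}
    for table in protein_tables.values():
        sig = table.loc[table["pval"] <= p_threshold, "snp"].unique()
        for snp in sig:
            counts[snp] = counts.get(snp, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Proxy lookup
# ---------------------------------------------------------------------------

def find_proxy(target: str, ld: LDReference, available: set[str],
               params: SelectionParams | None = None) -> str | None:
    """Best available proxy for ``target``: maximal r² subject to
    r² > ``proxy_r2``; ties broken by smaller base-pair distance, then
    lexicographically smaller id.  Returns ``None`` if nothing
    qualifies (the target itself, if available, wins at r² = 1)."""
    params = params or SelectionParams()
    if target not in ld:
        raise ValueError(f"proxy target {target} absent from LD reference")
    t_pos = ld.position_of(target)
    best = None
    for snp in available:
        if snp not in ld:
            continue
        r2 = ld.pairwise_r2(target, snp)
        if r2 <= params.proxy_r2:
            continue
        key = (-r2, abs(ld.position_of(snp) - t_pos), snp)
        if best is None or key < best[0]:
            best = (key, snp)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(
    instrument_set: InstrumentSet,
    outcome_table: pd.DataFrame,
    outcome_id: str = "outcome",
    ld: LDReference | LDPanel | None = None,
    params: SelectionParams | None = None,
) -> HarmonizedDataset:
    """Align outcome effects to each instrument's effect allele.

    Matching allele labels are kept as-is; swapped labels flip the sign
    of the outcome effect; strand-complement labels are complemented
    first.  Palindromic variants are dropped unconditionally, as are
    variants whose allele sets cannot be reconciled.  Instruments
    missing from the outcome table are resolved through
    :func:`find_proxy` (the proxy's own outcome association, unscaled)
    when an LD reference is supplied, and dropped otherwise.
    """
    params = params or instrument_set.params or SelectionParams()
    if outcome_table["snp"].duplicated().any():
        dups = outcome_table.loc[outcome_table["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicate snp ids in outcome table: {dups[:5]}")
    snps_in = [a.snp for a in instrument_set.instruments]
    if len(set(snps_in)) != len(snps_in):
        raise ValueError("duplicate snp ids in instrument set")

    out_by_snp = {row.snp: row for row in outcome_table.itertuples(index=False)}
    notes: dict[str, str] = {}
    snp_l, bx_l, bxse_l, by_l, byse_l = [], [], [], [], []

    for assoc in instrument_set.instruments:
        row = out_by_snp.get(assoc.snp)
        used_snp = assoc.snp
        if row is None:
            proxy = None
            if ld is not None:
                ref = (ld.reference_for(assoc.chromosome)
                       if isinstance(ld, LDPanel) else ld)
                if ref is not None and assoc.snp in ref:
                    proxy = find_proxy(assoc.snp, ref,
                                       set(out_by_snp) & set(ref.variant_ids),
                                       params)
            if proxy is None:
                notes[assoc.snp] = "dropped: absent from outcome, no proxy"
                continue
            row = out_by_snp[proxy]
            used_snp = proxy
            notes[assoc.snp] = f"proxy:{proxy}"
        if is_palindromic(assoc.effect_allele, assoc.other_allele):
            notes[assoc.snp] = "dropped: palindromic"
            continue
        ea_x, oa_x = assoc.effect_allele.upper(), assoc.other_allele.upper()
        ea_y, oa_y = row.ea.upper(), row.oa.upper()
        if is_palindromic(ea_y, oa_y):
            notes[assoc.snp] = "dropped: palindromic in outcome"
            continue
        if (ea_y, oa_y) == (ea_x, oa_x):
            sign = 1.0
        elif (ea_y, oa_y) == (oa_x, ea_x):
            sign = -1.0
        elif (complement_allele(ea_y), complement_allele(oa_y)) == (ea_x, oa_x):
            sign = 1.0
        elif (complement_allele(ea_y), complement_allele(oa_y)) == (oa_x, ea_x):
            sign = -1.0
        else:
            notes[assoc.snp] = "dropped: ambiguous alleles"
            continue
        snp_l.append(assoc.snp)
        bx_l.append(assoc.beta)
        bxse_l.append(assoc.se)
        by_l.append(sign * row.beta)
        byse_l.append(row.se)
        notes.setdefault(assoc.snp, f"aligned via {used_snp}")

    return HarmonizedDataset(
        exposure_id=instrument_set.exposure_id,
        outcome_id=outcome_id,
        snp=snp_l, bx=bx_l, bxse=bxse_l, by=by_l, byse=byse_l,
        notes=notes,
    )
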