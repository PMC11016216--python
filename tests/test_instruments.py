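"""Tests for instrument selection, proxies and harmonization."""

import itertools

import numpy as np
import pytest

from pqtlmr import (
    InstrumentSet,
    LDReference,
    MissingLDError,
    SelectionParams,
    VariantAssociation,
    associations_from_table,
    compute_instrument_strength,
    cross_protein_counts,
    find_proxy,
    harmonize,
    select_instruments,
)

from conftest import make_table


def assoc(snp="rs1", chrom="1", pos=1_000_000, ea="A", oa="G", eaf=0.3,
          beta=0.1, se=0.01, pval=1e-10, n=10_000):
    return VariantAssociation(snp=snp, chromosome=chrom, position=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n)


def ld_from_r2(ids, r2, chrom="1", positions=None):
    positions = positions or [1_000_000 + 10_000 * i for i in range(len(ids))]
    return LDReference(variant_ids=list(ids), r2=np.asarray(r2, float),
                       positions=np.asarray(positions), chromosome=chrom)


class TestInstrumentStrength:
    def test_null_effect(self):
        r2, f = compute_instrument_strength(assoc(beta=0.0))
        assert r2 == 0.0 and f == 0.0

    def test_hand_arithmetic(self):
        r2, f = compute_instrument_strength(assoc(eaf=0.5, beta=0.2, n=3000))
        assert r2 == pytest.approx(0.02)
        assert f == pytest.approx(0.02 * 2998 / 0.98)

    def test_maf_folding(self):
        # eaf above 0.5 folds onto the minor-allele frequency
        a, b = assoc(eaf=0.8, beta=0.2), assoc(eaf=0.2, beta=0.2)
        ra, fa = compute_instrument_strength(a)
        rb, fb = compute_instrument_strength(b)
        assert ra == pytest.approx(rb)
        assert fa == pytest.approx(fb)

    def test_z2_formula(self):
        a = assoc(beta=0.1, se=0.01, n=10_000)
        z2 = 100.0
        r2, _ = compute_instrument_strength(a, formula="z2")
        assert r2 == pytest.approx(z2 / (z2 + 10_000))

    def test_tiny_sample_raises(self):
        with pytest.raises(ValueError):
            compute_instrument_strength(assoc(n=2))


class TestSelectInstruments:
    def test_significance_filter(self):
        ld = ld_from_r2(["rs1", "rs2"], np.eye(2))
        out = select_instruments(
            [assoc("rs1", pval=1e-10), assoc("rs2", pos=1_010_000, pval=1e-7)],
            {}, ld)
        assert [a.snp for a in out.instruments] == ["rs1"]
        assert any("rule1" in m for m in out.provenance["rs2"])

    def test_mhc_window_dropped_regardless_of_p(self):
        ld = ld_from_r2(["rs1"], [[1.0]], chrom="6", positions=[30_000_000])
        out = select_instruments([assoc("rs1", chrom="6", pos=30_000_000,
                                        pval=1e-300)], {}, ld)
        assert out.nsnp == 0
        assert any("mhc" in m for m in out.provenance["rs1"])

    def test_mhc_boundaries_inclusive(self):
        ld = ld_from_r2(["rs_in", "rs_out"], np.eye(2), chrom="6",
                        positions=[26_000_000, 25_999_999])
        out = select_instruments(
            [assoc("rs_in", chrom="6", pos=26_000_000),
             assoc("rs_out", chrom="6", pos=25_999_999)], {}, ld)
        assert [a.snp for a in out.instruments] == ["rs_out"]

    def test_clumping_keeps_lower_p(self):
        ld = ld_from_r2(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
        out = select_instruments(
            [assoc("rs1", pval=1e-9), assoc("rs2", pos=1_010_000, pval=1e-10)],
            {}, ld)
        assert [a.snp for a in out.instruments] == ["rs2"]

    def test_cross_protein_pleiotropy_exclusion(self):
        ld = ld_from_r2(["rs1", "rs2"], np.eye(2))
        out = select_instruments(
            [assoc("rs1"), assoc("rs2", pos=1_010_000)],
            {"rs1": 5, "rs2": 4}, ld)
        assert [a.snp for a in out.instruments] == ["rs2"]
        assert any("rule4" in m for m in out.provenance["rs1"])

    def test_weak_instruments_removed(self):
        ld = ld_from_r2(["rs_strong", "rs_weak"], np.eye(2))
        weak = assoc("rs_weak", pos=1_010_000, eaf=0.5, beta=0.04, n=10_000)
        strong = assoc("rs_strong", eaf=0.5, beta=0.2, n=10_000)
        assert compute_instrument_strength(weak)[1] < 10
        out = select_instruments([strong, weak], {}, ld)
        assert [a.snp for a in out.instruments] == ["rs_strong"]
        assert any("weak" in m for m in out.provenance["rs_weak"])

    def test_missing_same_chromosome_ld_raises(self):
        ld = ld_from_r2(["rs1"], [[1.0]])
        with pytest.raises(MissingLDError):
            select_instruments(
                [assoc("rs1", pval=1e-10), assoc("rs_other", pos=1_020_000)],
                {}, ld)

    def test_different_chromosomes_are_unlinked(self):
        ld = ld_from_r2(["rs1"], [[1.0]], chrom="1")
        out = select_instruments(
            [assoc("rs1"), assoc("rs2", chrom="2")], {}, ld)
        assert out.nsnp == 2

    def test_duplicate_candidates_raise(self):
        ld = ld_from_r2(["rs1"], [[1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            select_instruments([assoc("rs1"), assoc("rs1")], {}, ld)

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        ids = [f"rs{i}" for i in range(8)]
        a = rng.uniform(-1, 1, (8, 3))
        c = np.corrcoef(a @ a.T + np.eye(8))
        ld = ld_from_r2(ids, c**2)
        cands = [assoc(ids[i], pos=1_000_000 + 10_000 * i,
                       pval=10.0 ** -rng.uniform(8, 30)) for i in range(8)]
        first = select_instruments(cands, {}, ld)
        second = select_instruments(first.instruments, {}, ld)
        assert [x.snp for x in second.instruments] == \
               [x.snp for x in first.instruments]

    def test_monotonicity_in_p_threshold(self):
        ld = ld_from_r2([f"rs{i}" for i in range(6)], np.eye(6))
        cands = [assoc(f"rs{i}", pos=1_000_000 + 10_000 * i,
                       pval=10.0 ** -(4 + 2 * i)) for i in range(6)]
        kept = {}
        for thr in (1e-12, 5e-8, 1e-5):
            out = select_instruments(cands, {}, ld,
                                     SelectionParams(p_threshold=thr))
            kept[thr] = {a.snp for a in out.instruments}
        assert kept[1e-12] <= kept[5e-8] <= kept[1e-5]

    def test_greedy_clumping_matches_brute_force(self):
        """For small candidate sets, verify against the definition:
        kept pairs are mutually independent and every dropped variant
        conflicts with a kept, lower-p variant."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            m = int(rng.integers(2, 12))
            ids = [f"rs{i}" for i in range(m)]
            load = rng.uniform(-1, 1, (m, 2))
            corr = np.corrcoef((load @ load.T) + 0.3 * np.eye(m))
            ld = ld_from_r2(ids, np.clip(corr**2, 0, 1))
            pvals = 10.0 ** -rng.uniform(8, 30, m)
            cands = [assoc(ids[i], pos=1_000_000 + 10_000 * i, pval=pvals[i])
                     for i in range(m)]
            params = SelectionParams(clump_r2=float(rng.uniform(0.05, 0.8)))
            out = select_instruments(cands, {}, ld, params)
            kept = {a.snp: a for a in out.instruments}
            for a, b in itertools.combinations(kept.values(), 2):
                assert ld.pairwise_r2(a.snp, b.snp) < params.clump_r2
            for cand in cands:
                if cand.snp in kept:
                    continue
                conflicts = [k for k in kept.values()
                             if ld.pairwise_r2(cand.snp, k.snp) >= params.clump_r2
                             and (k.pval, k.snp) < (cand.pval, cand.snp)]
                assert conflicts, f"{cand.snp} dropped without a conflict"


class TestCrossProteinCounts:
    def test_pooled_across_studies(self):
        t1 = make_table(["rs1", "rs2"], pval=[1e-10, 1e-5])
        t2 = make_table(["rs1"], pval=[1e-9])
        counts = cross_protein_counts({"p1": t1, "p2": t2})
        assert counts == {"rs1": 2}


class TestFindProxy:
    def test_target_itself_wins(self):
        ld = ld_from_r2(["rs1", "rs2"], [[1, 0.9], [0.9, 1]])
        assert find_proxy("rs1", ld, {"rs1", "rs2"}) == "rs1"

    def test_below_threshold_returns_none(self):
        ld = ld_from_r2(["rs1", "rs2"], [[1, 0.79], [0.79, 1]])
        assert find_proxy("rs1", ld, {"rs2"}) is None

    def test_threshold_is_strict(self):
        ld = ld_from_r2(["rs1", "rs2"], [[1, 0.8], [0.8, 1]])
        assert find_proxy("rs1", ld, {"rs2"}) is None

    def test_tie_breaks_distance_then_id(self):
        # rs_b and rs_c both at r2=0.9 and equidistant -> lexicographic
        r2 = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.5], [0.9, 0.5, 1.0]])
        ld = ld_from_r2(["rs_a", "rs_c", "rs_b"], r2,
                        positions=[1_000_000, 990_000, 1_010_000])
        assert find_proxy("rs_a", ld, {"rs_b", "rs_c"}) == "rs_b"

    def test_absent_target_raises(self):
        ld = ld_from_r2(["rs1"], [[1.0]])
        with pytest.raises(ValueError):
            find_proxy("rs_missing", ld, {"rs1"})


def iset(*assocs):
    return InstrumentSet(exposure_id="exp", instruments=list(assocs),
                         r2_explained=[0.02] * len(assocs),
                         f_stat=[100.0] * len(assocs))


class TestHarmonize:
    def test_identical_alleles_kept(self):
        out = make_table(["rs1"], ea="A", oa="G", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="G")), out)
        assert data.by[0] == pytest.approx(0.1)

    def test_swapped_alleles_flip_sign(self):
        out = make_table(["rs1"], ea="G", oa="A", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="G")), out)
        assert data.by[0] == pytest.approx(-0.1)

    def test_strand_complement_aligned(self):
        # exposure A/G; outcome reported on the other strand as T/C
        out = make_table(["rs1"], ea="T", oa="C", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="G")), out)
        assert data.by[0] == pytest.approx(0.1)

    def test_strand_complement_swapped_flips_sign(self):
        out = make_table(["rs1"], ea="C", oa="T", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="G")), out)
        assert data.by[0] == pytest.approx(-0.1)

    def test_palindromic_dropped_even_if_aligned(self):
        out = make_table(["rs1"], ea="A", oa="T", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="T")), out)
        assert data.nsnp == 0
        assert "palindromic" in data.notes["rs1"]

    def test_irreconcilable_alleles_dropped(self):
        out = make_table(["rs1"], ea="A", oa="C", beta=0.1)
        data = harmonize(iset(assoc("rs1", ea="A", oa="G")), out)
        assert data.nsnp == 0
        assert "ambiguous" in data.notes["rs1"]

    def test_duplicate_outcome_rows_raise(self):
        import pandas as pd
        out = pd.concat([make_table(["rs1"]), make_table(["rs1"])],
                        ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(iset(assoc("rs1")), out)

    def test_missing_variant_resolved_by_proxy(self):
        inst = assoc("rs1", ea="A", oa="G")
        ld = ld_from_r2(["rs1", "rs2"], [[1, 0.95], [0.95, 1]])
        out = make_table(["rs2"], pos=[1_010_000], ea="A", oa="G", beta=0.07)
        data = harmonize(iset(inst), out, ld=ld)
        assert data.nsnp == 1
        assert data.by[0] == pytest.approx(0.07)  # proxy effect used unscaled
        assert data.notes["rs1"] == "proxy:rs2"

    def test_missing_variant_without_proxy_dropped(self):
        out = make_table(["rs_other"])
        data = harmonize(iset(assoc("rs1")), out)
        assert data.nsnp == 0
        assert "no proxy" in data.notes["rs1"]

    def test_involution_under_programmatic_swap(self):
        """Swapping outcome alleles and negating effects is undone by
        harmonization."""
        rng = np.random.default_rng(9)
        insts = [assoc(f"rs{i}", pos=1_000_000 + 10_000 * i,
                       ea="A", oa="G", beta=float(rng.uniform(0.05, 0.3)))
                 for i in range(6)]
        out = make_table([f"rs{i}" for i in range(6)], ea="A", oa="G",
                         eaf=0.3, beta=list(rng.normal(0, 0.1, 6)))
        swapped = out.copy()
        swapped["ea"], swapped["oa"] = out["oa"], out["ea"]
        swapped["beta"] = -out["beta"]
        swapped["eaf"] = 1 - out["eaf"]
        direct = harmonize(iset(*insts), out)
        undone = harmonize(iset(*insts), swapped)
        assert direct.snp == undone.snp
        np.testing.assert_allclose(direct.by, undone.by, atol=1e-12)
        np.testing.assert_allclose(direct.bx, undone.bx)
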