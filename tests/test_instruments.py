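import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtmr.exceptions import ConfigurationError, EmptyRegionError, LDMatrixError
from dtmr.instruments import (
    SelectionConfig,
    bonferroni_threshold,
    drop_palindromic,
    extract_region_snps,
    ld_clump,
    select_instruments,
)
from dtmr.io import GenomicRegion, LDMatrix, VariantAssociation


def snp(rsid, pos, pval, ea="A", oa="G", chrom="1"):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa,
                              beta=0.1, se=0.01, pval=pval)


def ld_from(rsids, pairs):
    mat = np.eye(len(rsids))
    idx = {r: i for i, r in enumerate(rsids)}
    for a, b, r2 in pairs:
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r2
    return LDMatrix(rsids=list(rsids), r2=mat)


class TestRegionExtraction:
    REGIONS = [GenomicRegion("IL6R", "gene", "1", 1000, 2000),
               GenomicRegion("IL6R", "promoter", "1", 1800, 2500)]

    def test_inside_and_outside(self):
        snps = [snp("in", 1500, 1e-8), snp("out", 2501, 1e-8)]
        kept = extract_region_snps(snps, self.REGIONS, "IL6R")
        assert [s.rsid for s in kept] == ["in"]

    def test_overlapping_intervals_count_once(self):
        snps = [snp("both", 1900, 1e-8)]
        kept = extract_region_snps(snps, self.REGIONS, "IL6R")
        assert len(kept) == 1

    def test_unknown_target_is_config_error(self):
        with pytest.raises(ConfigurationError, match="TUBB"):
            extract_region_snps([], self.REGIONS, "TUBB")


class TestBonferroni:
    @pytest.mark.parametrize("alpha, n, expected", [
        (0.05, 100, 5e-4), (0.05, 1, 0.05), (0.05, 2000, 2.5e-5)])
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_empty_region_errors(self):
        with pytest.raises(EmptyRegionError):
            bonferroni_threshold(0.05, 0)


class TestClumping:
    def test_hand_worked_three_snp_case(self):
        # greedy: rs1 (1e-8) claims rs2 (r2 .5); rs3 independent survives
        snps = [snp("rs1", 1000, 1e-8), snp("rs2", 2000, 1e-6),
                snp("rs3", 3000, 1e-5)]
        ld = ld_from(["rs1", "rs2", "rs3"],
                     [("rs1", "rs2", 0.5), ("rs1", "rs3", 0.05),
                      ("rs2", "rs3", 0.02)])
        kept = ld_clump(snps, ld)
        assert [s.rsid for s in kept] == ["rs1", "rs3"]

    def test_distant_linked_pair_both_kept(self):
        snps = [snp("rs1", 1000, 1e-8), snp("rs2", 2_001_000, 1e-6)]
        ld = ld_from(["rs1", "rs2"], [("rs1", "rs2", 0.9)])
        assert len(ld_clump(snps, ld)) == 2

    def test_single_snp_kept(self):
        ld = ld_from(["rs1"], [])
        assert len(ld_clump([snp("rs1", 1000, 1e-8)], ld)) == 1

    def test_strict_mode_errors_on_missing_variant(self):
        ld = ld_from(["rs1"], [])
        snps = [snp("rs1", 1000, 1e-8), snp("rsX", 2000, 1e-6)]
        with pytest.raises(LDMatrixError, match="rsX"):
            ld_clump(snps, ld, SelectionConfig(strict_ld=True))
        assert len(ld_clump(snps, ld)) == 2  # lenient: unlinked

    @staticmethod
    def _greedy_oracle(snps, r2, r2_max, window):
        """Independent re-statement of the greedy clumping rule."""
        remaining = sorted(range(len(snps)),
                           key=lambda i: (snps[i].pval, snps[i].rsid))
        kept = []
        while remaining:
            i = remaining.pop(0)
            kept.append(i)
            remaining = [
                j for j in remaining
                if not (r2[i][j] >= r2_max
                        and abs(snps[i].pos - snps[j].pos) <= window)]
        return sorted(snps[i].rsid for i in kept)

    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_exhaustive_greedy_oracle(self, data):
        k = data.draw(st.integers(1, 8))
        pvals = data.draw(st.lists(
            st.floats(1e-30, 1.0, allow_nan=False), min_size=k, max_size=k))
        positions = data.draw(st.lists(
            st.integers(1, 3_000_000), min_size=k, max_size=k, unique=True))
        tri = data.draw(st.lists(st.floats(0, 1), min_size=k * k,
                                 max_size=k * k))
        r2 = np.array(tri).reshape(k, k)
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        snps = [snp(f"rs{i}", positions[i], pvals[i]) for i in range(k)]
        ld = LDMatrix(rsids=[s.rsid for s in snps], r2=r2)
        got = sorted(s.rsid for s in ld_clump(snps, ld))
        want = self._greedy_oracle(snps, r2.tolist(), 0.1, 1_000_000)
        assert got == want
        # validity: no kept pair is both linked and near
        kept = ld_clump(snps, ld)
        for a in kept:
            for b in kept:
                if a.rsid < b.rsid:
                    assert not (ld.lookup(a.rsid, b.rsid) >= 0.1
                                and abs(a.pos - b.pos) <= 1_000_000)

    def test_tightening_r2_never_keeps_more(self):
        rng = np.random.default_rng(0)
        k = 8
        snps = [snp(f"rs{i}", 1000 * (i + 1), float(rng.uniform(1e-9, 1e-3)))
                for i in range(k)]
        raw = rng.uniform(0, 1, (k, k))
        r2 = (raw + raw.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(rsids=[s.rsid for s in snps], r2=r2)
        counts = [len(ld_clump(snps, ld, SelectionConfig(r2_max=r)))
                  for r in (0.8, 0.5, 0.2, 0.05)]
        assert counts == sorted(counts, reverse=True)


class TestPalindromeFilter:
    @pytest.mark.parametrize("ea, oa, kept", [
        ("A", "T", False), ("C", "G", False), ("A", "G", True),
        ("T", "C", True)])
    def test_definition(self, ea, oa, kept):
        out = drop_palindromic([snp("rs1", 1, 1e-8, ea=ea, oa=oa)])
        assert bool(out) is kept


class TestSelectInstruments:
    def test_staged_counts_on_constructed_fixture(self):
        """50 region SNPs; 10 significant; 4 survive clumping; 1 of the
        survivors is palindromic, leaving 3."""
        regions = [GenomicRegion("G", "gene", "1", 1, 60_000_000)]
        snps = []
        # 40 decoys well above the threshold 0.05/50 = 1e-3
        for i in range(40):
            snps.append(snp(f"dec{i}", 50_000_000 + 1000 * i, 0.5))
        # 10 significant in three tight LD blocks (sizes 4, 3, 2) plus
        # one palindromic singleton; block members sit 10 kb apart
        blocks = [[0, 1, 2, 3], [4, 5, 6], [7, 8]]
        pairs = []
        for b, members in enumerate(blocks):
            for i in members:
                snps.append(snp(f"sig{i}", 5_000_000 * (b + 1) + 10_000 * i,
                                1e-9 * (i + 1)))
            pairs += [(f"sig{a}", f"sig{c}", 0.95)
                      for a in members for c in members if a < c]
        snps.append(snp("sig9", 45_000_000, 1e-8, ea="A", oa="T"))
        ld = ld_from([s.rsid for s in snps], pairs)
        report = select_instruments(snps, regions, "G", ld)
        assert report.n_region_snps == 50
        assert report.p_threshold == pytest.approx(1e-3)
        assert report.n_significant == 10
        assert report.n_post_clump == 4
        assert report.n_post_palindrome == 3
        assert sorted(report.kept_rsids) == ["sig0", "sig4", "sig7"]
        # counts weakly decreasing along the pipeline
        assert (report.n_region_snps >= report.n_significant
                >= report.n_post_clump >= report.n_post_palindrome)

    def test_independent_snps_all_survive_clump(self):
        regions = [GenomicRegion("G", "gene", "1", 1, 10_000_000)]
        snps = [snp(f"rs{i}", 100_000 * (i + 1), 1e-9) for i in range(5)]
        ld = ld_from([s.rsid for s in snps], [])
        report = select_instruments(snps, regions, "G", ld)
        assert report.n_post_clump == report.n_significant == 5

    def test_empty_region_overlap_raises(self):
        regions = [GenomicRegion("G", "gene", "2", 1, 100)]
        snps = [snp("rs1", 1000, 1e-9)]
        ld = ld_from(["rs1"], [])
        with pytest.raises(EmptyRegionError):
            select_instruments(snps, regions, "G", ld)

    def test_raising_alpha_never_loses_significant_snps(self):
        regions = [GenomicRegion("G", "gene", "1", 1, 10_000_000)]
        rng = np.random.default_rng(1)
        snps = [snp(f"rs{i}", 100_000 * (i + 1),
                    float(rng.uniform(1e-8, 1e-2))) for i in range(20)]
        ld = ld_from([s.rsid for s in snps], [])
        n_sig = [select_instruments(snps, regions, "G", ld,
                                    SelectionConfig(alpha=a)).n_significant
                 for a in (0.01, 0.05, 0.2, 0.8)]
        assert n_sig == sorted(n_sig)
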