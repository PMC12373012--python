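"""Cell QC, hypomethylation scoring, LSI embedding and marker calling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from methyl3c import methylome as meth
from methyl3c import simulate as sim
from methyl3c.cells import CellContacts, CellMethylome
from methyl3c.genome import GenomeSpec, Region, RegionSet


def _cell(records, cell_id="c"):
    return CellMethylome(cell_id, pd.DataFrame(records, columns=["chrom", "pos", "context", "mc", "cov"]))


def _contacts(n, genome, rng=None):
    rng = rng or np.random.default_rng(0)
    chroms = rng.choice(genome.names, size=n)
    pos1 = rng.integers(0, 100_000, size=n)
    pos2 = pos1 + rng.integers(1, 50_000, size=n)
    return CellContacts("c", pd.DataFrame({"chrom1": chroms, "pos1": pos1, "chrom2": chroms, "pos2": pos2}))


class TestQC:
    def _passing_cell(self):
        recs = [("chr1", i * 10, "CG", 8, 10) for i in range(50)]
        recs += [("chr1", 5000 + i, "CH", 0, 10) for i in range(20)]
        recs += [("chr1", 6000 + i, "CCC", 0, 10) for i in range(20)]
        return _cell(recs)

    def test_high_nonconversion_fails(self, small_genome):
        cell = self._passing_cell()
        cell.sites.loc[cell.sites["context"] == "CCC", "mc"] = 1  # mCCC = 0.1
        q = meth.qc_filter(cell, _contacts(150_000, small_genome), small_genome)
        assert not q.passed and "mccc" in q.fail_reasons

    def test_zero_contacts_fails(self, small_genome):
        q = meth.qc_filter(
            self._passing_cell(), CellContacts("c", pd.DataFrame()), small_genome
        )
        assert not q.passed and "contacts" in q.fail_reasons

    def test_global_mcg_exactly_at_threshold_fails(self, small_genome):
        # (4,5) and (1,5) -> global mCG = 5/10 = 0.5, strict > 0.5 required
        cell = _cell([("chr1", 10, "CG", 4, 5), ("chr1", 20, "CG", 1, 5)])
        q = meth.qc_filter(cell, _contacts(150_000, small_genome), small_genome)
        assert q.global_mcg == 0.5
        assert not q.passed and "mcg" in q.fail_reasons

    def test_no_cg_coverage(self, small_genome):
        cell = _cell([("chr1", 10, "CH", 0, 3)])
        q = meth.qc_filter(cell, _contacts(150_000, small_genome), small_genome)
        assert not q.passed and q.fail_reasons == ("no_coverage",)

    def test_missing_autosome_contact_fails(self, small_genome):
        df = pd.DataFrame({"chrom1": ["chr1"] * 150_000, "pos1": 10, "chrom2": ["chr1"] * 150_000, "pos2": 20})
        q = meth.qc_filter(self._passing_cell(), CellContacts("c", df), small_genome)
        assert "autosome_coverage" in q.fail_reasons

    def test_pass_invariant_to_record_order(self, small_genome):
        cell = self._passing_cell()
        shuffled = CellMethylome("c", cell.sites.sample(frac=1, random_state=4))
        con = _contacts(150_000, small_genome)
        assert (
            meth.qc_filter(cell, con, small_genome).passed
            == meth.qc_filter(shuffled, con, small_genome).passed
        )


class TestBinHypomethylation:
    def test_exact_binomial_example(self, small_genome):
        # cov=10, mc=0, global mCG 0.8 -> p = 0.2^10, indicator 1
        recs = [("chr1", i, "CG", 8, 10) for i in range(10_000, 14_000, 100)]
        recs += [("chr1", 100 + i * 10, "CG", 0, 1) for i in range(10)]
        cell = _cell(recs)
        m = meth.bin_hypomethylation([cell], small_genome, bin_size=5000)
        g = cell.global_fraction("CG")
        b0 = m.pvalues[0, 0]
        assert np.isclose(b0, stats.binom.cdf(0, 10, g))
        assert m.indicator[0, 0] == 1

    def test_fully_methylated_bin_not_flagged(self, small_genome):
        recs = [("chr1", 100 + i, "CG", 1, 1) for i in range(10)]
        recs += [("chr1", 10_000 + i * 100, "CG", 1, 2) for i in range(50)]
        m = meth.bin_hypomethylation([_cell(recs)], small_genome, bin_size=5000)
        assert m.pvalues[0, 0] == 1.0 and m.indicator[0, 0] == 0

    def test_zero_coverage_is_missing(self, small_genome):
        recs = [("chr1", 100, "CG", 1, 2)]
        m = meth.bin_hypomethylation([_cell(recs)], small_genome, bin_size=5000)
        assert m.missing[0, 1:].all() and not m.missing[0, 0]

    def test_blacklisted_bins_absent(self, small_genome):
        recs = [("chr1", 100, "CG", 1, 2)]
        bl = RegionSet([Region("chr1", 0, 5000)])
        m = meth.bin_hypomethylation([_cell(recs)], small_genome, bin_size=5000, blacklist=bl)
        assert not ((m.bins["chrom"] == "chr1") & (m.bins["start"] == 0)).any()

    @given(st.integers(1, 50), st.integers(0, 50), st.floats(0.05, 0.95))
    def test_score_matches_exact_cdf(self, cov, mc, g):
        mc = min(mc, cov)
        # independent oracle: explicit pmf summation
        from math import comb

        pmf = [comb(cov, k) * g**k * (1 - g) ** (cov - k) for k in range(mc + 1)]
        assert abs(meth.hypomethylation_pvalue(mc, cov, g) - sum(pmf)) < 1e-12


class TestLSI:
    def _block_matrix(self):
        rng = np.random.default_rng(0)
        X = np.zeros((40, 60))
        X[:20, :30] = rng.random((20, 30)) < 0.6
        X[20:, 30:] = rng.random((20, 30)) < 0.6
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(60) * 5000, "end": (np.arange(60) + 1) * 5000})
        return meth.BinScoreMatrix(
            [f"c{i}" for i in range(40)], bins, X.astype(float),
            np.ones_like(X, float), np.zeros_like(X, bool), np.ones_like(X, float),
        )

    def test_component_separates_groups(self):
        emb = meth.lsi_embed(self._block_matrix(), n_components=5)
        labels = np.array([0] * 20 + [1] * 20)
        best = 0.5
        for k in range(emb.shape[1]):
            auroc = stats.mannwhitneyu(emb[labels == 0, k], emb[labels == 1, k]).statistic / 400
            best = max(best, max(auroc, 1 - auroc))
        assert best == 1.0

    def test_rank_one_input(self):
        m = self._block_matrix()
        m.indicator = np.tile(m.indicator[:1], (40, 1))
        emb = meth.lsi_embed(m, n_components=5)
        assert np.allclose(np.std(emb[:, 1:], axis=0), 0, atol=1e-8)

    def test_output_shape_and_reduction_warning(self):
        m = self._block_matrix()
        emb = meth.lsi_embed(m, n_components=10)
        assert emb.shape[0] == 40 and emb.shape[1] <= 10
        with pytest.warns(UserWarning):
            small = meth.BinScoreMatrix(
                m.cell_ids[:3], m.bins, m.indicator[:3], m.pvalues[:3], m.missing[:3], m.coverage[:3]
            )
            meth.lsi_embed(small, n_components=30)


class TestGeneBodyMCG:
    def test_normalization_example(self):
        # raw 2/10 = 0.2 in a cell with global mCG 0.8 -> normalized 0.25
        recs = [("chr1", 100 + i * 10, "CG", 0, 1) for i in range(2)]
        recs[0] = ("chr1", 100, "CG", 2, 10)
        filler = [("chr1", 10_000 + i, "CG", 4, 5) for i in range(38)]
        cell = _cell(recs + filler)
        genes = RegionSet([Region("chr1", 50, 500, "g")])
        g = meth.gene_body_mcg([cell], genes, min_cov=5)
        global_mcg = cell.global_fraction("CG")
        assert np.isclose(g.raw[0, 0], 2 / 11)
        assert np.isclose(g.normalized[0, 0], (2 / 11) / global_mcg)

    def test_low_coverage_missing_and_cap(self):
        cell = _cell([("chr1", 100, "CG", 2, 3), ("chr1", 10_000, "CG", 9, 10), ("chr1", 10_010, "CG", 0, 990)])
        genes = RegionSet([Region("chr1", 50, 500, "lowcov"), Region("chr1", 9_900, 10_005, "hot")])
        g = meth.gene_body_mcg([cell], genes, min_cov=5)
        names = g.gene_names
        assert np.isnan(g.raw[0, names.index("lowcov")])
        assert g.normalized[0, names.index("hot")] == 10.0  # capped

    def test_small_covered_gene_excluded(self):
        genes = RegionSet(
            [Region("chr1", 100, 250, "small"), Region("chr1", 50, 500, "big")]
        )
        cell = _cell([("chr1", 150, "CG", 1, 10)])
        g = meth.gene_body_mcg([cell], genes, min_cov=5)
        assert g.gene_names == ["big"]


class TestMarkers:
    def _gbm(self, rng, n_in=20, n_out=60, diff=0.3):
        n_genes = 20
        norm = rng.normal(0.7, 0.05, size=(n_in + n_out, n_genes))
        norm[:n_in, 0] -= diff  # gene 0 hypomethylated in the tested type
        mc = np.full_like(norm, 50.0)
        cov = np.full_like(norm, 100.0)
        genes = [Region("chr1", i * 1000, i * 1000 + 500, f"g{i}") for i in range(n_genes)]
        gbm = meth.GeneBodyMCG(
            [f"c{i}" for i in range(n_in + n_out)], genes, norm.copy(), norm, mc, cov
        )
        labels = ["A"] * n_in + ["B"] * (n_out // 2) + ["C"] * (n_out - n_out // 2)
        return gbm, labels

    def test_planted_marker_recovered_in_both_modes(self):
        gbm, labels = self._gbm(np.random.default_rng(0))
        for mode in ("cluster", "dmg"):
            table = meth.call_mcg_markers(gbm, labels, mode=mode)
            passed = table[(table["cell_type"] == "A") & table["passed"]]
            assert "g0" in set(passed["gene"])

    def test_constant_gene_not_marker(self):
        gbm, labels = self._gbm(np.random.default_rng(1))
        gbm.normalized[:, 5] = 0.7
        table = meth.call_mcg_markers(gbm, labels, mode="dmg")
        row = table[(table["gene"] == "g5") & (table["cell_type"] == "A")]
        assert float(row["p"].iloc[0]) == 1.0 and not bool(row["passed"].iloc[0])

    def test_multi_type_marker_not_unique(self):
        gbm, labels = self._gbm(np.random.default_rng(2))
        # gene 1 hypomethylated in both A and B relative to C
        lab = np.asarray(labels)
        gbm.normalized[lab != "C", 1] -= 0.3
        table = meth.call_mcg_markers(gbm, labels, mode="dmg")
        g1 = table[(table["gene"] == "g1") & table["passed"]]
        assert len(g1) >= 2
        assert not g1["unique"].any()

    def test_permuted_labels_give_no_markers(self):
        gbm, labels = self._gbm(np.random.default_rng(3), diff=0.0)
        counts = []
        for s in range(10):
            perm = np.random.default_rng(s).permutation(labels)
            table = meth.call_mcg_markers(gbm, perm, mode="cluster")
            counts.append(int(table["passed"].sum()) if len(table) else 0)
        assert np.median(counts) == 0
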