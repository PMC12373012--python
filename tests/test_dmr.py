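"""DMS testing against enumeration oracles, state assignment, DMR merging."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methyl3c import dmr as dmr_mod


def _table(rows):
    """rows: list of (chrom, pos, (m_a, n_a, m_b, n_b, ...))"""
    K = len(rows[0][2]) // 2
    types = [chr(ord("a") + k) for k in range(K)]
    data = {}
    for k, t in enumerate(types):
        data[f"m_{t}"] = [r[2][2 * k] for r in rows]
        data[f"n_{t}"] = [r[2][2 * k + 1] for r in rows]
    idx = pd.MultiIndex.from_tuples([(r[0], r[1]) for r in rows])
    return pd.DataFrame(data, index=idx)


class TestStatistic:
    def test_residual_arithmetic(self):
        # m=8, n=10, pooled fraction 0.5 -> r = 3/sqrt(2.5)
        s, r = dmr_mod.dms_statistic(np.array([[8, 2]]), np.array([[10, 10]]))
        assert np.isclose(r[0, 0], 3 / np.sqrt(2.5))

    def test_degenerate_pool_gives_zero(self):
        s, _ = dmr_mod.dms_statistic(np.array([[10, 10]]), np.array([[10, 10]]))
        assert s[0] == 0.0

    def test_uncovered_type_contributes_zero_residual(self):
        _, r = dmr_mod.dms_statistic(np.array([[5, 0]]), np.array([[10, 0]]))
        assert r[0, 1] == 0.0


class TestPermutationOracle:
    def _exact_p(self, m_obs, n=(10, 10)):
        """Exhaustive fixed-margin enumeration for a K=2 table."""
        total_m = sum(m_obs)

        def stat(m1):
            s, _ = dmr_mod.dms_statistic(
                np.array([[m1, total_m - m1]]), np.array([list(n)])
            )
            return s[0]

        denom = comb(sum(n), total_m)
        p = 0.0
        s_obs = stat(m_obs[0])
        for m1 in range(max(0, total_m - n[1]), min(n[0], total_m) + 1):
            if stat(m1) >= s_obs - 1e-12:
                p += comb(n[0], m1) * comb(n[1], total_m - m1) / denom
        return p

    @pytest.mark.parametrize("m_obs", [(10, 0), (8, 2), (6, 4)])
    def test_permutation_matches_enumeration(self, m_obs):
        p_exact = self._exact_p(m_obs)
        tab = _table([("chr1", 100, (m_obs[0], 10, m_obs[1], 10))])
        n_perm = 40_000
        res = dmr_mod.test_dms(tab, n_perm=n_perm, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res["p"][0] - p_exact) < max(4 * se, 2 / n_perm)

    def test_null_site_not_significant(self):
        rows = [("chr1", i * 100, (10, 20, 10, 20, 10, 20)) for i in range(20)]
        res = dmr_mod.test_dms(_table(rows), n_perm=200, seed=1)
        assert not res["significant"].any()
        assert (res["q"] > 0.5).all()

    def test_low_coverage_sites_dropped(self):
        tab = _table([("chr1", 100, (1, 1, 0, 0)), ("chr1", 200, (5, 9, 1, 8))])
        res = dmr_mod.test_dms(tab, n_perm=50, seed=0)
        assert len(res) == 1 and res["pos"][0] == 200


class TestStates:
    def _dms(self, residuals, chrom="chr1"):
        n = len(residuals)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(n) * 100,
                "s": 1.0,
                "p": 0.001,
                "q": 0.001,
                "significant": True,
                "residual_a": residuals,
                "fraction_a": 0.5,
                "n_a": 10,
            }
        )
        return df

    def test_quantile_thresholds_match_oracle(self):
        r = [-3.0, -1.0, 0.0, 1.0, 3.0] * 3  # 15 sites on one chromosome
        out = dmr_mod.assign_states(self._dms(r))
        t_lo, t_hi = np.quantile(r, [0.4, 0.6])
        expected = np.where(np.array(r) < t_lo, "hypo", np.where(np.array(r) > t_hi, "hyper", "neutral"))
        assert (out["state_a"].to_numpy() == expected).all()

    def test_median_residual_is_neutral(self):
        r = list(np.linspace(-2, 2, 15))
        out = dmr_mod.assign_states(self._dms(r))
        median_idx = 7
        assert out["state_a"][median_idx] == "neutral"

    def test_genome_wide_fallback_warns(self):
        df = pd.concat(
            [self._dms([-1.0, 0.0, 1.0], "chr1"), self._dms(list(np.linspace(-2, 2, 12)), "chr2")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="genome-wide"):
            dmr_mod.assign_states(df)

    def test_antisymmetry_under_count_swap(self, methylome_sim):
        _, cells, labels, _ = methylome_sim
        tables = dmr_mod.aggregate_sites(cells[:20], labels[:20])
        types = sorted({c[2:] for c in tables.columns if c.startswith("m_")})
        swapped = tables.copy()
        for t in types:
            swapped[f"m_{t}"] = tables[f"n_{t}"] - tables[f"m_{t}"]
        res = dmr_mod.assign_states(dmr_mod.test_dms(tables, n_perm=100, seed=0))
        res_sw = dmr_mod.assign_states(dmr_mod.test_dms(swapped, n_perm=100, seed=0))
        flip = {"hypo": "hyper", "hyper": "hypo", "neutral": "neutral"}
        for t in types:
            assert (res[f"state_{t}"].map(flip).to_numpy() == res_sw[f"state_{t}"].to_numpy()).all()


def _sig_dms(chrom, pos, fracs, states):
    K = len(fracs)
    row = {"chrom": chrom, "pos": pos, "s": 1.0, "p": 1e-4, "q": 1e-4, "significant": True}
    for k in range(K):
        t = chr(ord("a") + k)
        row[f"fraction_{t}"] = fracs[k]
        row[f"state_{t}"] = states[k]
        row[f"residual_{t}"] = 0.0
    return row


class TestMergeDMRs:
    def test_identical_vectors_merge(self):
        df = pd.DataFrame(
            [
                _sig_dms("chr1", 100, (0.1, 0.9), ("hypo", "hyper")),
                _sig_dms("chr1", 200, (0.1, 0.9), ("hypo", "hyper")),
            ]
        )
        out = dmr_mod.merge_dmrs(df)
        assert len(out) == 1 and out["n_dms"][0] == 2
        assert out["start"][0] == 100 and out["end"][0] == 201

    def test_distant_sites_become_filtered_singletons(self):
        df = pd.DataFrame(
            [
                _sig_dms("chr1", 100, (0.1, 0.9), ("hypo", "hyper")),
                _sig_dms("chr1", 400, (0.1, 0.9), ("hypo", "hyper")),  # 300 bp away
            ]
        )
        assert len(dmr_mod.merge_dmrs(df)) == 0

    def test_state_from_mean_of_codes(self):
        # three chained sites; type-a codes (-1,-1,0) -> mean -2/3 -> hypo
        df = pd.DataFrame(
            [
                _sig_dms("chr1", 100, (0.10, 0.90, 0.5), ("hypo", "hyper", "neutral")),
                _sig_dms("chr1", 200, (0.11, 0.89, 0.5), ("hypo", "hyper", "neutral")),
                _sig_dms("chr1", 300, (0.12, 0.88, 0.52), ("neutral", "neutral", "neutral")),
            ]
        )
        out = dmr_mod.merge_dmrs(df)
        assert len(out) == 1 and out["n_dms"][0] == 3
        assert out["state_a"][0] == "hypo" and out["state_b"][0] == "hyper"
        assert out["state_c"][0] == "n.s."

    def test_constant_vector_not_mergeable(self):
        df = pd.DataFrame(
            [
                _sig_dms("chr1", 100, (0.5, 0.5), ("hypo", "hyper")),
                _sig_dms("chr1", 150, (0.4, 0.9), ("hypo", "hyper")),
            ]
        )
        assert len(dmr_mod.merge_dmrs(df)) == 0

    def test_all_neutral_region_excluded(self):
        df = pd.DataFrame(
            [
                _sig_dms("chr1", 100, (0.5, 0.7), ("neutral", "neutral")),
                _sig_dms("chr1", 150, (0.52, 0.72), ("neutral", "neutral")),
            ]
        )
        assert len(dmr_mod.merge_dmrs(df)) == 0

    def test_output_disjoint_sorted_and_members_within_span(self, methylome_sim):
        _, cells, labels, _ = methylome_sim
        tables = dmr_mod.aggregate_sites(cells, labels)
        dms = dmr_mod.assign_states(dmr_mod.test_dms(tables, n_perm=150, seed=0))
        out = dmr_mod.merge_dmrs(dms)
        assert len(out) > 0
        for chrom, sub in out.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts)
            assert (ends[order][:-1] <= starts[order][1:]).all()
        for rec in out.itertuples():
            assert all(rec.start <= p < rec.end for p in rec.dms_pos)


class TestSummaries:
    def test_marginals_and_combinations(self):
        dmrs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "start": np.arange(10) * 1000,
                "end": np.arange(10) * 1000 + 200,
                "state_a": ["hypo"] * 6 + ["n.s."] * 4,
                "state_b": ["n.s."] * 10,
            }
        )
        out = dmr_mod.summarize_states(dmrs)
        marg = out["marginals"].set_index("cell_type")
        assert np.isclose(marg.loc["a", "hypo"], 0.6)
        assert np.isclose(marg.loc["a"].sum(), 1.0)
        assert out["combinations"]["count"].iloc[0] == 6
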