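"""Generator contracts: determinism, planted structure, statistical targets."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methyl3c import simulate as sim
from methyl3c.genome import GenomeSpec, Region, RegionSet


def _meth_config(seed=0, **kw):
    cfg = sim.SimulationConfig(
        seed=seed, genome=GenomeSpec.uniform(2, 100_000), n_cell_types=2, cells_per_type=5
    )
    meth = dataclasses.replace(
        cfg.methylation, baselines=(0.75, 0.75), n_ch_sites=50, **kw
    )
    return dataclasses.replace(cfg, methylation=meth)


class TestMethylomes:
    def test_deterministic_under_seed(self):
        a = sim.simulate_methylomes(_meth_config(3))[0]
        b = sim.simulate_methylomes(_meth_config(3))[0]
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca.sites, cb.sites)

    def test_counts_within_coverage(self):
        cells, _, _ = sim.simulate_methylomes(_meth_config(1))
        for c in cells:
            assert (c.sites["mc"] <= c.sites["cov"]).all()
            assert (c.sites["mc"] >= 0).all()

    def test_planted_dmr_shifts_probabilities(self):
        cfg = _meth_config(2)
        dmr = sim.PlantedDMR("chr1", 1000, 2001, (0,), "hypo", 0.4)
        cfg = dataclasses.replace(
            cfg, methylation=dataclasses.replace(cfg.methylation, dmrs=(dmr,))
        )
        _, _, truth = sim.simulate_methylomes(cfg)
        pos = truth.cpg_positions["chr1"]
        inside = (pos >= 1000) & (pos < 2001)
        p = truth.methylation_p["chr1"]
        assert np.allclose(p[0, inside], 0.35)
        assert np.allclose(p[1, inside], 0.75)

    def test_clipping_warns(self):
        cfg = _meth_config(2)
        dmr = sim.PlantedDMR("chr1", 1000, 2001, (0,), "hyper", 0.5)
        cfg = dataclasses.replace(
            cfg, methylation=dataclasses.replace(cfg.methylation, dmrs=(dmr,))
        )
        with pytest.warns(UserWarning, match="clipping"):
            sim.simulate_methylomes(cfg)


def _contact_config(seed=0, **kw):
    cfg = sim.SimulationConfig(
        seed=seed, genome=GenomeSpec.uniform(1, 20_000_000), n_cell_types=2, cells_per_type=5
    )
    base = dict(
        n_contacts=20_000,
        decay_exponents=(1.4, 0.9),
        compartment_multiplier=1.0,
        flip_fraction=0.0,
    )
    base.update(kw)
    return dataclasses.replace(cfg, contacts=dataclasses.replace(cfg.contacts, **base))


class TestContacts:
    def test_deterministic_under_seed(self):
        a = sim.simulate_contacts(_contact_config(5))[0]
        b = sim.simulate_contacts(_contact_config(5))[0]
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca.pairs, cb.pairs)

    def test_decay_slope_matches_alpha(self):
        cfg = _contact_config(1)
        cells, labels, _ = sim.simulate_contacts(cfg)
        res = cfg.contacts.resolution
        for alpha, t in zip(cfg.contacts.decay_exponents, cfg.type_names()):
            d = np.concatenate(
                [c.distances() for c, l in zip(cells, labels) if l == t]
            ) // res
            n_bins = cfg.genome.length("chr1") // res
            counts = np.bincount(d, minlength=101)[2:101].astype(float)
            bins = np.arange(2, 101)
            counts /= n_bins - bins  # pairs available at each bin distance
            ok = counts > 0
            slope = np.polyfit(np.log(bins[ok] + 1), np.log(counts[ok]), 1)[0]
            assert abs(slope + alpha) < 0.15

    def test_steeper_decay_gives_higher_short_long_ratio(self):
        from methyl3c.contacts import short_long_ratio

        cfg = _contact_config(2, n_contacts=50_000)
        cfg = dataclasses.replace(cfg, genome=GenomeSpec.uniform(1, 40_000_000))
        cells, labels, _ = sim.simulate_contacts(cfg)
        ratios = {
            t: np.median(
                [short_long_ratio(c)[2] for c, l in zip(cells, labels) if l == t]
            )
            for t in cfg.type_names()
        }
        assert ratios["type1"] > ratios["type2"]  # alpha 1.4 vs 0.9


class TestExpression:
    @staticmethod
    def _expression_setup():
        """Methylome truth with long planted DMRs so genes carry mCG contrast."""
        cfg = sim.SimulationConfig(
            seed=8, genome=GenomeSpec.uniform(2, 400_000), n_cell_types=4, cells_per_type=5
        )
        meth = dataclasses.replace(cfg.methylation, n_ch_sites=0)
        cfg = dataclasses.replace(cfg, methylation=meth)
        cfg = dataclasses.replace(
            cfg,
            methylation=dataclasses.replace(
                cfg.methylation, dmrs=sim.random_dmrs(cfg, n=40, length=2000)
            ),
        )
        _, _, truth = sim.simulate_methylomes(cfg)
        return cfg, truth

    def test_anticorrelated_with_gene_body_mcg(self):
        cfg, truth = self._expression_setup()
        ec = dataclasses.replace(cfg.expression, n_genes=100, cells_per_type=30)
        cfg = dataclasses.replace(cfg, expression=ec)
        counts, labels = sim.simulate_expression(cfg, truth)
        labels = np.asarray(labels)
        p_tg = truth.gene_body_mcg
        mean_expr = np.stack(
            [counts.loc[:, labels == t].mean(axis=1).to_numpy() for t in cfg.type_names()]
        )
        marker = np.nanstd(p_tg, axis=0) > 0.02  # genes with a real mCG contrast
        assert marker.sum() >= 3
        cors = [
            np.corrcoef(p_tg[:, g], mean_expr[:, g])[0, 1] for g in np.where(marker)[0]
        ]
        assert np.mean(cors) <= -0.5

    def test_counts_are_nonnegative_integers(self, methylome_sim):
        cfg, _, _, truth = methylome_sim
        counts, _ = sim.simulate_expression(cfg, truth)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_equal_mcg_gives_equal_means(self, methylome_sim):
        cfg, _, _, truth = methylome_sim
        counts, labels = sim.simulate_expression(cfg, truth)
        labels = np.asarray(labels)
        p_tg = truth.gene_body_mcg
        flat = np.where(np.nanstd(p_tg, axis=0) < 1e-12)[0]
        assert len(flat) > 0
        means = np.stack(
            [counts.iloc[flat].loc[:, labels == t].mean(axis=1) for t in cfg.type_names()]
        )
        ratio = means.max(axis=0) / np.maximum(means.min(axis=0), 1e-9)
        assert np.median(ratio) < 1.5  # only NB noise separates the types


def _gen_config(seed=0, **kw):
    cfg = sim.SimulationConfig(seed=seed, genome=GenomeSpec.uniform(2, 10_000_000))
    return dataclasses.replace(cfg, genetics=dataclasses.replace(cfg.genetics, **kw))


class TestGenetics:
    def test_null_heritability_chi2(self):
        # mild LD keeps the Monte-Carlo error of the mean chi2 small
        cfg = _gen_config(5, heritability=0.0, ld_rho=0.3)
        ann = RegionSet([Region("chr1", 0, 2_000_000)])
        _, _, ss, _ = sim.simulate_genetics(cfg, ann)
        chi2 = (ss["beta"] / ss["se"]) ** 2
        assert abs(chi2.mean() - 1) < 0.1

    def test_adjacent_dosage_correlation(self):
        cfg = _gen_config(5)
        dos, _, _, _ = sim.simulate_genetics(cfg, RegionSet([]))
        D = dos.to_numpy(float)
        bs = cfg.genetics.ld_block_size
        cors = [
            np.corrcoef(D[:, b + j], D[:, b + j + 1])[0, 1]
            for b in range(0, D.shape[1] - bs, bs)
            for j in range(bs - 1)
        ]
        assert abs(np.mean(cors) - cfg.genetics.ld_rho) < 0.1

    def test_no_enrichment_matches_genomic_proportion(self):
        cfg = _gen_config(7, annotation_fold=1.0, causal_fraction=0.1)
        ann = RegionSet([Region("chr1", 0, 5_000_000)])  # 25% of the genome
        _, _, ss, truth = sim.simulate_genetics(cfg, ann)
        prop = truth.annotation_mask.mean()
        k = truth.annotation_mask[truth.causal_variants].sum()
        n = len(truth.causal_variants)
        se = np.sqrt(prop * (1 - prop) / n)
        assert abs(k / n - prop) < 4 * se

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_genetics(_gen_config(0, heritability=1.5), RegionSet([]))

    def test_deterministic_under_seed(self):
        a = sim.simulate_genetics(_gen_config(3), RegionSet([]))[0]
        b = sim.simulate_genetics(_gen_config(3), RegionSet([]))[0]
        pd.testing.assert_frame_equal(a, b)
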