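"""Synthetic-data generators: determinism, truth labels, planted effects."""

import math

import numpy as np
import pytest
from scipy import stats

from mirsnp import (
    SimulationConfig,
    classify_all,
    run_enrichment,
    simulate_annotations,
    simulate_bundle,
    simulate_catalog,
    simulate_expression,
    simulate_snp_gene_map,
    simulate_snps,
    spearman_assoc,
    wilcoxon_rank_sum,
)
from mirsnp.swap import changed_flags


class TestCatalog:
    def test_empty_config_gives_empty_catalog(self):
        assert len(simulate_catalog(SimulationConfig(n_mirnas=0))) == 0

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_mirnas=50, seed=9)
        assert simulate_catalog(cfg).records == simulate_catalog(cfg).records

    def test_large_catalog_has_unique_seeds(self):
        catalog = simulate_catalog(SimulationConfig(n_mirnas=2000, seed=1))
        seeds = {m.seed for m in catalog.records}
        assert len(seeds) == 2000

    def test_mature_length(self):
        catalog = simulate_catalog(SimulationConfig(n_mirnas=5, seed=2))
        assert all(len(m.mature_seq) == 22 for m in catalog.records)


class TestSnps:
    def test_truth_labels_exact_by_construction(self):
        cfg = SimulationConfig(n_snps=300, n_mirnas=60, seed=4)
        catalog = simulate_catalog(cfg)
        snps, truth = simulate_snps(cfg, catalog)
        changes, _ = classify_all(snps, catalog)
        for change in changes:
            assert change.changed == truth[change.snp_id]

    def test_zero_change_rate_all_unchanged(self):
        cfg = SimulationConfig(n_snps=100, n_mirnas=30, change_rate_target=0.0, seed=5)
        catalog = simulate_catalog(cfg)
        _, truth = simulate_snps(cfg, catalog)
        assert not truth.any()

    def test_fraction_changed_within_binomial_99ci(self):
        cfg = SimulationConfig(n_snps=2000, n_mirnas=60, seed=6)
        catalog = simulate_catalog(cfg)
        _, truth = simulate_snps(cfg, catalog)
        rate = cfg.change_rate_target
        lo, hi = stats.binom(cfg.n_snps, rate).ppf([0.005, 0.995]) / cfg.n_snps
        assert lo <= truth.mean() <= hi

    def test_same_seed_identical_records(self):
        cfg = SimulationConfig(n_snps=50, n_mirnas=30, seed=7)
        catalog = simulate_catalog(cfg)
        assert simulate_snps(cfg, catalog)[0] == simulate_snps(cfg, catalog)[0]


class TestAnnotations:
    @staticmethod
    def _truth(cfg, n):
        rng = np.random.default_rng(cfg.seed + 1000)
        import pandas as pd

        return pd.Series(
            rng.random(n) < cfg.change_rate_target,
            index=[f"rs{i:06d}" for i in range(n)],
        )

    def test_null_disease_plant_covers_or_one(self):
        cfg = SimulationConfig(
            n_snps=20000, planted_or_disease=1.0, clinvar_baseline_rate=0.07, seed=8
        )
        truth = self._truth(cfg, cfg.n_snps)
        tracks = simulate_annotations(cfg, truth)
        from mirsnp import RegulationChange

        changes = [
            RegulationChange(s, frozenset({"m"}) if c else frozenset(), frozenset())
            for s, c in truth.items()
        ]
        result = run_enrichment(changes, tracks["disease_clinvar"], "disease")
        t = result.table
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        assert abs(math.log(result.odds_ratio)) <= 1.96 * se

    def test_ihs_shift_detectable_by_wilcoxon(self):
        cfg = SimulationConfig(n_snps=9000, planted_ihs_shift=0.1, seed=9)
        truth = self._truth(cfg, cfg.n_snps)
        tracks = simulate_annotations(cfg, truth)
        values = tracks["ihs_ASN"].values
        xs = [abs(v) for s, v in values.items() if truth[s]]
        ys = [abs(v) for s, v in values.items() if not truth[s]]
        assert len(xs) > 2500 and len(ys) > 2500
        assert wilcoxon_rank_sum(xs, ys) <= 0.05

    def test_ihs_track_is_partial(self):
        cfg = SimulationConfig(n_snps=1000, ihs_missing_frac=0.3, seed=10)
        truth = self._truth(cfg, cfg.n_snps)
        tracks = simulate_annotations(cfg, truth)
        coverage = len(tracks["ihs_CEU"].values) / cfg.n_snps
        assert 0.6 < coverage < 0.8

    def test_null_tail_fraction_matches_config(self):
        cfg = SimulationConfig(
            n_snps=50000, change_rate_target=0.0, ihs_tail_frac=0.0124, seed=11
        )
        truth = self._truth(cfg, cfg.n_snps)
        tracks = simulate_annotations(cfg, truth)
        values = np.array(list(tracks["ihs_YRI"].values.values()))
        frac = np.mean(np.abs(values) >= 2.5)
        assert frac == pytest.approx(0.0124, abs=0.003)


class TestExpression:
    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_snps=100, seed=12)
        truth = TestAnnotations._truth(cfg, cfg.n_snps)
        mapping = simulate_snp_gene_map(cfg, list(truth.index))
        first = simulate_expression(cfg, truth, mapping)
        second = simulate_expression(cfg, truth, mapping)
        assert first[0].data.equals(second[0].data)
        assert first[1].data.equals(second[1].data)

    def test_null_eqtl_fraction_plants_nothing(self):
        cfg = SimulationConfig(n_snps=100, eqtl_frac=0.0, seed=13)
        truth = TestAnnotations._truth(cfg, cfg.n_snps)
        mapping = simulate_snp_gene_map(cfg, list(truth.index))
        _, _, planted = simulate_expression(cfg, truth, mapping)
        assert planted == {}

    def test_genotypes_are_hardy_weinberg_dosages(self):
        cfg = SimulationConfig(n_snps=200, n_samples=60, seed=14)
        truth = TestAnnotations._truth(cfg, cfg.n_snps)
        mapping = simulate_snp_gene_map(cfg, list(truth.index))
        gmat, _, _ = simulate_expression(cfg, truth, mapping)
        values = gmat.data.to_numpy()
        assert set(np.unique(values)) <= {0.0, 1.0, 2.0}

    def test_planted_pairs_detected_more_often_than_null(self):
        cfg = SimulationConfig(
            n_snps=600, n_samples=60, eqtl_frac=0.5, eqtl_effect_sd=1.0, seed=15
        )
        truth = TestAnnotations._truth(cfg, cfg.n_snps)
        mapping = simulate_snp_gene_map(cfg, list(truth.index))
        gmat, emat, planted = simulate_expression(cfg, truth, mapping)
        planted_hits, planted_n = 0, 0
        null_hits, null_n = 0, 0
        for snp_id in gmat.snp_ids:
            gene = mapping[snp_id]
            rho, p, _ = spearman_assoc(gmat.data.loc[snp_id], emat.data.loc[gene])
            if math.isnan(rho):
                continue
            if gene in planted:
                planted_hits += p <= 0.05
                planted_n += 1
            else:
                null_hits += p <= 0.05
                null_n += 1
        assert planted_hits / planted_n > null_hits / null_n


class TestBundle:
    def test_bundle_is_consistent_and_deterministic(self):
        cfg = SimulationConfig(n_snps=120, n_mirnas=40, seed=16)
        bundle = simulate_bundle(cfg)
        assert len(bundle.snps) == 120
        assert set(bundle.truth.index) == {s.snp_id for s in bundle.snps}
        assert set(bundle.snp_to_gene) == set(bundle.truth.index)
        again = simulate_bundle(cfg)
        assert bundle.truth.equals(again.truth)
        assert bundle.genotypes.data.equals(again.genotypes.data)

    def test_pipeline_stages_run_on_bundle(self):
        cfg = SimulationConfig(n_snps=150, n_mirnas=40, clinvar_baseline_rate=0.1, seed=17)
        bundle = simulate_bundle(cfg)
        changes, summary = classify_all(bundle.snps, bundle.catalog)
        assert summary.loc["all", "n"] == 150
        result = run_enrichment(changes, bundle.tracks["disease_clinvar"], "disease")
        assert 0 <= result.p_value <= 1
        flags = changed_flags(changes)
        assert sum(flags.values()) == bundle.truth.sum()
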