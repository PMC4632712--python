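"""Contingency-table statistics: Fisher, odds ratios, |iHS| screen, Wilcoxon."""

import math

import numpy as np
import pytest

from mirsnp import (
    AnnotationTrack,
    ContingencyTable2x2,
    RegulationChange,
    fisher_exact,
    make_table,
    odds_ratio,
    run_enrichment,
    strong_selection_flags,
    wilcoxon_rank_sum,
)
from mirsnp.errors import EmptySampleError, EmptyUniverseError, InvalidThresholdError

from _oracles import fisher_two_sided_enumeration, rank_sum_exact_two_sided


class TestSelectionFlags:
    def test_absolute_threshold_both_signs(self):
        track = AnnotationTrack("scalar", {"s1": 2.91, "s2": -2.6, "s3": 1.0})
        assert strong_selection_flags(track) == {"s1": 1, "s2": 1, "s3": 0}

    def test_empty_track(self):
        assert strong_selection_flags(AnnotationTrack("scalar", {})) == {}

    def test_boundary_is_inclusive(self):
        track = AnnotationTrack("scalar", {"s1": -0.5})
        assert strong_selection_flags(track, threshold=0.5) == {"s1": 1}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            strong_selection_flags(AnnotationTrack("scalar", {"s": 1.0}), threshold=0)


class TestMakeTable:
    def test_all_unannotated_fills_second_column(self):
        changed = {f"s{i}": int(i < 3) for i in range(10)}
        annotated = {f"s{i}": 0 for i in range(10)}
        t = make_table(changed, annotated)
        assert (t.a, t.b, t.c, t.d) == (0, 3, 0, 7)

    def test_counts_match_brute_force_tally(self, rng):
        ids = [f"s{i}" for i in range(200)]
        changed = {i: int(rng.random() < 0.4) for i in ids}
        annotated = {i: int(rng.random() < 0.1) for i in ids}
        t = make_table(changed, annotated)
        expect = [0, 0, 0, 0]
        for i in ids:
            expect[(1 - changed[i]) * 2 + (1 - annotated[i])] += 1
        assert [t.a, t.b, t.c, t.d] == expect
        assert t.total == 200

    def test_universe_is_intersection(self):
        t = make_table({"x": 1, "y": 0}, {"y": 1, "z": 0})
        assert (t.a, t.b, t.c, t.d) == (0, 0, 1, 0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(EmptyUniverseError):
            make_table({"x": 1}, {"y": 1})


class TestFisherAndOddsRatio:
    def test_symmetric_table_is_null(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(200):
            cells = rng.integers(0, 11, size=4)
            if cells.sum() == 0 or cells.sum() > 40:
                continue
            t = ContingencyTable2x2(*map(int, cells))
            if t.has_zero_margin():
                continue
            expected = fisher_two_sided_enumeration(t.a, t.b, t.c, t.d)
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_simultaneous_transposition(self, rng):
        for _ in range(50):
            a, b, c, d = map(int, rng.integers(1, 50, size=4))
            p1 = fisher_exact(ContingencyTable2x2(a, b, c, d))
            p2 = fisher_exact(ContingencyTable2x2(a, c, b, d))  # transpose
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_odds_ratio_reciprocal_under_row_swap(self, rng):
        for _ in range(50):
            a, b, c, d = map(int, rng.integers(1, 50, size=4))
            orig = odds_ratio(ContingencyTable2x2(a, b, c, d))
            swapped = odds_ratio(ContingencyTable2x2(c, d, a, b))
            assert swapped == pytest.approx(1 / orig, rel=1e-12)

    def test_zero_cell_conventions(self):
        assert odds_ratio(ContingencyTable2x2(5, 0, 3, 7)) == math.inf
        assert math.isnan(odds_ratio(ContingencyTable2x2(0, 5, 0, 7)))

    def test_zero_margin_degenerate_p_is_one(self):
        t = ContingencyTable2x2(0, 0, 3, 7)
        assert t.has_zero_margin()
        assert fisher_exact(t) == 1.0

    def test_scaling_cells_sharpens_significance(self):
        base = (6, 4, 3, 7)
        p1 = fisher_exact(ContingencyTable2x2(*base))
        p2 = fisher_exact(ContingencyTable2x2(*(4 * x for x in base)))
        assert p2 <= p1


class TestWilcoxon:
    def test_identical_samples_null(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(xs, list(xs)) == pytest.approx(1.0)

    def test_small_samples_match_rank_split_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, size=2)
            xs = rng.normal(size=int(n1))
            ys = rng.normal(size=int(n2))
            expected = rank_sum_exact_two_sided(xs, ys)
            assert wilcoxon_rank_sum(xs, ys) == pytest.approx(expected, rel=1e-9)

    def test_power_against_planted_shift(self, rng):
        """A 0.1 location shift in |iHS| at 3000/group is detected at 0.05
        in at least 80% of replicates."""
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            base = np.abs(rng.normal(size=3000))
            shifted = np.abs(rng.normal(size=3000)) + 0.1
            hits += wilcoxon_rank_sum(shifted, base) <= 0.05
        assert hits / n_rep >= 0.8

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            wilcoxon_rank_sum([], [1.0])


class TestRunEnrichment:
    @staticmethod
    def _changes(flags):
        return [
            RegulationChange(s, frozenset({"m"}) if f else frozenset(), frozenset())
            for s, f in flags.items()
        ]

    def test_selection_mode_composes_threshold_and_table(self):
        flags = {"a": 1, "b": 1, "c": 0, "d": 0}
        track = AnnotationTrack(
            "scalar", {"a": 2.7, "b": 0.3, "c": -2.6, "d": 0.1}, population="ASN"
        )
        result = run_enrichment(self._changes(flags), track, "selection")
        t = result.table
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert result.population == "ASN"

    def test_selection_universe_excludes_snps_without_score(self):
        flags = {"a": 1, "b": 1, "c": 0, "d": 0}
        track = AnnotationTrack("scalar", {"a": 2.7, "c": 0.0, "d": 3.0})
        result = run_enrichment(self._changes(flags), track, "selection")
        assert result.table.total == 3  # "b" has no iHS value

    def test_disease_mode_uses_binary_track_directly(self):
        flags = {"a": 1, "b": 1, "c": 0, "d": 0}
        track = AnnotationTrack("binary", {"a": 1, "b": 0, "c": 0, "d": 1})
        result = run_enrichment(self._changes(flags), track, "disease")
        t = result.table
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_changed_universe_is_degenerate(self):
        flags = {"a": 1, "b": 1}
        track = AnnotationTrack("binary", {"a": 1, "b": 0})
        result = run_enrichment(self._changes(flags), track, "disease")
        assert result.degenerate
        assert result.p_value == 1.0

    def test_planted_odds_ratio_recovered_within_wald_ci(self, rng):
        """A planted OR of 1.6 on 47k SNPs lands inside the 95% Wald CI."""
        n = 47_000
        changed = rng.random(n) < 0.459
        base, planted = 0.002, 1.6
        logit = math.log(base / (1 - base)) + np.where(changed, math.log(planted), 0.0)
        disease = rng.random(n) < 1 / (1 + np.exp(-logit))
        ids = [f"s{i}" for i in range(n)]
        track = AnnotationTrack("binary", dict(zip(ids, disease.astype(int))))
        changes = self._changes(dict(zip(ids, changed.astype(int))))
        result = run_enrichment(changes, track, "disease")
        t = result.table
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        log_or = math.log(result.odds_ratio)
        assert log_or - 1.96 * se <= math.log(planted) <= log_or + 1.96 * se
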