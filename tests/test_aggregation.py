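"""Inclusion-count table handling and the consequence/aggregation
association statistic."""

import numpy as np
import pytest
from scipy import stats

from helpers import fisher_exact_p

from sodscan.aggregation import (
    InclusionCounts,
    aggregator_table,
    associate,
    call_aggregator,
    format_percentage,
    inclusion_fraction,
    load_packaged_counts,
    packaged_expected_labels,
    read_counts_table,
    round_half_up,
)


class TestFractions:
    def test_e40g_48h_is_78_percent(self):
        c = InclusionCounts("E40G", 48, 238, 186)
        assert round_half_up(inclusion_fraction(c)) == 78

    def test_zero_inclusions_zero_percent(self):
        c = InclusionCounts("E40Q", 48, 229, 0)
        assert inclusion_fraction(c) == 0.0
        assert format_percentage(c) == "0%"

    def test_wild_type_background_renders_le_one(self):
        c = InclusionCounts("WT", 24, 656, 5)
        assert inclusion_fraction(c) == pytest.approx(0.762, abs=1e-3)
        assert format_percentage(c) == "≤ 1%"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            InclusionCounts("X", 24, 0, 0)
        with pytest.raises(ValueError):
            InclusionCounts("X", 24, 10, 11)


class TestPackagedTable:
    def test_twelve_variants_two_timepoints(self):
        records = load_packaged_counts()
        assert len(records) == 24
        assert len({r.variant for r in records}) == 12

    def test_all_printed_percentages_reproduced(self):
        expected = {
            ("WT", 24): "≤ 1%", ("WT", 48): "1%",
            ("G93A", 24): "23%", ("G93A", 48): "48%",
            ("E40D", 24): "34%", ("E40D", 48): "23%",
            ("E40G", 24): "29%", ("E40G", 48): "78%",
            ("E40Q", 24): "0%", ("E40Q", 48): "0%",
            ("E40V", 24): "24%", ("E40V", 48): "25%",
            ("E133D", 24): "0%", ("E133D", 48): "0%",
            ("E133G", 24): "0%", ("E133G", 48): "0%",
            ("E133L", 24): "0%", ("E133L", 48): "0%",
            ("E133M", 24): "0%", ("E133M", 48): "0%",
            ("E133V", 24): "12%", ("E133V", 48): "24%",
            ("E133del", 24): "6%", ("E133del", 48): "24%",
        }
        for rec in load_packaged_counts():
            assert format_percentage(rec) == expected[(rec.variant, rec.timepoint)]

    def test_expected_labels_cover_the_panel(self):
        labels = packaged_expected_labels()
        assert len(labels) == 11 and "WT" not in labels


class TestAggregatorCalls:
    def _pair(self, variant, f24, f48, n=300):
        return (
            InclusionCounts(variant, 24, n, int(round(n * f24 / 100))),
            InclusionCounts(variant, 48, n, int(round(n * f48 / 100))),
        )

    def test_high_frequency_variant_is_aggregator(self):
        c24 = InclusionCounts("E133V", 24, 324, 38)
        c48 = InclusionCounts("E133V", 48, 254, 62)
        is_agg, margin = call_aggregator(c24, c48, cutoff=5.0)
        assert is_agg and margin > 0

    def test_zero_variant_is_not(self):
        c24 = InclusionCounts("E133L", 24, 275, 0)
        c48 = InclusionCounts("E133L", 48, 373, 0)
        assert call_aggregator(c24, c48, cutoff=5.0)[0] is False

    def test_cutoff_boundary_strict(self):
        c24, c48 = self._pair("X", 5.0, 5.0, n=100)
        assert call_aggregator(c24, c48, cutoff=5.0)[0] is False

    def test_variant_mismatch_rejected(self):
        a, _ = self._pair("A", 1, 1)
        _, b = self._pair("B", 1, 1)
        with pytest.raises(ValueError, match="variant"):
            call_aggregator(a, b)

    def test_calls_monotone_in_cutoff(self):
        records = load_packaged_counts()
        prev = None
        for cutoff in (1.5, 3.0, 5.0, 10.0, 25.0):
            tab = aggregator_table(records, cutoff=cutoff)
            n = int(tab["aggregator"].sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_packaged_panel_dichotomy_at_default_cutoff(self):
        tab = aggregator_table(load_packaged_counts(), cutoff=5.0)
        agg = set(tab[tab["aggregator"]]["variant"])
        assert agg == {"G93A", "E40D", "E40G", "E40V", "E133V", "E133del"}


class TestAssociation:
    def test_packaged_panel_perfectly_concordant(self):
        tab = aggregator_table(load_packaged_counts(), cutoff=5.0)
        sub = tab[tab["variant"] != "WT"]
        labels = packaged_expected_labels()
        cons = [labels[v] != "None" for v in sub["variant"]]
        result = associate(cons, list(sub["aggregator"]))
        assert result.contingency.tolist() == [[6, 0], [0, 5]]
        assert result.p_value == pytest.approx(fisher_exact_p([[6, 0], [0, 5]]), abs=1e-12)
        assert result.haldane_corrected
        assert result.odds_ratio == pytest.approx((6.5 * 5.5) / 0.25)

    def test_fisher_p_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            scipy_p = stats.fisher_exact(t)[1]
            assert scipy_p == pytest.approx(fisher_exact_p(t.tolist()), abs=1e-10)

    def test_degenerate_all_aggregators_flagged(self):
        result = associate([True, True, False], [True, True, True])
        assert result.haldane_corrected
        assert np.isfinite(result.odds_ratio)

    def test_length_mismatch_and_tiny_panels_rejected(self):
        with pytest.raises(ValueError):
            associate([True], [True, False])
        with pytest.raises(ValueError):
            associate([True], [True])

    def test_null_p_values_are_valid(self):
        """With aggregation independent of the calls, P(p <= t) must not
        exceed t (beyond Monte-Carlo error) at any level: the exact test
        is valid, if conservative, on a small panel."""
        rng = np.random.default_rng(42)
        cons = [True] * 6 + [False] * 5
        pvals = []
        for _ in range(1000):
            flags = list(rng.permutation([True] * 6 + [False] * 5))
            pvals.append(associate(cons, flags).p_value)
        pvals = np.array(pvals)
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert np.mean(pvals <= t) <= t + 0.05


class TestReadCountsTable:
    def test_packaged_csv_parses(self):
        assert len(load_packaged_counts()) == 24

    def test_tsv_accepted(self):
        text = (
            "variant\ttimepoint_hr\tn_counted\tn_inclusions\n"
            "X\t24\t100\t5\nX\t48\t100\t9\n"
        )
        recs = read_counts_table(text)
        assert len(recs) == 2 and recs[1].n_inclusions == 9

    def test_row_invariant_violation_reported(self):
        text = "variant,timepoint_hr,n_counted,n_inclusions\nX,24,10,11\n"
        with pytest.raises(ValueError, match="row 0"):
            read_counts_table(text)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            read_counts_table("")

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="required column"):
            read_counts_table("variant,n_counted\nX,10\n")
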