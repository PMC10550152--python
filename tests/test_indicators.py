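"""Unit and property tests for the twelve plot-level indicators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meadowtrade as mt
from meadowtrade.errors import DomainError, MeadowTradeError
from meadowtrade.indicators import (
    INDICATORS,
    assemble_indicator_matrix,
    bumblebee_abundance,
    correlation_screen,
    forb_richness,
    mean_dry_matter,
    nectar_productivity,
    percent_parasitism,
    shannon_index,
)

abundances = st.lists(
    st.floats(min_value=0.01, max_value=1e6, allow_nan=False), min_size=1, max_size=30
)


class TestShannonIndex:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ([10], 0.0),
            ([5, 5], math.log(2)),
            # oracle: direct summation of -sum(p ln p) for p = (0.2, 0.3, 0.5)
            ([2, 3, 5], 1.0296530140645737),
            ([1, 0, 1, 0], math.log(2)),  # zeros ignored
        ],
    )
    def test_matches_hand_computed_entropy(self, vector, expected):
        assert shannon_index(vector) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("vector", [[], [0, 0], [1, -2]])
    def test_undefined_inputs_raise(self, vector):
        with pytest.raises(DomainError):
            shannon_index(vector)

    @settings(max_examples=100, derandomize=True)
    @given(abundances)
    def test_bounds_zero_to_log_richness(self, a):
        h = shannon_index(a)
        assert -1e-12 <= h <= math.log(len(a)) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(abundances, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, c):
        assert shannon_index([c * x for x in a]) == pytest.approx(
            shannon_index(a), rel=1e-9, abs=1e-9
        )

    def test_maximal_iff_even_community(self):
        assert shannon_index([3, 3, 3]) == pytest.approx(math.log(3), abs=1e-12)
        assert shannon_index([3, 3, 4]) < math.log(3)


class TestForbRichness:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["plot", "species", "percent_cover", "is_forb"])

    def test_empty_is_zero(self):
        assert forb_richness(self.make([])) == 0

    def test_counts_only_distinct_abundant_forbs(self):
        rows = [
            ("p1", "f1", 10.0, True),
            ("p1", "f1", 5.0, True),  # duplicate cover record -> counted once
            ("p1", "f2", 1.0, True),
            ("p1", "f3", 2.0, True),
            ("p1", "g1", 60.0, False),
            ("p1", "g2", 20.0, False),
            ("p1", "f4", 0.0, True),  # zero cover -> not counted
        ]
        assert forb_richness(self.make(rows)) == 3


class TestNectarProductivity:
    REF = {"A": 0.5, "B": 1.2}

    @pytest.mark.parametrize(
        "counts, ref, expected",
        [
            ({}, {"A": 0.5}, 0.0),
            ({"A": 10}, {"A": 2.0}, 20.0),
            ({"A": 7, "B": 3}, {"A": 0.5, "B": 1.2}, 7.1),  # 3.5 + 3.6 by hand
        ],
    )
    def test_sum_of_counts_times_reference(self, counts, ref, expected):
        assert nectar_productivity(counts, ref) == pytest.approx(expected, abs=1e-9)

    def test_additive_over_disjoint_species_sets(self):
        whole = nectar_productivity({"A": 7, "B": 3}, self.REF)
        parts = nectar_productivity({"A": 7}, self.REF) + nectar_productivity(
            {"B": 3}, self.REF
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_unknown_species_policy(self):
        with pytest.raises(DomainError):
            nectar_productivity({"X": 2}, self.REF)
        assert nectar_productivity({"X": 2, "A": 2}, self.REF, on_missing="skip") == 1.0


class TestPercentParasitism:
    def make(self, n_para, n_miner):
        rows = [("p1", "parasitoid", f"w{i}") for i in range(n_para)]
        rows += [("p1", "miner_adult", f"m{i}") for i in range(n_miner)]
        return pd.DataFrame(rows, columns=["plot", "outcome", "species"])

    @pytest.mark.parametrize(
        "n_para, n_miner, expected", [(0, 20, 0.0), (5, 15, 25.0)]
    )
    def test_share_of_total_emergences(self, n_para, n_miner, expected):
        assert percent_parasitism(self.make(n_para, n_miner)) == pytest.approx(expected)

    def test_pooled_study_scale_counts(self):
        # 515 parasitoids alongside 1565 miner adults -> 100*515/2080
        out = percent_parasitism(self.make(515, 1565))
        assert out == pytest.approx(100 * 515 / 2080, abs=1e-9)
        alt = percent_parasitism(self.make(515, 1565), denominator="miner_adults_only")
        assert alt == pytest.approx(100 * 515 / 1565, abs=1e-9)

    def test_record_order_irrelevant_and_bounded(self):
        df = self.make(5, 15)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert percent_parasitism(shuffled) == percent_parasitism(df)
        assert 0.0 <= percent_parasitism(df) <= 100.0

    def test_no_emergences_is_undefined_not_zero(self):
        with pytest.raises(DomainError):
            percent_parasitism(self.make(0, 0))


class TestBumblebeeAbundance:
    def test_sums_only_flagged_rows(self):
        df = pd.DataFrame(
            [("p1", "b1", 3, True), ("p1", "b2", 4, True), ("p1", "h1", 9, False)],
            columns=["plot", "species", "count", "is_bumblebee"],
        )
        assert bumblebee_abundance(df) == 7
        assert bumblebee_abundance(df.iloc[:0]) == 0


class TestMeanDryMatter:
    @pytest.mark.parametrize(
        "yields, expected",
        [({2011: 400}, 400), ({2011: 400, 2012: 600}, 500),
         ({2011: 380, 2012: 420, 2013: 510, 2014: 450}, 440)],
    )
    def test_arithmetic_mean_over_years(self, yields, expected):
        assert mean_dry_matter(yields) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            mean_dry_matter({})


class TestAssembleMatrix:
    def test_default_dataset_shape_and_completeness(self, default_dataset, default_matrix):
        assert default_matrix.shape == (24, 15)
        assert list(default_matrix.columns[3:]) == list(INDICATORS)
        assert not default_matrix.isna().any().any()

    def test_missing_rearing_records_name_plot(self, default_dataset):
        tables = default_dataset.tables().copy()
        tables["rearing"] = tables["rearing"][tables["rearing"]["plot"] != "p01"]
        with pytest.raises(MeadowTradeError, match="p01.*parasitism"):
            assemble_indicator_matrix(tables)

    def test_noise_free_generation_is_recovered_exactly(self):
        ds = mt.generate_dataset(mt.DesignSpec(seed=11), mt.EffectSpec().noise_free())
        re = assemble_indicator_matrix(ds.tables())
        np.testing.assert_allclose(
            re[list(INDICATORS)].to_numpy(),
            ds.truth_indicators[list(INDICATORS)].to_numpy(),
            rtol=0, atol=1e-12,
        )
        # all noise off: every plot of a treatment carries identical values
        spread = re.groupby("treatment")[list(INDICATORS)].std(ddof=0)
        assert float(spread.max().max()) == 0.0


class TestCorrelationScreen:
    def test_duplicated_column_flagged_at_r_one(self, default_matrix):
        m = default_matrix.copy()
        m["ash"] = m["crude_protein"]
        flagged = correlation_screen(m)
        pairs = set(map(tuple, flagged[["indicator_a", "indicator_b"]].to_numpy()))
        assert ("ash", "crude_protein") in pairs or ("crude_protein", "ash") in pairs
        row = flagged[flagged["pearson_r"].abs() >= 1 - 1e-12]
        assert len(row) >= 1

    def test_threshold_zero_flags_all_66_pairs(self, default_matrix):
        assert len(correlation_screen(default_matrix, threshold=0.0)) == 66

    def test_independent_noise_typically_passes(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(24, 12)), columns=INDICATORS)
        m.insert(0, "plot", [f"p{i}" for i in range(24)])
        m.insert(1, "block", "B1")
        m.insert(2, "treatment", "A")
        assert len(correlation_screen(m)) == 0

    def test_constant_column_skipped_with_warning(self, default_matrix, caplog):
        m = default_matrix.copy()
        m["ash"] = 5.0
        with caplog.at_level("WARNING"):
            flagged = correlation_screen(m, threshold=0.0)
        assert "constant" in caplog.text
        assert len(flagged) == 55  # 11 choose 2
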