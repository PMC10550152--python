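"""Tests for block-constrained randomization inference."""

import numpy as np
import pandas as pd
import pytest

import meadowtrade as mt
from meadowtrade.errors import DomainError, MeadowTradeError
from meadowtrade.indicators import INDICATORS
from meadowtrade.randomization import (
    PermutationConfig,
    composite_test,
    exact_enumeration_test,
    group_average_test,
    pairwise_indicator_test,
    permute_within_blocks,
    run_full_contrast_table,
)


class TestPermuteWithinBlocks:
    def test_per_block_treatment_multisets_conserved(self):
        reg = mt.DesignSpec(seed=0).plot_registry()
        rng = np.random.default_rng(0)
        for _ in range(200):
            permuted = permute_within_blocks(reg, rng)
            for block, idx in reg.groupby("block").groups.items():
                assert sorted(permuted.loc[idx]) == sorted(reg.loc[idx, "treatment"])

    def test_single_plot_blocks_unchanged(self):
        reg = pd.DataFrame(
            {"plot": ["p1", "p2"], "block": ["B1", "B2"], "treatment": ["A", "B"]}
        )
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert permute_within_blocks(reg, rng).tolist() == ["A", "B"]

    def test_two_by_two_block_arrangements_uniform(self):
        # one block, treatments A,A,B,B: 6 distinct assignments, each ~1/6
        reg = pd.DataFrame(
            {"plot": list("pqrs"), "block": "B1", "treatment": ["A", "A", "B", "B"]}
        )
        rng = np.random.default_rng(2)
        seen = {}
        n = 6000
        for _ in range(n):
            key = tuple(permute_within_blocks(reg, rng))
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 6
        freqs = np.array(list(seen.values())) / n
        assert np.all(np.abs(freqs - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / n))


class TestPairwiseIndicatorTest:
    def test_self_contrast_centers_at_half(self, default_matrix):
        cfg = PermutationConfig(n_randomizations=2000, seed=3, tie_rule="half_ties")
        r = pairwise_indicator_test(default_matrix, "ash", "FYM", "FYM", cfg)
        assert r.observed == 0.0
        assert r.p_greater == pytest.approx(0.5, abs=0.05)

    def test_constant_indicator_resolved_by_tie_rule(self, default_matrix):
        m = default_matrix.copy()
        m["ash"] = 1.0
        exceed = pairwise_indicator_test(
            m, "ash", "FYM", "NoFert", PermutationConfig(n_randomizations=100, seed=0)
        )
        assert exceed.p_greater == 1.0  # all null values tie and count as exceeded
        half = pairwise_indicator_test(
            m, "ash", "FYM", "NoFert",
            PermutationConfig(n_randomizations=100, seed=0, tie_rule="half_ties"),
        )
        assert half.p_greater == 0.5

    def test_unknown_labels_raise(self, default_matrix):
        with pytest.raises(MeadowTradeError):
            pairwise_indicator_test(default_matrix, "ash", "FYM", "nope")
        with pytest.raises(MeadowTradeError):
            pairwise_indicator_test(default_matrix, "nope", "FYM", "NPK")

    def test_seed_determinism(self, default_matrix):
        cfg = PermutationConfig(n_randomizations=500, seed=11)
        a = pairwise_indicator_test(default_matrix, "crude_protein", "FYM", "NoFert", cfg)
        b = pairwise_indicator_test(default_matrix, "crude_protein", "FYM", "NoFert", cfg)
        assert a.p_greater == b.p_greater
        np.testing.assert_array_equal(a.null_sample, b.null_sample)

    def test_complementarity_under_half_ties(self, default_matrix):
        cfg = PermutationConfig(n_randomizations=1000, seed=5, tie_rule="half_ties")
        ab = pairwise_indicator_test(default_matrix, "ash", "FYM", "NPK", cfg)
        ba = pairwise_indicator_test(default_matrix, "ash", "NPK", "FYM", cfg)
        assert ab.p_greater + ba.p_greater == pytest.approx(1.0, abs=1e-12)


class TestExactEnumeration:
    def test_single_block_two_by_two_has_six_splits(self):
        reg = pd.DataFrame(
            {"plot": list("pqrs"), "block": "B1", "treatment": ["A", "A", "B", "B"]}
        )
        reg["diversity_plants"] = [1.0, 2.0, 10.0, 20.0]
        r = exact_enumeration_test(reg, "diversity_plants", "A", "B")
        assert r.n_arrangements == 6

    def test_symmetric_data_gives_half_under_half_ties(self):
        reg = pd.DataFrame(
            {"plot": list("pqrs"), "block": "B1", "treatment": ["A", "A", "B", "B"]}
        )
        reg["diversity_plants"] = [1.0, 4.0, 1.0, 4.0]  # A and B identical
        r = exact_enumeration_test(reg, "diversity_plants", "A", "B", tie_rule="half_ties")
        assert r.p_greater == pytest.approx(0.5, abs=1e-12)

    def test_monte_carlo_converges_to_enumeration(self, tiny_matrix):
        exact = exact_enumeration_test(
            tiny_matrix, "diversity_plants", "A", "B", tie_rule="half_ties"
        )
        assert exact.n_arrangements == 36
        last_err = None
        for n_rand in (1000, 10_000, 100_000):
            mc = pairwise_indicator_test(
                tiny_matrix, "diversity_plants", "A", "B",
                PermutationConfig(n_randomizations=n_rand, seed=21, tie_rule="half_ties"),
            )
            se = np.sqrt(exact.p_greater * (1 - exact.p_greater) / n_rand)
            err = abs(mc.p_greater - exact.p_greater)
            assert err <= 4 * se
            last_err = err
        assert last_err <= 0.01

    def test_oversized_design_refused(self):
        reg = mt.DesignSpec(seed=0).plot_registry()
        rng = np.random.default_rng(0)
        reg["ash"] = rng.normal(size=len(reg))
        with pytest.raises(DomainError, match="Monte"):
            exact_enumeration_test(reg, "ash", "FYM", "NPK", max_arrangements=100)


class TestGroupAndCompositeTests:
    def test_single_indicator_group_reduces_to_pairwise(self, default_matrix):
        # a synthetic one-member group: compare via a matrix holding only ash
        sub = default_matrix[["plot", "block", "treatment", "ash"]]
        cfg = PermutationConfig(n_randomizations=800, seed=9)
        pw = pairwise_indicator_test(sub, "ash", "FYM", "NPK", cfg)
        grp = group_average_test(sub, "forage", "FYM", "NPK", cfg)
        assert grp.p_greater == pw.p_greater
        assert grp.observed == pytest.approx(pw.observed, abs=1e-12)

    def test_targeted_forage_effect_detected_only_in_forage_group(self):
        eff = mt.EffectSpec().zero_treatment_effects()
        shift = {k: 4 * eff.residual_sd[k] for k in
                 ("ash", "crude_protein", "metabolizable_energy", "mean_dry_matter")}
        ds = mt.generate_dataset(mt.DesignSpec(seed=17), eff.with_effect("FYM", shift))
        cfg = PermutationConfig(n_randomizations=2000, seed=1)
        m = ds.truth_indicators
        forage = group_average_test(m, "forage", "FYM", "NoFert", cfg)
        assert forage.p_greater > 0.95
        plant = group_average_test(m, "plant", "FYM", "NoFert", cfg)
        insect = group_average_test(m, "insect", "FYM", "NoFert", cfg)
        assert 0.02 < plant.p_greater < 0.98
        assert 0.02 < insect.p_greater < 0.98

    def test_composite_dominant_treatment_rejects(self):
        eff = mt.EffectSpec().zero_treatment_effects()
        boost = {k: 3 * max(eff.residual_sd[k], 1e-6) for k in INDICATORS}
        ds = mt.generate_dataset(mt.DesignSpec(seed=23), eff.with_effect("NPK", boost))
        rescaled = mt.standardize_and_rescale(ds.truth_indicators)
        r = composite_test(rescaled, None, "NPK", "NoFert", "weighted_mean",
                           PermutationConfig(n_randomizations=2000, seed=2))
        assert r.p_greater > 0.95

    def test_weighted_sd_result_notes_direction(self, default_matrix):
        rescaled = mt.standardize_and_rescale(default_matrix)
        r = composite_test(rescaled, None, "FYM", "NoFert", "weighted_sd",
                           PermutationConfig(n_randomizations=200, seed=0))
        assert "lower" in r.note


@pytest.fixture(scope="module")
def table(default_matrix):
    cfg = PermutationConfig(n_randomizations=1500, seed=42, tie_rule="half_ties")
    return run_full_contrast_table(default_matrix, config=cfg)


class TestFullContrastTable:
    def test_dimensions_12_pairs_by_17_statistics(self, table):
        assert len(table) == 12 * 17
        assert table["statistic"].nunique() == 17

    def test_ordered_pair_probabilities_complement(self, table):
        idx = table.set_index(["first_treatment", "second_treatment", "statistic"])
        for (a, b, s), row in idx.iterrows():
            mirror = idx.loc[(b, a, s)]
            assert row["p_greater"] + mirror["p_greater"] == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self, default_matrix, table):
        cfg = PermutationConfig(n_randomizations=1500, seed=42, tie_rule="half_ties")
        again = run_full_contrast_table(default_matrix, config=cfg)
        pd.testing.assert_frame_equal(table, again)

    def test_significance_flags_match_tail_rule(self, table):
        sig = (table["p_greater"] < 0.05) | (table["p_greater"] > 0.95)
        assert (table["significant"] == sig).all()
        assert (table.loc[table["significant"], "stars"] == "*").all()
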