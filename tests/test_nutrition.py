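"""Nutrient scoring: content scores, intake scores, discrepancy, pools."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fkgm import nutrition as nut


def oracle_nds(user_nis, recipe_ncs):
    """Independent term-by-term evaluation with the math module."""
    sp = lambda x: math.log(1.0 + math.exp(x - 4.0))
    return sum(sp(a) * sp(b) for a, b in zip(user_nis, recipe_ncs))


class TestNCS:
    @pytest.mark.parametrize(
        "content,nutrient,expected",
        [
            (2.81, "sodium", 40.14),
            (19.97, "fat", 9.51),
            (12.16, "sugar", 4.50),
            (23.58, "fat", 11.23),
            (23.62, "fat", 11.25),
            (5.68, "saturated_fat", 9.47),
            (26.46, "sugar", 9.80),
            (0.0, "sodium", 0.0),
        ],
    )
    def test_worked_examples(self, content, nutrient, expected):
        assert round(nut.ncs(content, nutrient), 2) == expected

    def test_unknown_nutrient_and_negative_content(self):
        with pytest.raises(KeyError):
            nut.ncs(1.0, "fiber")
        with pytest.raises(ValueError):
            nut.ncs(-0.1, "fat")

    def test_vector_matches_scalar(self):
        row = {"sodium": 2.81, "fat": 19.97, "sugar": 12.16, "saturated_fat": 7.11}
        vec = nut.ncs_vector(row)
        assert np.allclose(vec, [nut.ncs(row[k], k) for k in nut.NUTRIENTS])
        assert np.allclose(nut.ncs_vector([0, 0, 0, 0]), 0.0)

    @given(st.floats(0, 100), st.floats(0.01, 10))
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, content, scale):
        assert nut.ncs(scale * content, "fat") == pytest.approx(
            scale * nut.ncs(content, "fat"), rel=1e-12, abs=1e-9
        )


class TestBands:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, "healthy"),
            (3.999, "healthy"),
            (4.0, "moderate"),
            (9.999, "moderate"),
            (10.0, "unhealthy"),
            (40.14, "unhealthy"),
        ],
    )
    def test_half_open_intervals(self, score, expected):
        assert nut.band(score) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nut.band(-0.001)

    @given(st.floats(0, 1e6, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_partition_covers_all_scores(self, score):
        assert nut.band(score) in {"healthy", "moderate", "unhealthy"}


class TestNIS:
    def test_grouped_weighted_average(self):
        # bands: {2,3} healthy, {5,9} moderate, {12,20} unhealthy
        # (2*2.5 + 2*7 + 2*16) / 6 = 8.5
        assert nut.nis([2, 3, 5, 9, 12, 20]) == pytest.approx(8.5)

    def test_single_band_collapses_to_median(self):
        assert nut.nis([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_single_score_is_identity(self):
        assert nut.nis([7.3]) == pytest.approx(7.3)

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            nut.nis([])

    @given(
        st.lists(st.floats(0, 50, allow_nan=False, allow_infinity=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_history_extremes(self, history):
        value = nut.nis(history)
        assert min(history) - 1e-9 <= value <= max(history) + 1e-9

    def test_table_users_cold_start_imputation(self, toy_bundle):
        ncs_t = nut.ncs_table(toy_bundle.nutrients)
        histories = dict(toy_bundle.train)
        histories[99] = []
        with pytest.raises(ValueError):
            nut.nis_table(histories, ncs_t)
        filled = nut.nis_table(histories, ncs_t, fill_empty="population_mean")
        warm = filled.drop(index=99)
        assert np.allclose(filled.loc[99], warm.mean(axis=0))


class TestSoftplusMod:
    def test_anchor_values(self):
        assert nut.softplus_mod(4.0) == pytest.approx(math.log(2.0))
        assert nut.softplus_mod(10.0) == pytest.approx(math.log(1 + math.e**6))
        assert float(nut.softplus_mod(10.0)) ** 2 == pytest.approx(36.0, abs=0.05)

    def test_asymptote_positive_not_underflowing(self):
        val = float(nut.softplus_mod(-20.0))
        assert 0 < val < 1e-9
        assert val == pytest.approx(math.exp(-24.0), rel=1e-6)

    def test_overflow_safe_and_increasing(self):
        xs = np.array([-1e3, 0.0, 4.0, 10.0, 1e3])
        ys = nut.softplus_mod(xs)
        assert np.all(np.isfinite(ys)) and np.all(np.diff(ys) > 0)
        assert ys[-1] == pytest.approx(1e3 - 4.0)


class TestNDS:
    def test_single_nutrient_anchor_near_36(self):
        value = nut.nds([10, 0, 0, 0], [10, 0, 0, 0])
        assert value == pytest.approx(36.03, abs=0.01)

    def test_healthy_pair_is_tiny(self):
        assert nut.nds([0, 0, 0, 0], [0, 0, 0, 0]) <= 4 * math.log(1 + math.exp(-4.0)) ** 2

    @pytest.mark.parametrize(
        "user,recipe,frozen",
        [
            # worked-example score vectors; oracle values frozen from
            # term-by-term evaluation (oracle_nds) of the defining equations
            ((5.11, 12.33, 3.03, 6.40), (10.90, 11.25, 0.09, 9.47), 83.64583544120681),
            ((5.11, 12.33, 3.03, 6.40), (4.63, 5.80, 11.38, 5.51), 24.366830135555062),
            ((10.39, 4.50, 13.14, 6.24), (10.90, 11.25, 0.09, 9.47), 64.16912680078441),
            ((10.39, 4.50, 13.14, 6.24), (4.63, 5.80, 11.38, 5.51), 80.12023523996854),
        ],
    )
    def test_worked_pairs_pinned_to_oracle(self, user, recipe, frozen):
        assert oracle_nds(user, recipe) == pytest.approx(frozen, rel=1e-12)
        assert nut.nds(user, recipe) == pytest.approx(frozen, rel=1e-12)

    def test_missing_nutrient_raises(self):
        with pytest.raises(KeyError):
            nut.nds({"sodium": 1, "fat": 2, "sugar": 3}, {k: 0 for k in nut.NUTRIENTS})

    @given(
        st.lists(st.floats(0, 40), min_size=4, max_size=4),
        st.lists(st.floats(0, 40), min_size=4, max_size=4),
        st.integers(0, 3),
        st.floats(0.01, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_positive_and_componentwise_monotone(self, u, r, idx, bump):
        base = nut.nds(u, r)
        assert base > 0
        u2 = list(u)
        u2[idx] += bump
        assert nut.nds(u2, r) >= base

    def test_matrix_matches_pairwise(self, toy_bundle):
        ncs_t = nut.ncs_table(toy_bundle.nutrients)
        nis_t = nut.nis_table(toy_bundle.train, ncs_t)
        mat = nut.nds_matrix(nis_t, ncs_t)
        for u in nis_t.index[:3]:
            for rp in ncs_t.index[:4]:
                assert mat.at[u, rp] == pytest.approx(
                    nut.nds(nis_t.loc[u].to_dict(), ncs_t.loc[rp].to_dict())
                )


class TestHealthPools:
    def test_membership_matches_exhaustive_oracle(self, toy_bundle):
        ncs_t = nut.ncs_table(toy_bundle.nutrients)
        nis_t = nut.nis_table(toy_bundle.train, ncs_t)
        pools = nut.build_health_pools(nis_t, ncs_t)
        for u in nis_t.index:
            for rp in ncs_t.index:
                value = nut.nds(nis_t.loc[u].to_dict(), ncs_t.loc[rp].to_dict())
                if value >= pools.cutoff:
                    assert rp in pools.negative[u] and rp not in pools.positive[u]
                else:
                    assert rp in pools.positive[u] and rp not in pools.negative[u]

    def test_cutoff_is_inclusive_on_negative_side(self):
        nis_t = pd.DataFrame([[10.0, 0, 0, 0]], index=[0], columns=list(nut.NUTRIENTS))
        # craft one recipe whose NDS is exactly the cutoff
        sp_u = float(nut.softplus_mod(10.0))
        base = float(np.sum(nut.softplus_mod(np.array([0.0, 0.0, 0.0])) * nut.softplus_mod(0.0)))
        target = (36.0 - base) / sp_u  # softplus_mod(ncs_0) needed
        ncs_needed = 4.0 + math.log(math.expm1(target))
        content = ncs_needed * nut.DEFAULT_THRESHOLDS["sodium"] / 10.0
        ncs_t = nut.ncs_table(
            pd.DataFrame([[content, 0, 0, 0]], index=[7], columns=list(nut.NUTRIENTS))
        )
        pools = nut.build_health_pools(nis_t, ncs_t, cutoff=36.0)
        assert nut.nds(nis_t.loc[0].to_dict(), ncs_t.loc[7].to_dict()) == pytest.approx(36.0)
        assert 7 in pools.negative[0]

    def test_all_healthy_world_has_empty_negatives(self):
        nis_t = pd.DataFrame([[1.0, 1, 1, 1]], index=[0], columns=list(nut.NUTRIENTS))
        ncs_t = pd.DataFrame([[2.0, 2, 2, 2]], index=[0], columns=list(nut.NUTRIENTS))
        pools = nut.build_health_pools(nis_t, ncs_t)
        assert pools.negative[0].size == 0 and pools.positive[0].size == 1

    def test_separation_invariant(self, toy_bundle):
        ncs_t = nut.ncs_table(toy_bundle.nutrients)
        nis_t = nut.nis_table(toy_bundle.train, ncs_t)
        pools = nut.build_health_pools(nis_t, ncs_t)
        mat = nut.nds_matrix(nis_t, ncs_t)
        for u in nis_t.index:
            pos, neg = pools.positive[u], pools.negative[u]
            if pos.size and neg.size:
                assert mat.loc[u, pos].max() < pools.cutoff <= mat.loc[u, neg].min()

    def test_json_round_trip(self, toy_bundle, tmp_path):
        ncs_t = nut.ncs_table(toy_bundle.nutrients)
        nis_t = nut.nis_table(toy_bundle.train, ncs_t)
        pools = nut.build_health_pools(nis_t, ncs_t)
        pools.to_json(tmp_path / "pools.json")
        back = nut.HealthPools.from_json(tmp_path / "pools.json")
        assert back.cutoff == pools.cutoff
        for u in pools.positive:
            assert np.array_equal(back.positive[u], pools.positive[u])
            assert np.array_equal(back.negative[u], pools.negative[u])


class TestNutrientTableIO:
    def test_round_trip(self, toy_bundle, tmp_path):
        nut.write_nutrients(toy_bundle.nutrients, tmp_path / "n.csv")
        back = nut.read_nutrients(tmp_path / "n.csv")
        pd.testing.assert_frame_equal(back, toy_bundle.nutrients, check_names=False)

    def test_salt_column_converted_to_sodium(self, tmp_path):
        path = tmp_path / "n.csv"
        path.write_text(
            "recipe_id,sodium,fat,sugar,saturated_fat,salt\n0,0.1,1.0,2.0,0.5,1.0\n"
        )
        df = nut.read_nutrients(path)
        assert df.at[0, "sodium"] == pytest.approx(0.1 + nut.SALT_TO_SODIUM)
        assert "salt" not in df.columns

    def test_negative_content_rejected(self, tmp_path):
        path = tmp_path / "n.csv"
        path.write_text("recipe_id,sodium,fat,sugar,saturated_fat\n0,-1,1,1,1\n")
        with pytest.raises(ValueError):
            nut.read_nutrients(path)
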