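"""Scale scoring, reliability and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelnet.scoring import (ScoringError, describe_by_group,
                              mcdonalds_omega, omega_from_cov,
                              pearson_matrix, recode_ctspc, reverse_code,
                              score_composite, score_items,
                              split_half_spearman_brown)


class TestRecode:
    @pytest.mark.parametrize("raw,expected", [
        (0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 6),
        (7, 0), (8, 0),
    ])
    def test_exhaustive_domain(self, raw, expected):
        assert recode_ctspc(raw) == expected

    @pytest.mark.parametrize("bad", [-1, 9, 3.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ScoringError):
            recode_ctspc(bad)


class TestReverseCode:
    @pytest.mark.parametrize("score,lo,hi,expected", [
        (1, 1, 4, 4),       # 4-point stress scale, strongly agree -> 4
        (2.5, 1, 4, 2.5),   # midpoint fixed point
        (0, 0, 6, 6),       # endpoint swap on the frequency scale
    ])
    def test_examples(self, score, lo, hi, expected):
        assert reverse_code(score, lo, hi) == expected

    @given(st.floats(0, 6, allow_nan=False))
    def test_involution(self, x):
        assert reverse_code(reverse_code(x, 0, 6), 0, 6) == pytest.approx(x)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ScoringError):
            reverse_code(5, 0, 4)


class TestComposite:
    def test_mean_and_missing_rule(self):
        assert score_composite([0, 1, 2], 3) == 1.0
        assert score_composite([2, 2, 2], 3) == 2.0
        # 2 of 3 present < min_items -> missing (oracle: count non-missing)
        assert np.isnan(score_composite([1, np.nan, 2], 3))
        assert score_composite([1, np.nan, 2], 2) == 1.5

    def test_empty_is_missing(self):
        assert np.isnan(score_composite([], 1))

    @given(st.lists(st.floats(0, 6, allow_nan=False), min_size=1,
                    max_size=8), st.randoms(use_true_random=False))
    def test_permutation_invariant_and_bounded(self, items, rnd):
        a = score_composite(items, 1)
        shuffled = list(items)
        rnd.shuffle(shuffled)
        assert score_composite(shuffled, 1) == pytest.approx(a)
        assert min(items) - 1e-12 <= a <= max(items) + 1e-12


class TestOmega:
    def test_closed_form_recovery(self):
        # items x_j = 0.7 f + e, theta = 0.51: omega =
        # (3*0.7)^2 / ((3*0.7)^2 + 3*0.51) = 4.41/5.94 = 0.7424
        rng = np.random.default_rng(42)
        n = 20000
        f = rng.normal(size=n)
        X = 0.7 * f[:, None] + np.sqrt(0.51) * rng.normal(size=(n, 3))
        res = mcdonalds_omega(X)
        assert res.converged
        assert res.omega == pytest.approx(4.41 / 5.94, abs=0.02)

    def test_item_reordering_invariance(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=500)
        X = np.array([0.8, 0.6, 0.5, 0.7]) * f[:, None] \
            + rng.normal(size=(500, 4)) * 0.6
        a = mcdonalds_omega(X).omega
        b = mcdonalds_omega(X[:, [2, 0, 3, 1]]).omega
        assert a == pytest.approx(b, abs=1e-6)

    def test_identical_columns_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        with pytest.warns(UserWarning, match="Heywood"):
            res = mcdonalds_omega(np.column_stack([x, x, x]))
        assert res.omega > 0.999
        assert res.heywood

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 4))
        assert abs(mcdonalds_omega(X).omega) < 0.03

    def test_tau_equivalent_equals_alpha_at_population(self):
        # equal loadings: omega == Cronbach's alpha, computed independently
        lam = np.full(4, 0.6)
        S = np.outer(lam, lam) + np.diag(1 - lam**2)
        p = 4
        alpha = p / (p - 1) * (1 - np.trace(S) / S.sum())
        assert omega_from_cov(S).omega == pytest.approx(alpha, abs=1e-6)

    def test_too_few_items_rejected(self):
        with pytest.raises(ScoringError):
            mcdonalds_omega(np.zeros((100, 2)) + np.arange(100)[:, None])


class TestSplitHalf:
    def test_limits(self):
        x = np.arange(20.0)
        assert split_half_spearman_brown(x, x) == pytest.approx(1.0)
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 50000))
        assert split_half_spearman_brown(a, b) == pytest.approx(0.0,
                                                                abs=0.02)

    def test_reported_value_from_population_r(self):
        # 2r/(1+r) = 0.55 at r = 0.3793
        r = 0.3793
        rng = np.random.default_rng(6)
        z = rng.normal(size=50000)
        a = np.sqrt(r) * z + np.sqrt(1 - r) * rng.normal(size=50000)
        b = np.sqrt(r) * z + np.sqrt(1 - r) * rng.normal(size=50000)
        assert split_half_spearman_brown(a, b) == pytest.approx(0.55,
                                                                abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ScoringError):
            split_half_spearman_brown(np.ones(20), np.arange(20.0))


def _score_frame(groups_values, variable="irr", wave=3):
    rows = []
    for g, vals in groups_values.items():
        for i, v in enumerate(vals):
            rows.append({"person_id": f"{g}{i}", "group": g, "wave": wave,
                         variable: v})
    return pd.DataFrame(rows)


class TestDescribeByGroup:
    def test_identical_groups(self):
        d = describe_by_group(
            _score_frame({"G1": [1, 2, 3], "G2": [1, 2, 3]}), "irr", 3)
        assert d["F"] == pytest.approx(0.0)
        assert d["p"] == pytest.approx(1.0)

    def test_degenerate_separation_flagged(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            d = describe_by_group(
                _score_frame({"G1": [0, 0, 0], "G2": [1, 1, 1]}), "irr", 3)
        assert d["zero_within_variance"]
        assert d["p"] == 0.0

    def test_brute_force_sum_of_squares(self):
        groups = {"G1": [1.0, 2.0], "G2": [2.0, 3.0], "G3": [3.0, 4.0]}
        d = describe_by_group(_score_frame(groups), "irr", 3)
        allv = np.concatenate(list(groups.values()))
        gm = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - gm) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                  for v in groups.values())
        F = (ssb / 2) / (ssw / 3)
        assert d["F"] == pytest.approx(F, abs=1e-10)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 30))
        from scipy.stats import ttest_ind
        d = describe_by_group(
            _score_frame({"G1": a.tolist(), "G2": b.tolist()}), "irr", 3)
        t = ttest_ind(a, b).statistic
        assert d["F"] == pytest.approx(t**2, abs=1e-10)

    def test_small_group_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            d = describe_by_group(
                _score_frame({"G1": [1, 2, 3], "G2": [1, 3], "G3": [2]}),
                "irr", 3)
        assert len(d["groups"]) == 2


class TestPearsonMatrix:
    def test_unit_diagonal_and_brute_force(self):
        df = pd.DataFrame({
            "person_id": range(5), "group": "G1", "wave": 3,
            "x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 6],
        })
        R = pearson_matrix(df, 3, ["x", "y"])
        assert R.loc["x", "x"] == 1.0
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum())
        assert R.loc["x", "y"] == pytest.approx(num / den)
        assert np.allclose(R.values, R.values.T)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"person_id": range(10000), "group": "G1",
                           "wave": 3, "x": rng.normal(size=10000),
                           "y": rng.normal(size=10000)})
        assert abs(pearson_matrix(df, 3, ["x", "y"]).loc["x", "y"]) < 0.03

    def test_constant_flagged(self):
        df = pd.DataFrame({"person_id": range(6), "group": "G1", "wave": 3,
                           "x": 1.0, "y": [1.0, 2, 3, 4, 5, 6]})
        with pytest.warns(UserWarning, match="undefined"):
            R = pearson_matrix(df, 3, ["x", "y"])
        assert np.isnan(R.loc["x", "y"])


class TestScoreItems:
    def test_roundtrip_from_generator(self):
        from panelnet.synthetic import generate_study
        panel = generate_study("shared", {"G1": 80, "G2": 60, "G3": 60},
                               seed=3, items=True, missingness=False)
        scored = score_items(panel.items)
        merged = scored.merge(panel.scores, on=["person_id", "wave"],
                              suffixes=("_i", "_c"))
        # item-derived composites correlate strongly with the continuous
        # composites they measure (attenuated by Likert measurement error)
        for v in ("irr", "pstr", "phyAs"):
            r = np.corrcoef(merged[f"{v}_i"], merged[f"{v}_c"])[0, 1]
            assert r > 0.6, v
        # composite bounds respected
        assert scored["irr"].dropna().between(0, 2).all()
        assert scored["pstr"].dropna().between(1, 4).all()
        assert scored["nVio"].dropna().between(0, 6).all()
        # cultural variables constant across waves per person
        g = scored.groupby("person_id")["cAtt"].nunique()
        assert (g <= 1).all()

    def test_duplicate_records_rejected(self):
        items = pd.DataFrame({
            "person_id": ["a", "a"], "group": "G1", "wave": [3, 3],
            "instrument": "CBCL_IRR", "item_id": ["irr_1", "irr_1"],
            "raw_code": [1, 2]})
        with pytest.raises(ScoringError, match="duplicate"):
            score_items(items)


class TestWideItems:
    def test_wide_round_trip_matches_long(self):
        from panelnet.scoring import items_from_wide
        from panelnet.synthetic import generate_study
        panel = generate_study("shared", {"G1": 60, "G2": 60, "G3": 60},
                               seed=12, items=True, missingness=False)
        long = panel.items
        wide = long.assign(
            col=long["instrument"] + "." + long["item_id"] + "."
            + long["wave"].astype(str)).pivot_table(
            index=["person_id", "group"], columns="col",
            values="raw_code", aggfunc="first").reset_index()
        back = items_from_wide(wide)
        a = score_items(long).set_index(["person_id", "wave"]).sort_index()
        b = score_items(back).set_index(["person_id", "wave"]).sort_index()
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_bad_column_name_rejected(self):
        from panelnet.scoring import items_from_wide
        df = pd.DataFrame({"person_id": ["a"], "group": ["G1"],
                           "CTSPC.x": [1.0]})
        with pytest.raises(ScoringError, match="INSTRUMENT.item.wave"):
            items_from_wide(df)
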