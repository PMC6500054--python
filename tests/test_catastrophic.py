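"""Catastrophic health expenditure: flags, subsistence, incidence, strata."""

import numpy as np
import pandas as pd
import pytest

from finprotect.catastrophic import (
    CheConfig,
    CheFlagger,
    EstimationError,
    assign_quintiles,
    capacity_to_pay,
    che_flag,
    che_incidence,
    che_table,
    food_share,
    subsistence_spending,
)
from finprotect.datamodel import SurveyDataset

from conftest import make_frame

BS10 = CheConfig(method="budget_share", threshold=0.10)
CTP40 = CheConfig(method="capacity_to_pay", threshold=0.40)


def brute_force_subsistence(df: pd.DataFrame, lo: float, hi: float) -> float:
    """Independent oracle: sort by food share, walk cumulative weight to the
    band percentiles, average food spending of households inside the band."""
    shares = (df["food_expenditure"] / df["total_expenditure"]).to_numpy()
    w = df["weight"].to_numpy(float)
    order = np.argsort(shares, kind="stable")
    cum = np.cumsum(w[order])
    total = cum[-1]

    def pctl(p):
        for pos, c in enumerate(cum):
            if c >= p * total:
                return shares[order][pos]
        return shares[order][-1]

    v_lo, v_hi = pctl(lo), pctl(hi)
    sel = (shares >= v_lo) & (shares <= v_hi)
    return float(np.sum(df["food_expenditure"].to_numpy()[sel] * w[sel]) / np.sum(w[sel]))


class TestFoodShare:
    def test_direct_ratio(self):
        h = make_frame([dict(food_expenditure=300.0, total_expenditure=1000.0)]).iloc[0]
        assert food_share(h) == pytest.approx(0.30)

    @pytest.mark.parametrize("food,expected", [(0.0, 0.0), (1000.0, 1.0)])
    def test_boundaries(self, food, expected):
        h = make_frame([dict(food_expenditure=food, total_expenditure=1000.0)]).iloc[0]
        assert food_share(h) == expected

    def test_zero_total_is_undefined(self):
        h = make_frame([dict(food_expenditure=0.0, total_expenditure=0.0, oop_health=0.0)]).iloc[0]
        with pytest.raises(EstimationError):
            food_share(h)


class TestSubsistence:
    def test_eleven_household_band_selects_middle(self, eleven_band_survey):
        """Shares 0.10..0.20 with food 100..200: the 45-55% band centres on
        the 0.15-share household and the weighted mean is exactly 150."""
        assert subsistence_spending(eleven_band_survey) == pytest.approx(150.0)

    def test_matches_brute_force_scan(self, eleven_band_survey, synthetic_2012):
        for ds in (eleven_band_survey, synthetic_2012):
            expected = brute_force_subsistence(ds.frame, 0.45, 0.55)
            assert subsistence_spending(ds) == pytest.approx(expected, rel=1e-12)

    def test_constant_distribution(self):
        ds = SurveyDataset(make_frame([dict(food_expenditure=150.0) for _ in range(7)]))
        assert subsistence_spending(ds) == pytest.approx(150.0)

    def test_single_household(self):
        ds = SurveyDataset(make_frame([dict(food_expenditure=321.0)]))
        assert subsistence_spending(ds) == pytest.approx(321.0)

    def test_weights_shift_the_band(self):
        # heavy weight on the low-share households pulls the band down
        rows = [
            dict(weight=10.0, total_expenditure=1000.0, food_expenditure=100.0),
            dict(weight=1.0, total_expenditure=1000.0, food_expenditure=500.0),
            dict(weight=1.0, total_expenditure=1000.0, food_expenditure=600.0),
        ]
        ds = SurveyDataset(make_frame(rows))
        assert subsistence_spending(ds) == pytest.approx(100.0)

    def test_equivalence_scale_rescales(self, eleven_band_survey):
        cfg = CheConfig(method="capacity_to_pay", threshold=0.4, eq_scale_beta=0.56)
        se = subsistence_spending(eleven_band_survey, cfg)
        # sizes are all 1, so equivalisation is the identity here
        assert se == pytest.approx(150.0)


class TestCapacityToPay:
    def test_branch_food_at_least_subsistence(self):
        h = make_frame([dict(total_expenditure=1000.0, food_expenditure=300.0)]).iloc[0]
        assert capacity_to_pay(h, 250.0) == pytest.approx(750.0)

    def test_branch_food_below_subsistence(self):
        h = make_frame([dict(total_expenditure=1000.0, food_expenditure=200.0)]).iloc[0]
        assert capacity_to_pay(h, 250.0) == pytest.approx(800.0)

    def test_zero_subsistence_identity(self):
        h = make_frame([dict(total_expenditure=1000.0, food_expenditure=300.0)]).iloc[0]
        assert capacity_to_pay(h, 0.0) == pytest.approx(1000.0)

    def test_result_nonnegative_on_valid_data(self, synthetic_2012):
        se = subsistence_spending(synthetic_2012)
        for _, h in synthetic_2012.frame.head(50).iterrows():
            assert capacity_to_pay(h, se) >= 0.0

    def test_literal_branch_switch_swaps_branches(self):
        h = make_frame([dict(total_expenditure=1000.0, food_expenditure=200.0)]).iloc[0]
        assert capacity_to_pay(h, 250.0, literal=True) == pytest.approx(750.0)


class TestCheFlag:
    def test_exceedance(self):
        h = make_frame([dict(oop_health=120.0, total_expenditure=1000.0)]).iloc[0]
        assert che_flag(h, BS10) is True

    def test_strict_boundary_is_not_catastrophic(self):
        h = make_frame([dict(oop_health=100.0, total_expenditure=1000.0)]).iloc[0]
        assert che_flag(h, BS10) is False
        nonstrict = CheConfig(method="budget_share", threshold=0.10, strict=False)
        assert che_flag(h, nonstrict) is True

    @pytest.mark.parametrize("cfg", [BS10, CTP40, CheConfig(method="budget_share", threshold=0.25)])
    def test_zero_oop_never_catastrophic(self, cfg):
        h = make_frame([dict(oop_health=0.0)]).iloc[0]
        assert che_flag(h, cfg, se=100.0) is False

    def test_zero_denominator_with_positive_oop_is_catastrophic(self):
        # capacity to pay 0 (subsistence consumes everything), positive OOP
        h = make_frame([dict(total_expenditure=500.0, food_expenditure=500.0, oop_health=10.0)]).iloc[0]
        assert che_flag(h, CTP40, se=500.0) is True


class TestIncidence:
    def test_no_household_flagged(self, tiny_survey):
        cfg = CheConfig(method="budget_share", threshold=0.99)
        est = che_incidence(tiny_survey, cfg)
        assert est.proportion == 0.0
        assert (est.ci_low, est.ci_high) == (0.0, 0.0)

    def test_two_of_ten_wald_interval_unclamped(self, tiny_survey):
        est = che_incidence(tiny_survey, CheConfig(method="budget_share", threshold=0.30))
        assert est.proportion == pytest.approx(0.20)
        half = 1.959963984540054 * np.sqrt(0.2 * 0.8 / 10)
        assert est.ci_low == pytest.approx(0.2 - half)
        assert est.ci_high == pytest.approx(0.2 + half)
        assert est.ci_low < 0  # reporting convention: no clamping

    def test_weighted_mean_by_hand(self):
        rows = [
            dict(weight=3.0, oop_health=200.0, total_expenditure=1000.0),
            dict(weight=1.0, oop_health=0.0, total_expenditure=1000.0),
        ]
        est = che_incidence(SurveyDataset(make_frame(rows)), BS10)
        assert est.proportion == pytest.approx(0.75)

    def test_uniform_weights_equal_unweighted_proportion(self, synthetic_2012):
        est = che_incidence(synthetic_2012, BS10)
        flags = CheFlagger(method="budget_share", threshold=0.10).fit(synthetic_2012).transform(synthetic_2012)
        assert est.proportion == pytest.approx(flags.mean(), rel=1e-14)

    def test_threshold_monotonicity_within_method(self, synthetic_2012):
        for method in ("budget_share", "capacity_to_pay"):
            incid = [
                che_incidence(synthetic_2012, CheConfig(method=method, threshold=t)).proportion
                for t in (0.05, 0.10, 0.25, 0.40, 0.60)
            ]
            assert all(a >= b for a, b in zip(incid, incid[1:]))

    def test_budget_share_at_tau_one(self):
        rows = [dict(oop_health=500.0, total_expenditure=1000.0) for _ in range(4)]
        rows.append(dict(oop_health=1000.0, food_expenditure=0.0, total_expenditure=1000.0))
        ds = SurveyDataset(make_frame(rows))
        strict = CheConfig(method="budget_share", threshold=1.0)
        nonstrict = CheConfig(method="budget_share", threshold=1.0, strict=False)
        assert che_incidence(ds, strict).proportion == 0.0
        assert che_incidence(ds, nonstrict).proportion == pytest.approx(0.2)

    def test_scale_invariance(self, synthetic_2012):
        df = synthetic_2012.frame.copy()
        scaled = df.copy()
        for c in ("total_expenditure", "food_expenditure", "oop_health"):
            scaled[c] = scaled[c] * 1000.0
        for cfg in (BS10, CTP40):
            a = che_incidence(df, cfg).proportion
            b = che_incidence(scaled, cfg).proportion
            assert a == pytest.approx(b, rel=1e-12)
        pd.testing.assert_series_equal(assign_quintiles(df), assign_quintiles(scaled))

    def test_person_weighting_reweights_by_size(self):
        rows = [
            dict(household_size=5, oop_health=200.0, total_expenditure=1000.0),
            dict(household_size=1, oop_health=0.0, total_expenditure=1000.0),
        ]
        ds = SurveyDataset(make_frame(rows))
        est = che_incidence(ds, BS10, person_weighted=True)
        assert est.proportion == pytest.approx(5 / 6)


class TestQuintiles:
    def test_ten_distinct_households_two_per_quintile(self, tiny_survey):
        q = assign_quintiles(tiny_survey)
        assert sorted(q) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_identical_fall_in_quintile_one(self):
        ds = SurveyDataset(make_frame([{} for _ in range(8)]))
        assert (assign_quintiles(ds) == 1).all()

    def test_weighted_boundaries_match_brute_force(self):
        rng = np.random.default_rng(3)
        rows = [
            dict(
                weight=float(rng.integers(1, 6)),
                total_expenditure=float(rng.uniform(500, 5000)),
                food_expenditure=100.0,
                household_size=int(rng.integers(1, 5)),
            )
            for _ in range(40)
        ]
        df = make_frame(rows)
        got = assign_quintiles(df)
        # brute force: cumulative-weight walk in sorted per-capita order
        pc = (df["total_expenditure"] / df["household_size"]).to_numpy()
        w = df["weight"].to_numpy(float)
        order = np.argsort(pc, kind="stable")
        total = w.sum()
        cum = 0.0
        expected = np.empty(len(df), dtype=int)
        for pos in order:
            cum += w[pos]
            expected[pos] = min(5, max(1, int(np.ceil(5 * cum / total))))
        # tie rule: equal per-capita values share the lowest label
        for val in np.unique(pc):
            mask = pc == val
            expected[mask] = expected[mask].min()
        assert (got.to_numpy() == expected).all()

    def test_quintile_shares_near_twenty_percent(self, synthetic_2012):
        df = synthetic_2012.frame
        q = assign_quintiles(df)
        shares = df.groupby(q)["weight"].sum() / df["weight"].sum()
        assert np.allclose(shares, 0.2, atol=1.0 / len(df) + 1e-12)


class TestCheTable:
    def test_total_row_equals_full_dataset_incidence(self, synthetic_2012):
        table = che_table(synthetic_2012, [BS10])
        total = table[(table.stratum == "total")].iloc[0]
        est = che_incidence(synthetic_2012, BS10)
        assert total.proportion == pytest.approx(est.proportion)
        assert total.ci_low == pytest.approx(est.ci_low)

    def test_entirely_rural_dataset_marks_urban_missing(self):
        ds = SurveyDataset(make_frame([dict(region="rural") for _ in range(6)]))
        table = che_table(ds, [BS10])
        urban = table[(table.stratum == "region") & (table.level == "urban")].iloc[0]
        assert np.isnan(urban.proportion)
        assert urban.n == 0

    def test_weighted_flag_counts_add_up_across_any_partition(self, synthetic_2012):
        """Accounting identity: stratum-weighted flagged totals sum to the
        overall weighted flagged total for each partition variable."""
        table = che_table(synthetic_2012, [BS10, CTP40])
        for cfg in (BS10, CTP40):
            sub = table[(table.method == cfg.method) & (table.threshold == cfg.threshold)]
            total_row = sub[sub.stratum == "total"].iloc[0]
            total_flagged = total_row.proportion * total_row.weighted_n
            for stratum in ("region", "gender", "quintile", "marital", "education", "occupation"):
                rows = sub[sub.stratum == stratum].dropna(subset=["proportion"])
                flagged = (rows.proportion * rows.weighted_n).sum()
                assert flagged == pytest.approx(total_flagged, rel=1e-9)

    def test_pipeline_flags_match_naive_loop(self, synthetic_2012):
        """Vectorised flags equal a per-household loop applying the rule."""
        df = synthetic_2012.frame
        se = subsistence_spending(df)
        for cfg, se_used in ((BS10, 0.0), (CTP40, se)):
            est = CheFlagger(**{k: getattr(cfg, k) for k in (
                "method", "threshold", "band", "strict", "eq_scale_beta")}).fit(df)
            fast = est.transform(df)
            slow = np.array([che_flag(h, cfg, se_used) for _, h in df.iterrows()])
            assert (fast == slow).all()
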