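"""Harmonization: medication adjustment, PP, winsorization, drinks, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gxebp.harmonize import (
    adjust_medication,
    build_slices,
    classify_exposure,
    compute_pp,
    drinking_category,
    exclude_very_heavy,
    standard_drinks,
    winsorize,
)
from gxebp.simulate import SimulationConfig, simulate_cohort


class TestMedicationAdjustment:
    def test_treated_offsets(self):
        sbp, dbp = adjust_medication(130.0, 80.0, 1)
        assert (sbp, dbp) == (145.0, 90.0)

    def test_untreated_identity(self):
        sbp, dbp = adjust_medication(130.0, 80.0, 0)
        assert (sbp, dbp) == (130.0, 80.0)

    def test_offset_is_zero_or_fifteen(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(130, 20, 50)
        med = rng.integers(0, 2, 50)
        sbp, _ = adjust_medication(raw, raw, med)
        offsets = sbp - raw
        assert np.all(np.isclose(offsets, 0.0) | np.isclose(offsets, 15.0))

    def test_missing_propagates(self):
        sbp, dbp = adjust_medication([np.nan], [80.0], [1])
        assert np.isnan(sbp[0]) and dbp[0] == 90.0


class TestPulsePressure:
    def test_examples(self):
        assert compute_pp(145.0, 90.0) == 55.0
        assert compute_pp(120.0, 120.0) == 0.0

    def test_identity(self):
        rng = np.random.default_rng(1)
        sbp = rng.normal(130, 15, 100)
        dbp = rng.normal(80, 10, 100)
        assert np.allclose(compute_pp(sbp, dbp) + dbp, sbp)


class TestWinsorize:
    def test_extreme_value_capped_at_six_sd(self):
        x = np.concatenate([np.random.default_rng(2).normal(0, 1, 500), [8.0]])
        out = winsorize(x)
        hi = x.mean() + 6 * x.std(ddof=1)
        assert out.max() == pytest.approx(hi)
        assert (out[:-1] == x[:-1]).all()

    def test_within_bounds_unchanged(self):
        x = np.linspace(-2, 2, 50)
        assert np.array_equal(winsorize(x), x)

    def test_symmetric_input_symmetric_output(self):
        x = np.concatenate([np.linspace(-1, 1, 20), [-9.0, 9.0]])
        out = winsorize(x)
        assert np.allclose(np.sort(out), -np.sort(-out)[::-1])

    def test_zero_variance_unchanged(self):
        x = np.full(10, 3.0)
        assert np.array_equal(winsorize(x), x)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_never_increases_distance_from_mean(self, values):
        x = np.asarray(values)
        out = winsorize(x)
        mean, sd = x.mean(), x.std(ddof=1)
        assert np.all(np.abs(out - mean) <= np.abs(x - mean) + 1e-9)
        if sd > 0:
            assert out.min() >= mean - 6 * sd - 1e-9
            assert out.max() <= mean + 6 * sd + 1e-9


class TestStandardDrinks:
    def test_beer_is_one_standard_drink(self):
        # 12 fl oz at 5% ABV ~ 14 g ethanol ~ 1.00 US standard drink
        drinks = standard_drinks(12.0, abv=0.05, mode="volume_floz")
        assert drinks == pytest.approx(1.00, abs=0.01)
        assert drinks * 14.0 == pytest.approx(14.0, abs=0.1)

    def test_spirits_hand_arithmetic(self):
        # 1000 ml at 40% ABV: 1000*0.40*0.78945/14
        assert standard_drinks(1000.0, abv=0.40, mode="ml_abv") == pytest.approx(
            22.5557, abs=1e-3
        )

    def test_zero_volume(self):
        assert standard_drinks(0.0, abv=0.4, mode="ml_abv") == 0.0

    def test_grams_mode(self):
        assert standard_drinks(14.0, mode="grams_country") == 1.0

    def test_floz_and_ml_modes_agree(self):
        a = standard_drinks(12.0, abv=0.05, mode="volume_floz")
        c = standard_drinks(12.0 * 29.5735, abv=0.05, mode="ml_abv")
        assert abs(a - c) / c < 1e-3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"volume": -1.0, "abv": 0.4, "mode": "ml_abv"},
            {"volume": 10.0, "abv": 1.5, "mode": "ml_abv"},
            {"volume": 10.0, "abv": 0.4, "mode": "bad"},
            {"volume": 10.0, "mode": "ml_abv"},
        ],
    )
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            standard_drinks(**kwargs)


class TestExposureContrasts:
    @pytest.mark.parametrize(
        "dpw,sex,contrast,expected",
        [
            (8.0, "F", "HEAVYvsNEVER", 1.0),   # >7 DPW females is heavy
            (0.5, "F", "LIGHTvsNEVER", 0.0),   # <1 DPW is never
            (14.0, "M", "HEAVYvsLIGHT", 0.0),  # 1-14 DPW males is light (inclusive)
            (14.01, "M", "HEAVYvsLIGHT", 1.0),
            (7.0, "F", "HEAVYvsLIGHT", 0.0),
            (0.0, "M", "CURDRINK", 0.0),
            (1.0, "M", "CURDRINK", 1.0),
        ],
    )
    def test_boundaries(self, dpw, sex, contrast, expected):
        out = classify_exposure([dpw], [sex], contrast)
        assert out[0] == expected

    def test_non_members_excluded(self):
        # heavy drinkers are absent from the light-vs-never contrast
        out = classify_exposure([20.0], ["F"], "LIGHTvsNEVER")
        assert np.isnan(out[0])

    def test_unknown_contrast(self):
        with pytest.raises(ValueError):
            classify_exposure([1.0], ["F"], "WINEvsBEER")

    @given(
        st.floats(min_value=0.0, max_value=200.0, allow_nan=False),
        st.sampled_from(["F", "M"]),
    )
    @settings(deadline=None, max_examples=200)
    def test_categories_partition(self, dpw, sex):
        cat = drinking_category([dpw], [sex])[0]
        assert cat in ("never", "light", "heavy")
        cut = 7.0 if sex == "F" else 14.0
        if dpw < 1:
            assert cat == "never"
        elif dpw <= cut:
            assert cat == "light"
        else:
            assert cat == "heavy"


class TestVeryHeavyExclusion:
    def test_constant_dpw_keeps_all(self):
        keep = exclude_very_heavy(np.full(50, 5.0), np.array(["F"] * 50))
        assert keep.all()

    def test_single_extreme_dropped(self):
        dpw = np.concatenate([np.linspace(1, 5, 100), [1000.0]])
        sex = np.array(["F", "M"] * 50 + ["M"])
        keep = exclude_very_heavy(dpw, sex)
        assert not keep[-1]
        assert keep[:-1].all()
        # oracle: flag recomputed from the pre-exclusion combined moments
        drinkers = dpw[dpw >= 1]
        cut = drinkers.mean() + 6 * drinkers.std(ddof=1)
        assert dpw[-1] >= cut


class TestBuildSlices:
    def test_full_grid(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=400, n_variants=2, seed=1))
        slices = build_slices(cohort)
        assert len(slices) == 36
        for sl in slices:
            assert set(np.unique(sl.table["Alc"])) <= {0.0, 1.0}

    def test_single_sex_cohort_flags_other_sex(self):
        cohort = simulate_cohort(
            SimulationConfig(n_individuals=200, n_variants=2, p_male=0.0, seed=2)
        )
        slices = build_slices(cohort, traits=["SBP"], contrasts=["CURDRINK"])
        by_group = {sl.sex_group: sl for sl in slices}
        assert by_group["M"].flagged
        assert not by_group["F"].flagged

    def test_curdrink_covers_everyone_after_exclusions(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=500, n_variants=2, seed=3))
        keep = exclude_very_heavy(cohort.individuals["dpw"], cohort.individuals["sex"])
        sl = build_slices(
            cohort, traits=["SBP"], contrasts=["CURDRINK"], sex_groups=["combined"]
        )[0]
        assert sl.n == int(keep.sum())

    def test_pp_identity_holds_in_slices(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=300, n_variants=2, seed=4))
        slices = build_slices(
            cohort, traits=["SBP", "DBP", "PP"], contrasts=["CURDRINK"],
            sex_groups=["combined"],
        )
        by_trait = {sl.trait: sl for sl in slices}
        sbp = by_trait["SBP"].table["Y"].to_numpy()
        dbp = by_trait["DBP"].table["Y"].to_numpy()
        pp = by_trait["PP"].table["Y"].to_numpy()
        # PP is computed before winsorization; rows untouched by the 6-SD cap
        # (virtually all) satisfy the subtraction identity
        assert np.mean(np.isclose(pp, sbp - dbp)) > 0.99
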