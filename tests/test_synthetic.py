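"""Synthetic-data generator: structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from vicombo.design import DEFAULT_DRUGS, DesignMatrix, checkerboard_ladder
from vicombo.dose_response import DoseResponseCurve
from vicombo.response_surface import fit_response_surface
from vicombo.synergy import score_checkerboard
from vicombo.synthetic import (
    NoiseModel,
    SyntheticDataError,
    TrueSurface,
    make_sex_pair,
    simulate_checkerboard,
    simulate_design_responses,
    simulate_monotherapy,
)


def flat_surface(**kw):
    k = len(DEFAULT_DRUGS)
    defaults = dict(
        drugs=DEFAULT_DRUGS, intercept=0.0, linear=(0.0,) * k, quadratic=(0.0,) * k
    )
    defaults.update(kw)
    return TrueSurface(**defaults)


def run_matrix(*rows):
    return DesignMatrix(
        DEFAULT_DRUGS, np.array(rows), ("custom",) * len(rows)
    )


class TestSimulateMonotherapy:
    CURVE = DoseResponseCurve("d", "male", "asma_reduction", 100.0, 1.0, 1.0)

    def test_response_at_ec50_without_noise(self):
        tab = simulate_monotherapy(self.CURVE, [1.0], NoiseModel(0.0, 1, 0))
        assert tab["response_pct"].iloc[0] == pytest.approx(50.0)

    def test_zero_dose_gives_zero(self):
        tab = simulate_monotherapy(self.CURVE, [0.0], NoiseModel(0.0, 1, 0))
        assert tab["response_pct"].iloc[0] == 0.0

    def test_sample_means_converge_to_4pl(self):
        # oracle: direct 4PL evaluation, top 80 -> {7.27, 40.0, 72.7}
        c = DoseResponseCurve("d", "male", "asma_reduction", 80.0, 1.0, 1.0)
        tab = simulate_monotherapy(c, [0.1, 1.0, 10.0], NoiseModel(10.0, 1000, 7))
        means = tab.groupby("dose_uM")["response_pct"].mean()
        assert means[0.1] == pytest.approx(80 / 11, abs=1.0)
        assert means[1.0] == pytest.approx(40.0, abs=1.0)
        assert means[10.0] == pytest.approx(800 / 11, abs=1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(SyntheticDataError):
            simulate_monotherapy(self.CURVE, [-1.0], NoiseModel(0.0, 1, 0))

    def test_noise_calibration(self):
        # empirical SD of a fixed condition within 5% of well_sd=10
        tab = simulate_monotherapy(self.CURVE, [1.0], NoiseModel(10.0, 2000, 3))
        assert tab["response_pct"].std() == pytest.approx(10.0, rel=0.05)


class TestSimulateDesignResponses:
    def test_all_l0_run_gives_intercept(self):
        tab = simulate_design_responses(
            flat_surface(), run_matrix([0] * 8), NoiseModel(0.0, 1, 0)
        )
        assert tab["response_pct"].iloc[0] == 0.0

    def test_bilinear_hand_evaluation(self):
        # bilinear(d1,d2)=30 at both-L2 (coded 1*1) -> response 30
        surf = flat_surface(bilinear={(0, 1): 30.0})
        row = [2, 2] + [0] * 6
        tab = simulate_design_responses(surf, run_matrix(row), NoiseModel(0.0, 1, 0))
        assert tab["response_pct"].iloc[0] == pytest.approx(30.0)

    def test_determinism(self):
        surf, _ = make_sex_pair(3)
        d = run_matrix([1] * 8, [2] * 8)
        a = simulate_design_responses(surf, d, NoiseModel(10.0, 3, 11))
        b = simulate_design_responses(surf, d, NoiseModel(10.0, 3, 11))
        pd.testing.assert_frame_equal(a, b)

    def test_generator_analyzer_consistency(self, screen_design, drugs):
        # noiseless simulated responses refit to every true coefficient, 1e-6
        # strictly positive everywhere, so no positivity shift interferes
        surf = flat_surface(
            intercept=5.0,
            linear=(4.0, 0.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            bilinear={(1, 2): 25.0, (6, 7): -3.0},
        )
        tab = simulate_design_responses(surf, screen_design, NoiseModel(0.0, 1, 0))
        model = fit_response_surface(
            tab[list(drugs)].to_numpy(), tab["response_pct"].to_numpy(), drugs
        )
        assert model.transform_lambda == 1.0
        assert model.coefficient_for("intercept", ()) == pytest.approx(5.0, abs=1e-6)
        assert model.coefficient_for("linear", (0,)) == pytest.approx(4.0, abs=1e-6)
        assert model.coefficient_for("linear", (2,)) == pytest.approx(3.0, abs=1e-6)
        assert model.coefficient_for("bilinear", (1, 2)) == pytest.approx(25.0, abs=1e-6)
        assert model.coefficient_for("bilinear", (6, 7)) == pytest.approx(-3.0, abs=1e-6)


class TestSimulateCheckerboard:
    # partial-efficacy curves keep expected + excess below saturation, so
    # the planted Bliss excess is exactly invertible from the scored grid
    CURVE_A = DoseResponseCurve("a", "male", "asma_reduction", 50.0, 1.0, 1.0)
    CURVE_B = DoseResponseCurve("b", "male", "asma_reduction", 40.0, 0.5, 1.5)
    LA = checkerboard_ladder(1.0, "a")
    LB = checkerboard_ladder(0.5, "b")

    def test_no_excess_no_noise_scores_zero(self):
        tab = simulate_checkerboard(
            self.CURVE_A, self.CURVE_B, 0.0, self.LA, self.LB, NoiseModel(0.0, 1, 0)
        )
        smap = score_checkerboard(tab)
        assert np.allclose(smap.cells["score"], 0.0, atol=1e-12)

    def test_planted_excess_recovered_exactly_without_noise(self):
        tab = simulate_checkerboard(
            self.CURVE_A, self.CURVE_B, 20.0, self.LA, self.LB, NoiseModel(0.0, 1, 0)
        )
        smap = score_checkerboard(tab)
        assert np.allclose(smap.cells["score"], 20.0, atol=1e-9)

    def test_planted_excess_recovered_under_noise(self):
        # well SD 5, 4 replicates: mean recovered score within 5 of 20
        tab = simulate_checkerboard(
            self.CURVE_A, self.CURVE_B, 20.0, self.LA, self.LB, NoiseModel(5.0, 4, 5)
        )
        smap = score_checkerboard(tab)
        assert smap.cells["score"].mean() == pytest.approx(20.0, abs=5.0)

    def test_ladder_without_zero_rejected(self):
        bad = checkerboard_ladder(1.0, "a")
        object.__setattr__(bad, "doses", (0.25, 0.5, 1.0))
        with pytest.raises(SyntheticDataError):
            simulate_checkerboard(
                self.CURVE_A, self.CURVE_B, 0.0, bad, self.LB, NoiseModel(0.0, 1, 0)
            )


class TestMakeSexPair:
    @pytest.mark.parametrize("seed", [0, 1, 17, 123])
    def test_monotherapies_broadly_ineffective(self, seed):
        male, female = make_sex_pair(seed)
        for surf in (male, female):
            for j in range(8):
                lv = [0] * 8
                lv[j] = 2
                assert surf.observed(lv) <= 15.0

    def test_same_seed_identical(self):
        a = make_sex_pair(5)
        b = make_sex_pair(5)
        assert a == b

    def test_bilinear_sex_difference_at_least_20(self):
        male, female = make_sex_pair(2)
        diffs = [
            abs(male.bilinear.get(k, 0.0) - female.bilinear.get(k, 0.0))
            for k in set(male.bilinear) | set(female.bilinear)
        ]
        assert max(diffs) >= 20.0

    @pytest.mark.parametrize("seed", [0, 9, 42])
    def test_planted_pair_male_biased_by_construction(self, seed):
        male, female = make_sex_pair(seed)
        lv = [0] * 8
        lv[6] = lv[7] = 2  # the male-specific synergy pair at L2/L2
        assert male.observed(lv) - female.observed(lv) >= 20.0
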