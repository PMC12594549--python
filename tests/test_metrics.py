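"""Profile extraction, RMSE and gamma analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

from shiftqa import (
    DetectorLayout,
    DoseGrid,
    GammaParams,
    Measurement,
    Profile,
    compute_rmse,
    extract_profile,
    film_sample,
    gamma,
    pass_rate_table,
    sample,
)

from gamma_oracle import gamma_bruteforce


class TestProfileExtraction:
    def test_film_row_n_equals_nodes_on_line(self, single_grid):
        m = film_sample(single_grid, extent_mm=60.0)
        prof = extract_profile(single_grid, m, axis="SI")
        assert prof.n == 61
        np.testing.assert_allclose(prof.d_ref, prof.d_meas, atol=1e-9)

    def test_coarse_array_has_at_most_three_infield_points(self, single_grid):
        # 10 mm pitch on a 1 cm target: only the peak and the two gradient
        # feet carry >= 10% of the maximum on the central profile
        layout = DetectorLayout(pitch=(10, 10), n_diodes=(9, 9))
        m = sample(single_grid, layout)
        prof = extract_profile(single_grid, m, axis="SI", resample="measured")
        assert prof.n == 9
        assert np.count_nonzero(prof.d_meas >= 10.0) <= 3

    def test_line_without_points_errors(self, single_grid):
        layout = DetectorLayout(pitch=(10, 10), n_diodes=(9, 9))
        m = sample(single_grid, layout)
        with pytest.raises(ValueError, match="fewer than 2"):
            extract_profile(single_grid, m, axis="SI", line_position_mm=3.3)


class TestRmse:
    def test_identical_columns_zero(self):
        p = Profile([0.0, 1.0, 2.0], [10.0, 50.0, 90.0], [10.0, 50.0, 90.0])
        res = compute_rmse(p)
        assert res.rmse == 0.0 and res.n == 3

    def test_hand_computed_example(self):
        # pairs (100,98), (50,52), (0,1): sqrt((4+4+1)/3) = sqrt(3)
        p = Profile([0.0, 1.0, 2.0], [100.0, 50.0, 0.0], [98.0, 52.0, 1.0])
        assert compute_rmse(p).rmse == pytest.approx(np.sqrt(3.0), abs=1e-12)
        assert compute_rmse(p, drop_last=True).rmse == pytest.approx(2.0)
        assert compute_rmse(p, drop_last=True).n == 2

    def test_pair_order_irrelevant(self, rng):
        ref = rng.uniform(0, 100, 20)
        meas = ref + rng.normal(0, 2, 20)
        x = np.arange(20.0)
        r1 = compute_rmse(Profile(x, ref, meas)).rmse
        perm = rng.permutation(20)
        r2 = compute_rmse(Profile(x, ref[perm], meas[perm])).rmse
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Profile([0.0, 0.0, 1.0], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="two paired"):
            Profile([0.0], [1.0], [1.0])


def flat_grid(value=100.0, n=41):
    half = (n - 1) / 2.0
    return DoseGrid(values=np.full((n, n), value), origin=(-half, -half))


class TestGamma:
    def test_perfect_agreement(self, single_grid):
        m = film_sample(single_grid, extent_mm=60.0)
        for dd, dta in [(3, 3), (3, 2), (2, 2), (3, 1)]:
            res = gamma(single_grid, m, GammaParams(dose_diff=dd, dta=dta))
            assert res.pass_rate == 100.0
            assert np.all(res.gamma <= 1e-9)

    def test_three_percent_excess_on_flat_field_is_boundary(self):
        grid = flat_grid(100.0)
        m = Measurement([0.0], [0.0], [103.0])
        res = gamma(grid, m, GammaParams(3.0, 3.0, threshold=10.0))
        assert res.gamma[0] == pytest.approx(1.0, abs=1e-9)
        assert res.pass_rate == 100.0

    def test_threshold_excludes_and_errors(self, single_grid):
        m = Measurement([0.0, 20.0], [0.0, 0.0], [99.0, 1.5])
        res = gamma(single_grid, m, GammaParams(3.0, 3.0, threshold=10.0))
        assert res.n_evaluated == 1
        with pytest.raises(ValueError, match="99.9%"):
            gamma(single_grid, m, GammaParams(3.0, 3.0, threshold=99.9))

    def test_monotone_in_tolerances(self, single_grid):
        layout = DetectorLayout(pitch=(5, 5), n_diodes=(9, 9), footprint=(7, 3))
        m = sample(single_grid, layout)
        g33 = gamma(single_grid, m, GammaParams(3, 3)).gamma
        g32 = gamma(single_grid, m, GammaParams(3, 2)).gamma
        g22 = gamma(single_grid, m, GammaParams(2, 2)).gamma
        g31 = gamma(single_grid, m, GammaParams(3, 1)).gamma
        assert np.all(g33 <= g32 + 1e-9)  # looser dta -> smaller gamma
        assert np.all(g32 <= g22 + 1e-9)  # looser dose_diff -> smaller gamma
        assert np.all(g32 <= g31 + 1e-9)

    def test_pure_dose_difference_limit(self):
        # huge dta: gamma collapses to the best dose match within reach,
        # bounded by the dose difference at the point itself
        grid = flat_grid(100.0)
        m = Measurement([0.0], [0.0], [106.0])
        res = gamma(grid, m, GammaParams(dose_diff=3.0, dta=40.0, search_radius_factor=0.25))
        assert res.gamma[0] == pytest.approx(2.0, rel=1e-6)  # 6% / 3%

    def test_pure_dta_limit(self):
        # a tight dose criterion forces the search to the exact-agreement
        # position: gamma collapses to distance-to-agreement / dta
        x = np.arange(-20.0, 21.0)
        SI, RL = np.meshgrid(x, x, indexing="ij")
        grid = DoseGrid(values=50.0 + 2.0 * SI, origin=(-20.0, -20.0))
        m = Measurement([0.0], [0.0], [grid.dose_at(2.0, 0.0)])  # agreement 2 mm away
        res = gamma(
            grid, m,
            GammaParams(dose_diff=0.25, dta=1.0, threshold=0.0, ref_upsample_step=0.05),
        )
        assert res.gamma[0] == pytest.approx(2.0, abs=0.02)

    def test_scale_covariance_global(self, single_grid):
        layout = DetectorLayout(pitch=(5, 5), n_diodes=(5, 5), footprint=(7, 3))
        m = sample(single_grid, layout)
        g1 = gamma(single_grid, m, GammaParams(3, 2)).gamma
        scaled_grid = DoseGrid(
            values=single_grid.values * 7.3,
            spacing=single_grid.spacing,
            origin=single_grid.origin,
        )
        m2 = Measurement(m.pos_si, m.pos_rl, m.dose * 7.3)
        g2 = gamma(scaled_grid, m2, GammaParams(3, 2)).gamma
        np.testing.assert_allclose(g1, g2, rtol=1e-9)
        p1 = compute_rmse(extract_profile(single_grid, m, tolerance_mm=0.5)).rmse
        p2 = compute_rmse(extract_profile(scaled_grid, m2, tolerance_mm=0.5)).rmse
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_bruteforce_on_small_case(self, rng):
        # quick dual-route check; the exhaustive version runs in acceptance
        x = np.arange(-15.0, 16.0)
        SI, RL = np.meshgrid(x, x, indexing="ij")
        vals = 60 + 40 * np.exp(-(SI**2 + RL**2) / 60.0)
        grid = DoseGrid(values=vals, origin=(-15.0, -15.0))
        psi = rng.uniform(-8, 8, 5)
        prl = rng.uniform(-8, 8, 5)
        doses = grid.dose_at(psi, prl) * rng.uniform(0.95, 1.05, 5)
        m = Measurement(psi, prl, doses)
        res = gamma(
            grid, m, GammaParams(3.0, 2.0, threshold=0.0, ref_upsample_step=0.05)
        )
        oracle = gamma_bruteforce(grid, psi, prl, doses, 3.0, 2.0)
        np.testing.assert_allclose(res.gamma, oracle, atol=1e-3)

    def test_local_normalization_tighter_in_low_dose(self):
        # 100% peak with a flat 50% plateau: a 3-unit excess measured on the
        # plateau is exactly at tolerance globally but double it locally
        x = np.arange(-20.0, 21.0)
        SI, RL = np.meshgrid(x, x, indexing="ij")
        vals = np.where(np.hypot(SI, RL) < 5.0, 100.0, 50.0)
        grid = DoseGrid(values=vals, origin=(-20.0, -20.0))
        m = Measurement([15.0], [0.0], [53.0])
        glob = gamma(grid, m, GammaParams(3, 1, threshold=0.0)).gamma[0]
        loc = gamma(grid, m, GammaParams(3, 1, threshold=0.0, normalization="local")).gamma[0]
        assert glob == pytest.approx(1.0, abs=1e-6)
        assert loc == pytest.approx(2.0, abs=1e-6)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GammaParams(dose_diff=0.0)
        with pytest.raises(ValueError):
            GammaParams(threshold=100.0)
        with pytest.raises(ValueError):
            GammaParams(dta=2.0, ref_upsample_step=0.5)
        with pytest.raises(ValueError):
            GammaParams(normalization="percent")


class TestPassRateTable:
    def _result(self, rates):
        from shiftqa.metrics import GammaResult

        return [
            GammaResult(
                pos_si=np.zeros(4), pos_rl=np.zeros(4), gamma=np.zeros(4),
                n_evaluated=4, n_pass=int(r / 25), pass_rate=r,
                params=GammaParams(),
            )
            for r in rates
        ]

    def test_single_replicate_zero_sd(self):
        table = pass_rate_table({"3%/3mm": self._result([75.0])[0]})
        assert table.loc[0, "sd_pass_rate"] == 0.0
        assert table.loc[0, "mean_pass_rate"] == 75.0

    def test_identical_replicates(self):
        table = pass_rate_table({"3%/3mm": self._result([50.0, 50.0, 50.0])})
        assert table.loc[0, "mean_pass_rate"] == 50.0
        assert table.loc[0, "sd_pass_rate"] == 0.0

    @given(st.lists(st.floats(0, 100), min_size=3, max_size=3))
    def test_mean_within_replicate_range(self, rates):
        table = pass_rate_table({"t": self._result(rates)})
        mean = table.loc[0, "mean_pass_rate"]
        assert min(rates) - 1e-9 <= mean <= max(rates) + 1e-9
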