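"""Tests of intensity conversion, uncertainty propagation and global fitting."""

import numpy as np
import pandas as pd
import pytest

from ringflip.dispersion import (
    DispersionDataset,
    FitConfig,
    R2EFF_COLUMNS,
    detect_exchange,
    global_fit,
    mc_parameter_uncertainty,
    pooled_sd,
    propagate_r2eff_errors,
    r2eff_from_intensities,
)
from ringflip.errors import DataError
from ringflip.synthetic import make_dispersion_dataset, nitrogen_schedule

SMALL_SCHEDULES = (
    ("15N", 600.0, nitrogen_schedule),
    ("15N", 850.0, nitrogen_schedule),
)
FAST_CONFIG = FitConfig(
    kex_starts=(1000.0, 2500.0, 7000.0), pminor_starts=(0.02, 0.1),
    n_refine_starts=1, seed=0,
)


class TestR2effConversion:
    @pytest.mark.parametrize(
        "i, i0, t, expected",
        [
            (70.0, 70.0, 0.032, 0.0),
            (50.0, 100.0, 0.032, np.log(2) / 0.032),  # ~21.66 1/s
            (100.0 * np.exp(-1.0), 100.0, 0.020, 50.0),
        ],
    )
    def test_constant_time_closed_form(self, i, i0, t, expected):
        assert r2eff_from_intensities(i, i0, t) == pytest.approx(expected)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(DataError):
            r2eff_from_intensities(-1.0, 100.0, 0.032)

    def test_roundtrip_with_forward_model_is_identity(self):
        r2eff = np.array([8.0, 12.5, 30.0])
        intens = 100.0 * np.exp(-r2eff * 0.032)
        back = r2eff_from_intensities(intens, 100.0, 0.032)
        np.testing.assert_allclose(back, r2eff, rtol=1e-12)


class TestPooledSd:
    def test_identical_replicates_give_zero(self):
        assert pooled_sd([[5.0, 5.0], [3.0, 3.0, 3.0]]) == 0.0

    def test_single_pair_formula(self):
        assert pooled_sd([[4.0, 7.0]]) == pytest.approx(3.0 / np.sqrt(2))

    def test_matches_direct_summation(self):
        pools = [[1.0, 2.0, 4.0], [10.0, 11.0], [5.0, 5.5, 6.5, 7.0]]
        num = sum(
            sum((x - np.mean(p)) ** 2 for x in p) for p in pools
        )
        dof = sum(len(p) - 1 for p in pools)
        assert pooled_sd(pools) == pytest.approx(np.sqrt(num / dof))

    def test_no_valid_pool_is_an_error(self):
        with pytest.raises(DataError):
            pooled_sd([[1.0], [2.0]])


class TestErrorPropagation:
    def test_zero_noise_gives_zero(self):
        assert propagate_r2eff_errors(70.0, 100.0, 0.0, 0.032) == 0.0

    def test_small_noise_matches_delta_method(self):
        # first-order: var(R2eff) = (s/I)^2/T^2 + (s0/I0)^2/T^2
        i, i0, s, t = 70.0, 100.0, 0.5, 0.032
        expected = np.sqrt((s / i) ** 2 + (s / i0) ** 2) / t
        got = propagate_r2eff_errors(i, i0, s, t, n_draws=20000, seed=1)
        assert got == pytest.approx(expected, rel=0.1)

    def test_approximately_linear_in_noise(self):
        a = propagate_r2eff_errors(70.0, 100.0, 0.25, 0.032, n_draws=20000, seed=2)
        b = propagate_r2eff_errors(70.0, 100.0, 0.50, 0.032, n_draws=20000, seed=2)
        assert b / a == pytest.approx(2.0, rel=0.05)

    def test_reproducible_under_seed(self):
        a = propagate_r2eff_errors(70.0, 100.0, 0.5, 0.032, n_draws=500, seed=7)
        b = propagate_r2eff_errors(70.0, 100.0, 0.5, 0.032, n_draws=500, seed=7)
        assert a == b

    def test_invalid_noise_model_rejected(self):
        # both peak and reference barely above zero with huge noise:
        # the joint acceptance rate drops below 50%
        with pytest.raises(DataError):
            propagate_r2eff_errors(0.5, 0.5, 5.0, 0.032, n_draws=200, seed=0)


class TestGlobalFit:
    def test_noiseless_recovery_to_point_one_percent(self):
        data, truth = make_dispersion_dataset(
            "wildtype", n_spins=5, noise=0.0, seed=3
        )
        fit = global_fit(data, FitConfig(seed=1))
        assert fit.params.k_ex == pytest.approx(2600.0, rel=1e-3)
        assert fit.params.p_minor == pytest.approx(0.028, rel=1e-3)

    def test_record_order_invariance(self):
        data, _ = make_dispersion_dataset(
            "wildtype", n_spins=2, schedules=SMALL_SCHEDULES, noise=0.01, seed=5
        )
        fit_a = global_fit(data, FAST_CONFIG)
        shuffled = DispersionDataset(
            data.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        fit_b = global_fit(shuffled, FAST_CONFIG)
        assert fit_a.params.k_ex == pytest.approx(fit_b.params.k_ex, rel=1e-6)
        assert fit_a.params.p_minor == pytest.approx(fit_b.params.p_minor, rel=1e-6)

    def test_null_data_shows_no_exchange_contribution(self):
        # p_minor = 0 truth: the fitted exchange amplitudes are negligible
        data, _ = make_dispersion_dataset(
            "wildtype", n_spins=3, schedules=SMALL_SCHEDULES, noise=0.0, seed=2
        )
        df = data.df.copy()
        # rebuild flat intensities at the fitted R2,0 level
        df["intensity"] = df["intensity_ref"] * np.exp(-8.0 * df["relax_time_s"])
        flat = DispersionDataset(df)
        r2 = flat.to_r2eff()
        for (spin, nuc, f), g in r2.df.groupby(["spin", "nucleus", "field_mhz"]):
            res = detect_exchange(g["nu_cpmg_hz"], g["r2eff"],
                                  np.full(len(g), 0.2))
            assert not res["exchange"]


class TestMcUncertainty:
    def test_zero_noise_gives_tiny_sigma_and_noise_grows_sigma(self):
        sigmas = []
        for noise in (0.005, 0.02):
            data, _ = make_dispersion_dataset(
                "wildtype", n_spins=2, schedules=SMALL_SCHEDULES,
                noise=noise, seed=9,
            )
            fit = global_fit(data, FAST_CONFIG)
            out = mc_parameter_uncertainty(fit, data, n_draws=12, seed=3,
                                           config=FAST_CONFIG)
            sigmas.append(out.kex_err)
        assert sigmas[0] < sigmas[1]

    def test_seed_reproducibility(self):
        data, _ = make_dispersion_dataset(
            "wildtype", n_spins=2, schedules=SMALL_SCHEDULES, noise=0.02, seed=4
        )
        fit = global_fit(data, FAST_CONFIG)
        a = mc_parameter_uncertainty(fit, data, n_draws=8, seed=11,
                                     config=FAST_CONFIG)
        b = mc_parameter_uncertainty(fit, data, n_draws=8, seed=11,
                                     config=FAST_CONFIG)
        assert a.kex_err == b.kex_err


class TestDetectExchange:
    NU = np.array([31.25, 62.5, 125.0, 187.5, 250.0, 312.5, 375.0,
                   500.0, 625.0, 750.0, 875.0, 1000.0])

    def test_noiseless_flat_profile_is_not_exchange(self):
        res = detect_exchange(self.NU, np.full(self.NU.size, 8.0),
                              np.full(self.NU.size, 0.2))
        assert not res["exchange"]

    def test_strong_dispersion_is_detected(self):
        rex = 10.0 * (1 - (4 * self.NU / 2000.0) * np.tanh(2000.0 / (4 * self.NU)))
        rng = np.random.default_rng(0)
        obs = 8.0 + rex + 0.3 * rng.standard_normal(self.NU.size)
        res = detect_exchange(self.NU, obs, np.full(self.NU.size, 0.3))
        assert res["exchange"]
        assert res["aic_exchange"] < res["aic_flat"]

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            detect_exchange(self.NU[:4], np.full(4, 8.0), np.full(4, 0.2))


def test_dataset_rejects_mixed_modes():
    df = pd.DataFrame(columns=R2EFF_COLUMNS + ["intensity"])
    with pytest.raises(DataError):
        DispersionDataset(df)


class TestRecoveryGrid:
    def test_kex_recovery_across_exchange_regimes(self):
        """Median relative k_ex error < 10% over a slow-to-fast grid of
        truths at 2% noise with two static fields."""
        from ringflip.synthetic import FIXTURES

        grid_config = FitConfig(
            kex_starts=(250.0, 1000.0, 2500.0, 7000.0),
            pminor_starts=(0.01, 0.05, 0.15), n_refine_starts=2, seed=0,
        )
        errors = []
        saved = dict(FIXTURES["wildtype"])
        try:
            for i, kex in enumerate((800.0, 2600.0, 8000.0)):
                for j, pb in enumerate((0.01, 0.03, 0.10)):
                    FIXTURES["wildtype"] = dict(k_ex=kex, p_minor=pb)
                    data, _ = make_dispersion_dataset(
                        "wildtype", n_spins=6, schedules=SMALL_SCHEDULES,
                        noise=0.02, seed=700 + 10 * i + j,
                    )
                    fit = global_fit(data, grid_config)
                    errors.append(abs(fit.params.k_ex - kex) / kex)
        finally:
            FIXTURES["wildtype"] = saved
        assert np.median(errors) < 0.10
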