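import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from frysim import (
    BoilingModel,
    ElevationDataset,
    FryingConditions,
    PropertySet,
    boiling_temperature,
    crust_fraction,
    enthalpy_of_temperature,
    fit_boiling_elevation,
    mushy_density,
    temperature_of_enthalpy,
    thermal_diffusivity,
    volumetric_enthalpy,
)

DELTA = 0.005


class TestBoilingTemperature:
    def test_fixed_mode_ignores_position(self):
        m = BoilingModel(mode="fixed", Tb0=103.0)
        assert boiling_temperature(0.0, DELTA, m) == 103.0
        assert boiling_temperature(DELTA / 2, DELTA, m) == 103.0

    @pytest.mark.parametrize(
        "ym_frac, expected_elev, tol",
        [
            (0.0, 7e-10, 1e-12),  # exponent zero: elevation is the prefactor
            (0.5, 7e-10 * np.exp(25.455 * 0.5), 1e-9),  # ~2.4e-4 °C, negligible
            (1.0, 7e-10 * np.exp(25.455), 1e-6),  # ~79.4 °C at full depth
        ],
    )
    def test_variable_mode_elevation(self, ym_frac, expected_elev, tol):
        m = BoilingModel(mode="variable", Tb0=103.0, cap=1e9)
        got = boiling_temperature(ym_frac * DELTA / 2, DELTA, m) - 103.0
        assert got == pytest.approx(expected_elev, rel=tol, abs=1e-12)
        if ym_frac == 1.0:
            assert got == pytest.approx(79.44, abs=0.05)

    def test_cap_clamps(self):
        m = BoilingModel(mode="variable", cap=179.5)
        assert boiling_temperature(DELTA / 2, DELTA, m) == 179.5

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_non_decreasing_in_position(self, a, b):
        m = BoilingModel(mode="variable")
        lo, hi = sorted((a, b))
        assert boiling_temperature(hi * DELTA / 2, DELTA, m) >= boiling_temperature(
            lo * DELTA / 2, DELTA, m
        )

    def test_out_of_domain_position_rejected(self):
        with pytest.raises(ValueError):
            boiling_temperature(DELTA, DELTA, BoilingModel())
        with pytest.raises(ValueError):
            boiling_temperature(-1e-3, DELTA, BoilingModel())


class TestEnthalpyRelation:
    Tb, eps = 103.0, 0.5

    def test_core_branch_value(self, props):
        assert enthalpy_of_temperature(50.0, props, self.Tb, self.eps) == pytest.approx(
            172_500.0
        )

    def test_crust_branch_value(self, props):
        # Ccr*(Tb+eps) + w*lambda + (Cco-Ccr)*Tb with the default property set
        got = enthalpy_of_temperature(self.Tb + self.eps, props, self.Tb, self.eps)
        assert got == pytest.approx(2.021542e6, rel=1e-6)

    def test_continuity_at_both_band_edges(self, props):
        for T in (self.Tb - self.eps, self.Tb + self.eps):
            below = enthalpy_of_temperature(T - 1e-9, props, self.Tb, self.eps)
            above = enthalpy_of_temperature(T + 1e-9, props, self.Tb, self.eps)
            mid = enthalpy_of_temperature(T, props, self.Tb, self.eps)
            assert abs(above - below) / mid < 1e-5  # only the 1e-9 °C ramp
            assert below <= mid <= above

    def test_strictly_increasing(self, props):
        T = np.linspace(0.0, 200.0, 4001)
        H = enthalpy_of_temperature(T, props, self.Tb, self.eps)
        assert np.all(np.diff(H) > 0)

    def test_inverse_example(self, props):
        assert temperature_of_enthalpy(172_500.0, props, self.Tb, self.eps) == pytest.approx(
            50.0, abs=1e-9
        )

    def test_roundtrip_identity(self, props):
        T = np.linspace(0.0, 200.0, 1000)
        back = temperature_of_enthalpy(
            enthalpy_of_temperature(T, props, self.Tb, self.eps), props, self.Tb, self.eps
        )
        assert np.max(np.abs(back - T)) < 1e-9

    def test_nonpositive_epsilon_rejected(self, props):
        with pytest.raises(ValueError):
            enthalpy_of_temperature(50.0, props, self.Tb, 0.0)
        with pytest.raises(ValueError):
            temperature_of_enthalpy(1e5, props, self.Tb, -1.0)


class TestVolumetricEnthalpy:
    """E(T) must be the exact integral of rho(T)·dH/dT for both density rules."""

    @pytest.mark.parametrize("rule", ["core", "mixture"])
    @pytest.mark.parametrize("T_hi", [100.0, 103.2, 104.5, 150.0])
    def test_matches_numeric_integration(self, props, rule, T_hi):
        Tb, eps = 103.0, 0.5

        def integrand(T):
            dT = 1e-6
            dH = (
                enthalpy_of_temperature(T + dT, props, Tb, eps)
                - enthalpy_of_temperature(T - dT, props, Tb, eps)
            ) / (2 * dT)
            if rule == "core":
                rho = props.rho_crust if T >= Tb + eps else props.rho_core
            else:
                rho = mushy_density(crust_fraction(T, Tb, eps), props)
            return rho * dH

        expected, _ = quad(
            integrand, 20.0, T_hi, points=[Tb - eps, Tb + eps], limit=200
        )
        got = volumetric_enthalpy(T_hi, props, Tb, eps, rule) - volumetric_enthalpy(
            20.0, props, Tb, eps, rule
        )
        assert got == pytest.approx(expected, rel=1e-5)


class TestDiffusivityAndMixing:
    def test_diffusivity_values(self, props):
        assert thermal_diffusivity(0.11, 386, 1790) == pytest.approx(1.592e-7, rel=1e-3)
        assert thermal_diffusivity(0.73, 1132, 3450) == pytest.approx(1.869e-7, rel=1e-3)
        assert thermal_diffusivity(1, 1, 1) == 1.0

    def test_diffusivity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            thermal_diffusivity(0.0, 1.0, 1.0)

    def test_crust_fraction_linear_map(self):
        assert crust_fraction(102.5, 103.0, 0.5) == 0.0
        assert crust_fraction(103.5, 103.0, 0.5) == 1.0
        assert crust_fraction(103.0, 103.0, 0.5) == 0.5

    def test_crust_fraction_clamps_and_warns(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert crust_fraction(120.0, 103.0, 0.5, warn_out_of_band=True) == 1.0
            assert crust_fraction(20.0, 103.0, 0.5, warn_out_of_band=True) == 0.0
        assert len(rec) == 2

    def test_mushy_density_endpoints(self, props):
        assert mushy_density(0.0, props) == 1132.0
        assert mushy_density(1.0, props) == 386.0
        assert mushy_density(0.5, props) == 759.0

    def test_mushy_density_rejects_out_of_range(self, props):
        with pytest.raises(ValueError):
            mushy_density(1.5, props)

    def test_density_decreases_across_band(self, props):
        T = np.linspace(102.5, 103.5, 101)
        rho = mushy_density(crust_fraction(T, 103.0, 0.5), props)
        assert np.all(np.diff(rho) <= 0)


class TestElevationFit:
    A, B = 7e-10, 25.455

    def _exact(self):
        x = np.array([0.6, 0.7, 0.8, 0.9, 1.0])
        return x, self.A * np.exp(self.B * x)

    def test_noise_free_recovery_is_exact(self):
        x, y = self._exact()
        Ah, Bh = fit_boiling_elevation(ElevationDataset(x * 100, y), shift=0.0)
        assert Bh == pytest.approx(self.B, rel=1e-9)
        assert Ah == pytest.approx(self.A, rel=1e-6)
        # and the fit reproduces its own training data
        assert np.max(np.abs(Ah * np.exp(Bh * x) - y)) < 1e-9

    def test_shift_is_applied_before_fitting(self):
        # measured-liquid elevations sit 3 °C below the in-tissue curve;
        # restrict to losses where that difference stays positive
        x = np.array([0.88, 0.92, 0.96, 1.0])
        y = self.A * np.exp(self.B * x)
        A2, B2 = fit_boiling_elevation(ElevationDataset(x * 100, y - 3.0), shift=3.0)
        assert B2 == pytest.approx(self.B, rel=1e-9)
        assert A2 == pytest.approx(self.A, rel=1e-6)

    def test_noisy_recovery_within_five_percent(self):
        x, y = self._exact()
        rng = np.random.default_rng(20210721)
        est = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                noisy = np.clip(y + rng.normal(0.0, 0.5, y.size), 0.0, None)
                try:
                    _, Bh = fit_boiling_elevation(ElevationDataset(x * 100, noisy), shift=0.0)
                except ValueError:
                    continue
                est.append(Bh)
        assert len(est) > 80
        assert abs(np.mean(est) - self.B) / self.B < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boiling_elevation(
                ElevationDataset(np.array([80.0, 100.0]), np.array([1.0, 79.0])), shift=0.0
            )

    def test_nonpositive_shifted_points_dropped_with_warning(self):
        x = np.array([60.0, 80.0, 90.0, 100.0])
        y = np.array([0.0, 0.5, 6.2, 79.4])
        with pytest.warns(UserWarning, match="dropped"):
            fit_boiling_elevation(ElevationDataset(x, y), shift=0.0)


class TestValidation:
    def test_property_set_rejects_bad_moisture(self):
        with pytest.raises(ValueError):
            PropertySet(w=1.2)
        with pytest.raises(ValueError):
            PropertySet(k_core=-1.0)

    def test_conditions_require_frying_ordering(self):
        with pytest.raises(ValueError):
            FryingConditions(T_oil=100.0, Tb0=103.0, T_init=20.0)
        # equilibrium diagnostics are allowed
        FryingConditions(T_oil=20.0, T_init=20.0)

    def test_boiling_model_mode_checked(self):
        with pytest.raises(ValueError):
            BoilingModel(mode="sometimes")
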