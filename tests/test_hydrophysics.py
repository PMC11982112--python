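"""Salinity, equation of state, irradiance and convection diagnostics."""

import numpy as np
import pandas as pd
import pytest

from underice import hydrophysics as hp
from underice import synthetic_data as sd


def flat_spectrum_profile(value_uw, k_d=0.0, depths=None, temps=None,
                          time="2015-02-01 12:00"):
    depths = np.arange(1.0, 17.01, 0.5) if depths is None else np.asarray(depths, float)
    temps = np.full(depths.size, 2.0) if temps is None else np.asarray(temps, float)
    decay = np.exp(-k_d * depths)
    ed = {lam: value_uw * decay for lam in (398.76, 450.0, 490.0, 550.0,
                                            620.0, 700.04)}
    return hp.WaterColumnProfile(time=pd.Timestamp(time), depth_m=depths,
                                 temperature_c=temps, ed=ed)


# ---------------------------------------------------------------------------
# volumetric salinity
# ---------------------------------------------------------------------------

class TestVolumetricSalinity:
    def test_pure_water_ion_product_only(self):
        # at pH 7: 1e-7 mol/L of H+ (1.008 g/mol) and OH- (17.008 g/mol)
        s = hp.volumetric_salinity(hp.ChemistryTable(), ph=7.0, dic_mol_per_l=0.0)
        assert s == pytest.approx(1e-7 * (1.008 + 17.008), rel=1e-9)

    def test_ion_contribution_is_linear(self):
        base = hp.ChemistryTable(ca=5, mg=1, na=2, k=0.5, cl=3, so4=4)
        doubled = hp.ChemistryTable(ca=10, mg=2, na=4, k=1, cl=6, so4=8)
        ph, dic = 7.4, 2e-4
        s0 = hp.volumetric_salinity(hp.ChemistryTable(), ph, dic)
        s1 = hp.volumetric_salinity(base, ph, dic)
        s2 = hp.volumetric_salinity(doubled, ph, dic)
        assert s2 - s0 == pytest.approx(2 * (s1 - s0), rel=1e-12)

    @pytest.mark.parametrize("ph", [5.0, 6.0, 7.0, 8.3, 9.0, 10.0])
    def test_speciation_matches_closed_form(self, ph):
        """Two-pK partition: independent closed-form oracle, fractions sum to 1."""
        h = 10.0 ** -ph
        k1, k2 = 10.0 ** -6.35, 10.0 ** -10.33
        # closed form: [CO2]:[HCO3]:[CO3] = h^2 : h*K1 : K1*K2
        weights = np.array([h * h, h * k1, k1 * k2])
        expected = weights / weights.sum()
        got = np.array(hp.carbonate_speciation(ph))
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert got.sum() == pytest.approx(1.0)

    def test_ph_shifts_carbonate_speciation(self):
        a_acid = hp.carbonate_speciation(6.0)
        a_base = hp.carbonate_speciation(9.0)
        assert a_acid[0] > a_acid[1] > a_acid[2]  # CO2-dominated
        assert a_base[1] > a_base[0]              # bicarbonate-dominated

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            hp.ChemistryTable(ca=-1.0)

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hp.volumetric_salinity(hp.ChemistryTable(), ph=3.0)


# ---------------------------------------------------------------------------
# equation of state
# ---------------------------------------------------------------------------

class TestDensity:
    def test_freshwater_density_maximum_at_4c(self):
        t = np.arange(0.0, 8.0001, 0.01)
        rho = hp.density(t, 0.0, 0.0)
        assert round(float(t[np.argmax(rho)]), 1) == 4.0

    def test_salt_increases_density(self):
        assert hp.density(2.0, 0.1, 0.0) > hp.density(2.0, 0.0, 0.0)

    def test_below_maximum_lighter(self):
        assert hp.density(0.0, 0.0, 0.0) < hp.density(4.0, 0.0, 0.0)

    def test_pressure_increases_density(self):
        assert hp.density(4.0, 0.0, 50.0) > hp.density(4.0, 0.0, 0.0)

    @pytest.mark.parametrize("kwargs", [
        {"t_c": -5.0}, {"t_c": 50.0}, {"t_c": 4.0, "s_g_l": 50.0},
        {"t_c": 4.0, "p_dbar": -1.0},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hp.density(**{"s_g_l": 0.0, "p_dbar": 0.0, **kwargs})


class TestExpansibilityAndHeatCapacity:
    def test_alpha_sign_structure(self):
        assert hp.thermal_expansibility(2.0) < 0
        assert hp.thermal_expansibility(10.0) > 0
        t = np.arange(3.5, 4.5, 0.001)
        t_md = t[np.argmax(hp.density(t))]
        assert abs(hp.thermal_expansibility(float(t_md))) < 1e-6

    def test_alpha_consistent_with_density_slope(self):
        """Independent check: differentiate a fine density curve directly."""
        t = np.arange(1.0, 10.0001, 0.001)
        rho = hp.density(t)
        alpha_ref = -np.gradient(rho, t) / rho
        alpha = hp.thermal_expansibility(t)
        inner = slice(100, -100)
        scale = np.maximum(np.abs(alpha_ref[inner]), 1e-6)
        assert np.max(np.abs(alpha[inner] - alpha_ref[inner]) / scale) < 0.01

    def test_cp_near_4200_for_cold_fresh_water(self):
        for t in np.arange(0.0, 10.01, 0.5):
            assert hp.specific_heat(float(t)) == pytest.approx(4.2e3, rel=0.05)


# ---------------------------------------------------------------------------
# irradiance at depth
# ---------------------------------------------------------------------------

class TestSolarRadiationAtDepth:
    def test_zero_spectrum_gives_zero(self):
        q = hp.solar_radiation_at_depth(flat_spectrum_profile(0.0))
        np.testing.assert_array_equal(q, 0.0)

    def test_flat_spectrum_band_integral(self):
        # 1 µW cm⁻² nm⁻¹ over 301.28 nm -> 3.0128 W m⁻² planar, /0.75 scalar
        q = hp.solar_radiation_at_depth(flat_spectrum_profile(1.0))
        assert q[0] == pytest.approx(3.0128 / 0.75, rel=1e-6)

    def test_decaying_spectrum_monotone(self):
        q = hp.solar_radiation_at_depth(flat_spectrum_profile(10.0, k_d=0.4))
        assert np.all(np.diff(q) < 0)

    def test_missing_band_rejected(self):
        profile = flat_spectrum_profile(1.0)
        profile.ed = {490.0: profile.ed[490.0]}
        with pytest.raises(ValueError, match="PAR band"):
            hp.solar_radiation_at_depth(profile)


# ---------------------------------------------------------------------------
# stable layer detection
# ---------------------------------------------------------------------------

class TestStableSurfaceLayer:
    def test_uniform_density_no_layer(self):
        z = np.arange(1.0, 10.01, 0.5)
        assert hp.detect_stable_surface_layer(z, np.full(z.size, 999.9)) is None

    def test_two_metre_layer(self):
        z = np.arange(1.0, 10.01, 0.5)
        rho = np.where(z <= 3.0, 999.0 + 0.02 * (z - 1.0), 999.04)
        assert hp.detect_stable_surface_layer(z, rho) == pytest.approx(2.0)

    def test_failing_first_interval_means_no_layer(self):
        z = np.arange(1.0, 10.01, 0.5)
        rho = 999.0 + 0.005 * (z - 1.0)  # gradient below threshold everywhere
        assert hp.detect_stable_surface_layer(z, rho) is None

    def test_single_depth_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert hp.detect_stable_surface_layer(np.array([1.0]),
                                                  np.array([999.0])) is None

    def test_raising_threshold_never_deepens_layer(self):
        z = np.arange(1.0, 10.01, 0.5)
        rng = np.random.default_rng(5)
        rho = 999.0 + np.cumsum(rng.uniform(0.0, 0.02, z.size))
        h_values = []
        for threshold in (0.005, 0.01, 0.02, 0.04):
            h = hp.detect_stable_surface_layer(z, rho, threshold)
            h_values.append(0.0 if h is None else h)
        assert h_values == sorted(h_values, reverse=True)


# ---------------------------------------------------------------------------
# Richardson diagnosis
# ---------------------------------------------------------------------------

def convective_profile(e0_uw=40.0, t_test=2.0, below_gradient_c_per_m=0.002,
                       time="2015-02-01 12:00"):
    """Thin cold stable layer over a near-mixed interior, strong light."""
    depths = np.arange(1.0, 17.01, 0.5)
    temps = np.where(depths <= 2.5,
                     1.0 + (t_test - 1.0) * (depths - 1.0) / 1.5,
                     t_test + below_gradient_c_per_m * (depths - 2.5))
    decay = np.exp(-0.5 * depths)
    ed = {lam: e0_uw * decay for lam in (398.76, 450.0, 490.0, 550.0, 620.0,
                                         700.04)}
    return hp.WaterColumnProfile(time=pd.Timestamp(time), depth_m=depths,
                                 temperature_c=temps, ed=ed)


class TestRichardsonDiagnosis:
    def test_requires_detected_layer(self):
        with pytest.raises(ValueError, match="stable surface layer"):
            hp.richardson_diagnosis(convective_profile(), h=None)

    def test_no_sun_no_convection(self):
        profile = convective_profile(e0_uw=0.0)
        d = hp.richardson_diagnosis(profile, h=1.5)
        assert d.q_w_m2 == 0.0 and d.buoyancy_flux_m2_s3 == 0.0
        assert not d.convective and np.isinf(d.richardson)

    def test_warm_test_depth_no_convection(self):
        # alpha > 0 above the density maximum: heating stabilises
        profile = convective_profile(t_test=6.0)
        d = hp.richardson_diagnosis(profile, h=1.5)
        assert d.alpha_per_c > 0
        assert d.buoyancy_flux_m2_s3 < 0 and not d.convective

    def test_convective_case_matches_hand_computation(self):
        """Plug-in oracle: assemble b, w*, N², Ri independently from the
        module's own EOS pieces and a hand trapezoid of the spectrum."""
        profile = convective_profile()
        z_grid, rho = hp.density_profile(profile)
        h = hp.detect_stable_surface_layer(z_grid, rho)
        assert h == pytest.approx(1.5)
        d = hp.richardson_diagnosis(profile, h)

        z_test = 1.0 + h
        t_test = 2.0
        alpha = hp.thermal_expansibility(t_test, 0.0, z_test)
        cp = hp.specific_heat(t_test)
        rho_test = hp.density(t_test, 0.0, z_test)
        q = (40.0 * np.exp(-0.5 * z_test)) * (700.04 - 398.76) * 1e-2 / 0.75
        b = -9.81 * alpha * q / (rho_test * cp)
        w_star = (b * h) ** (1 / 3)
        grad_below = (hp.density(2.0 + 0.002 * 0.5, 0.0, 0.0)
                      - hp.density(2.0, 0.0, 0.0)) / 0.5
        n2 = 9.81 / rho_test * grad_below
        ri = n2 * h**2 / w_star**2

        assert d.q_w_m2 == pytest.approx(q, rel=1e-6)
        assert d.buoyancy_flux_m2_s3 == pytest.approx(b, rel=1e-6)
        assert d.w_star_m_s == pytest.approx(w_star, rel=1e-6)
        assert d.n_squared_s2 == pytest.approx(n2, rel=1e-3)
        assert d.richardson == pytest.approx(ri, rel=1e-3)
        assert b > 0 and ri <= 1.0 and d.convective

    def test_each_condition_is_necessary(self):
        """Removing any of {α<0, Q>0, Ri≤1} flips a convective case."""
        base = hp.richardson_diagnosis(convective_profile(), h=1.5)
        assert base.convective
        no_sun = hp.richardson_diagnosis(convective_profile(e0_uw=0.0), h=1.5)
        warm = hp.richardson_diagnosis(convective_profile(t_test=6.0), h=1.5)
        stratified = hp.richardson_diagnosis(
            convective_profile(below_gradient_c_per_m=2.0), h=1.5)
        assert not no_sun.convective       # Q > 0 removed
        assert not warm.convective         # alpha < 0 removed
        assert not stratified.convective   # Ri <= 1 removed
        assert stratified.richardson > 1.0


class TestSeasonDiagnosis:
    def test_stable_winter_layers_but_never_convective(self):
        times = pd.date_range("2015-02-01", periods=24, freq="2h")
        profiles = sd.generate_profiles(sd.scenario_stable_winter(), times)
        diagnoses = hp.season_diagnosis(profiles, salinity_g_l=0.02)
        assert all(d.stable_layer_thickness_m is not None for d in diagnoses)
        assert not any(d.convective for d in diagnoses)

    def test_clear_ice_heating_convects_at_midday(self):
        times = pd.date_range("2015-02-01", periods=12, freq="2h")
        profiles = sd.generate_profiles(sd.scenario_clear_ice_heating(), times)
        table = hp.diagnosis_table(hp.season_diagnosis(profiles, 0.02))
        assert table["convective"].sum() >= 1
        # night profiles are never convective
        night = pd.to_datetime(table["time"]).dt.hour.isin([0, 2, 4, 22])
        assert not table.loc[night, "convective"].any()

    def test_isothermal_autumn_has_no_layers(self):
        times = pd.date_range("2014-11-01", periods=6, freq="4h")
        profiles = sd.generate_profiles(sd.scenario_isothermal_autumn(), times)
        diagnoses = hp.season_diagnosis(profiles, 0.02)
        assert all(d.stable_layer_thickness_m is None for d in diagnoses)
        assert not any(d.convective for d in diagnoses)
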