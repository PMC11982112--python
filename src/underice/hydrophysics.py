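"""Water-column physics for under-ice convective-mixing diagnostics.

Under thick snow and ice, a lake is inversely stratified: cold, light water
(T < 4 °C) overlies warmer, denser water near the temperature of maximum
density. When enough solar radiation penetrates clear ice, it heats that cold
near-surface water, makes it denser, and can drive penetrative convection
*below* the stable surface layer that hugs the ice.

This module computes, per profile:

* volumetric salinity (g L⁻¹) from major-ion chemistry plus a two-pK
  carbonate speciation of DIC at the measured pH,
* density ρ(T, S, p) from a Chen–Millero-type limnological polynomial
  (coefficients in ``data/eos_chen_millero.json``),
* thermal expansibility α and specific heat c_p consistent with that EOS,
* scalar solar radiation at depth Q(z) from band-integrated planar PAR
  divided by 0.75,
* the stable-surface-layer thickness h from the 0.5-m density-gradient
  criterion (∂ρ/∂z > 0.01 kg m⁻⁴),
* the Richardson-number convection test: buoyancy flux b = −gαQ/(ρc_p),
  convective velocity w* = (bh)^{1/3}, buoyancy frequency N², and
  Ri = N²h²/w*²; convection is diagnosed iff Ri ≤ 1 and b > 0 (which
  requires α < 0, i.e. water below the density maximum).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

G = 9.81  # m s⁻²
SCALAR_IRRADIANCE_DIVISOR = 0.75
PAR_BAND_NM = (398.76, 700.04)
STABILITY_THRESHOLD = 0.01  # kg m⁻⁴
GRADIENT_INTERVAL_M = 0.5
ALPHA_FD_STEP_C = 0.01

# first/second dissociation of carbonic acid (freshwater, ~25 °C)
PK1, PK2 = 6.35, 10.33
MOLAR_MASS = {"CO2": 44.009, "HCO3": 61.016, "CO3": 60.008, "H": 1.008, "OH": 17.008}


def _load_eos() -> dict:
    with resources.files("underice.data").joinpath("eos_chen_millero.json").open() as fh:
        return json.load(fh)


_EOS = _load_eos()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ChemistryTable:
    """Major-ion concentrations (mg L⁻¹) of a dilute lake water sample."""

    ca: float = 0.0
    mg: float = 0.0
    na: float = 0.0
    k: float = 0.0
    cl: float = 0.0
    so4: float = 0.0
    nh4: float = 0.0
    no3: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.ion_concentrations().items():
            if value < 0:
                raise ValueError(f"negative concentration for {name}: {value}")

    def ion_concentrations(self) -> dict:
        return {
            "ca": self.ca, "mg": self.mg, "na": self.na, "k": self.k,
            "cl": self.cl, "so4": self.so4, "nh4": self.nh4, "no3": self.no3,
        }


def default_chemistry() -> ChemistryTable:
    """Dilute soft-water lake chemistry typical of the Eastern Townships."""
    return ChemistryTable(ca=5.0, mg=1.2, na=2.5, k=0.6, cl=3.0, so4=4.0,
                          nh4=0.02, no3=0.15)


@dataclass
class WaterColumnProfile:
    """One depth-resolved cast of environmental measurements.

    ``ed`` maps wavelength (nm) to planar downwelling irradiance
    (µW cm⁻² nm⁻¹) aligned with ``depth_m``; NaN marks gaps.
    """

    time: pd.Timestamp
    depth_m: np.ndarray
    temperature_c: np.ndarray
    conductivity_s_per_m: Optional[np.ndarray] = None
    pressure_dbar: Optional[np.ndarray] = None
    ed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = pd.Timestamp(self.time)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        if self.depth_m.size != self.temperature_c.size:
            raise ValueError("depth and temperature lengths differ")
        if self.depth_m.size >= 2 and not np.all(np.diff(self.depth_m) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.temperature_c <= -1.0):
            raise ValueError("temperature out of range (must exceed -1 °C)")
        if self.pressure_dbar is None:
            # hydrostatic approximation: 1 m ≈ 1 dbar in fresh water
            self.pressure_dbar = self.depth_m.copy()
        else:
            self.pressure_dbar = np.asarray(self.pressure_dbar, dtype=float)
        if self.conductivity_s_per_m is not None:
            self.conductivity_s_per_m = np.asarray(self.conductivity_s_per_m, dtype=float)
        self.ed = {float(lam): np.asarray(v, dtype=float) for lam, v in self.ed.items()}
        for lam, values in self.ed.items():
            if values.size != self.depth_m.size:
                raise ValueError(f"irradiance channel {lam} length mismatch")
            finite = values[np.isfinite(values)]
            if np.any(finite < 0):
                raise ValueError("irradiance must be non-negative")

    @property
    def is_empty(self) -> bool:
        return self.depth_m.size == 0


@dataclass
class StabilityDiagnosis:
    """Physics outputs of the convective-mixing test for one profile."""

    time: pd.Timestamp
    depth_grid_m: np.ndarray
    rho_kg_m3: np.ndarray
    drho_dz: np.ndarray  # per 0.5-m interval, kg m⁻⁴
    stable_layer_thickness_m: Optional[float]
    alpha_per_c: float = np.nan
    cp_j_kg_c: float = np.nan
    q_w_m2: float = np.nan
    buoyancy_flux_m2_s3: float = np.nan
    w_star_m_s: float = np.nan
    n_squared_s2: float = np.nan
    richardson: float = np.nan
    convective: bool = False


# ---------------------------------------------------------------------------
# salinity and equation of state
# ---------------------------------------------------------------------------

def carbonate_speciation(ph: float) -> tuple[float, float, float]:
    """Fractions (CO₂*, HCO₃⁻, CO₃²⁻) of DIC at the given pH (two-pK model)."""
    h = 10.0 ** (-ph)
    k1, k2 = 10.0 ** -PK1, 10.0 ** -PK2
    denom = 1.0 + k1 / h + k1 * k2 / h**2
    a0 = 1.0 / denom
    return a0, a0 * k1 / h, a0 * k1 * k2 / h**2


def volumetric_salinity(chem: ChemistryTable, ph: float, dic_mol_per_l: float = 0.0) -> float:
    """Total dissolved-solids concentration S in g L⁻¹.

    Sums the major-ion mass concentrations, the carbonate-system species
    partitioned from DIC by pH, and the H⁺/OH⁻ contribution of the pH itself.
    """
    if not 4.0 <= ph <= 11.0:
        raise ValueError(f"pH {ph} outside [4, 11]")
    if dic_mol_per_l < 0:
        raise ValueError("DIC must be non-negative")
    s_ions = sum(chem.ion_concentrations().values()) / 1000.0  # mg/L → g/L
    a0, a1, a2 = carbonate_speciation(ph)
    s_carb = dic_mol_per_l * (
        a0 * MOLAR_MASS["CO2"] + a1 * MOLAR_MASS["HCO3"] + a2 * MOLAR_MASS["CO3"]
    )
    s_ph = 10.0 ** (-ph) * MOLAR_MASS["H"] + 10.0 ** (ph - 14.0) * MOLAR_MASS["OH"]
    return s_ions + s_carb + s_ph


def _check_range(t_c, s_g_l, p_dbar) -> None:
    lo_t, hi_t = _EOS["valid_range"]["T_c"]
    lo_s, hi_s = _EOS["valid_range"]["S_g_per_l"]
    lo_p, hi_p = _EOS["valid_range"]["p_dbar"]
    t, s, p = np.asarray(t_c), np.asarray(s_g_l), np.asarray(p_dbar)
    if np.any(t < lo_t) or np.any(t > hi_t):
        raise ValueError(f"temperature outside [{lo_t}, {hi_t}] °C")
    if np.any(s < lo_s) or np.any(s > hi_s):
        raise ValueError(f"salinity outside [{lo_s}, {hi_s}] g/L")
    if np.any(p < lo_p) or np.any(p > hi_p):
        raise ValueError(f"pressure outside [{lo_p}, {hi_p}] dbar")


def density(t_c, s_g_l=0.0, p_dbar=0.0):
    """Water density ρ (kg m⁻³) from the limnological polynomial EOS.

    At S=0, p=0 the polynomial has its single interior maximum at ~3.98 °C,
    the temperature of maximum density of fresh water.
    """
    _check_range(t_c, s_g_l, p_dbar)
    t = np.asarray(t_c, dtype=float)
    s = np.asarray(s_g_l, dtype=float)
    p_bar = np.asarray(p_dbar, dtype=float) / 10.0
    rho0 = np.polynomial.polynomial.polyval(t, _EOS["rho0_coeffs"])
    rho = rho0 + np.polynomial.polynomial.polyval(t, _EOS["salinity_coeffs"]) * s
    bm = _EOS["bulk_modulus"]
    k = (np.polynomial.polynomial.polyval(t, bm["k0_coeffs"])
         + np.polynomial.polynomial.polyval(t, bm["kp_coeffs"]) * p_bar
         + s * (bm["ks_coeffs"][0] + bm["ks_coeffs"][1] * t + bm["ks_coeffs"][2] * p_bar))
    out = rho / (1.0 - p_bar / k)
    return float(out) if np.isscalar(t_c) and np.isscalar(s_g_l) and np.isscalar(p_dbar) else out


def thermal_expansibility(t_c, s_g_l=0.0, p_dbar=0.0, step_c: float = ALPHA_FD_STEP_C):
    """α = −(1/ρ)·∂ρ/∂T (°C⁻¹), centred finite difference on :func:`density`.

    Negative below the temperature of maximum density (~4 °C), ~0 at it,
    positive above — the sign that gates radiatively driven convection.
    """
    t = np.asarray(t_c, dtype=float)
    lo_t, hi_t = _EOS["valid_range"]["T_c"]
    t_plus = np.minimum(t + step_c / 2.0, hi_t)
    t_minus = np.maximum(t - step_c / 2.0, lo_t)
    drho = density(t_plus, s_g_l, p_dbar) - density(t_minus, s_g_l, p_dbar)
    alpha = -drho / (t_plus - t_minus) / density(t, s_g_l, p_dbar)
    return float(alpha) if np.isscalar(t_c) else alpha


def specific_heat(t_c, s_g_l=0.0):
    """Specific heat capacity c_p (J kg⁻¹ °C⁻¹) of dilute lake water."""
    _check_range(t_c, s_g_l, 0.0)
    t = np.asarray(t_c, dtype=float)
    cp = (np.polynomial.polynomial.polyval(t, _EOS["cp0_coeffs"])
          + np.polynomial.polynomial.polyval(t, _EOS["cps_coeffs"]) * np.asarray(s_g_l))
    return float(cp) if np.isscalar(t_c) else cp


# ---------------------------------------------------------------------------
# irradiance
# ---------------------------------------------------------------------------

def solar_radiation_at_depth(profile: WaterColumnProfile) -> np.ndarray:
    """Scalar solar radiation Q(z) in W m⁻² at the profile's depths.

    Band-integrates the spectral planar irradiance over the PAR band
    (398.76–700.04 nm) by the trapezoid rule, converts µW cm⁻² to W m⁻²
    (×0.01), and divides by 0.75 to approximate scalar from planar
    irradiance.
    """
    lams = np.array(sorted(lam for lam in profile.ed
                           if PAR_BAND_NM[0] <= lam <= PAR_BAND_NM[1]))
    if lams.size < 2 or lams.min() > 450.0 or lams.max() < 650.0:
        raise ValueError("spectral irradiance does not cover the PAR band")
    spectra = np.vstack([profile.ed[lam] for lam in lams])  # (n_lam, n_depth)
    par_planar = np.trapezoid(spectra, lams, axis=0) * 1e-2  # W m⁻²
    return par_planar / SCALAR_IRRADIANCE_DIVISOR


# ---------------------------------------------------------------------------
# stability and Richardson diagnosis
# ---------------------------------------------------------------------------

def density_profile(profile: WaterColumnProfile, salinity_g_l: float = 0.0,
                    dz: float = GRADIENT_INTERVAL_M,
                    reference_pressure_dbar: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Potential density resampled to a regular ``dz`` grid.

    Stability gradients use density referenced to a common pressure
    (surface by default) so that adiabatic compression — ~0.005 kg m⁻⁴ even
    in a perfectly mixed column — does not masquerade as stratification.
    Starts at the first valid depth.
    """
    rho = density(profile.temperature_c, salinity_g_l, reference_pressure_dbar)
    z0, z1 = profile.depth_m[0], profile.depth_m[-1]
    grid = np.arange(z0, z1 + 1e-9, dz)
    return grid, np.interp(grid, profile.depth_m, rho)


def detect_stable_surface_layer(z_grid: np.ndarray, rho: np.ndarray,
                                threshold: float = STABILITY_THRESHOLD) -> Optional[float]:
    """Thickness h (m) of the stable surface layer, or ``None``.

    An interval is stable iff ∂ρ/∂z > ``threshold`` (kg m⁻⁴). h is the extent
    of the maximal contiguous stable run starting at the first valid depth;
    if the very first interval fails the criterion no layer is diagnosed.
    """
    z_grid, rho = np.asarray(z_grid, float), np.asarray(rho, float)
    if z_grid.size < 2:
        warnings.warn("fewer than two valid depths; no layer diagnosed")
        return None
    grad = np.diff(rho) / np.diff(z_grid)
    stable = grad > threshold
    if not stable[0]:
        return None
    n = int(np.argmin(stable)) if not stable.all() else stable.size
    return float(z_grid[n] - z_grid[0])


def richardson_diagnosis(profile: WaterColumnProfile, h: Optional[float],
                         salinity_g_l: float = 0.0,
                         threshold: float = STABILITY_THRESHOLD,
                         n2_mode: str = "below") -> StabilityDiagnosis:
    """Convective-mixing test at the base of the stable surface layer.

    b = −gαQ/(ρc_p) at the test depth (positive when α < 0 under heating:
    convection-driving); w* = (bh)^{1/3} for b > 0 else 0; N² from the
    density gradient at the convective test depth — by default the first
    0.5-m interval *below* the layer base, where a convective layer would
    form (``n2_mode="layer"`` uses the within-layer mean gradient instead);
    Ri = N²h²/w*² (∞ when w* = 0). Convective ⇔ Ri ≤ 1 and b > 0.
    """
    if h is None:
        raise ValueError("no stable surface layer: run detect_stable_surface_layer first")
    if n2_mode not in ("below", "layer"):
        raise ValueError(f"unknown n2_mode {n2_mode!r}")
    z_grid, rho = density_profile(profile, salinity_g_l)
    grad = np.diff(rho) / np.diff(z_grid)
    z_test = z_grid[0] + h
    t_test = float(np.interp(z_test, profile.depth_m, profile.temperature_c))
    p_test = float(np.interp(z_test, profile.depth_m, profile.pressure_dbar))
    rho_test = float(density(t_test, salinity_g_l, p_test))
    alpha = float(thermal_expansibility(t_test, salinity_g_l, p_test))
    cp = float(specific_heat(t_test, salinity_g_l))
    q_all = solar_radiation_at_depth(profile)
    q = float(np.interp(z_test, profile.depth_m, q_all))

    b = -G * alpha * q / (rho_test * cp)
    w_star = (b * h) ** (1.0 / 3.0) if b > 0 else 0.0

    n_layer = max(1, int(round(h / GRADIENT_INTERVAL_M)))
    if n2_mode == "below" and n_layer < grad.size:
        grad_test = grad[n_layer]
    else:
        grad_test = float(np.mean(grad[:n_layer]))
    n2 = max(0.0, G / rho_test * grad_test)
    ri = np.inf if w_star == 0.0 else n2 * h**2 / w_star**2
    return StabilityDiagnosis(
        time=profile.time, depth_grid_m=z_grid, rho_kg_m3=rho, drho_dz=grad,
        stable_layer_thickness_m=h, alpha_per_c=alpha, cp_j_kg_c=cp, q_w_m2=q,
        buoyancy_flux_m2_s3=b, w_star_m_s=w_star, n_squared_s2=n2,
        richardson=float(ri), convective=bool(ri <= 1.0 and b > 0.0),
    )


def season_diagnosis(profiles, salinity_g_l: float = 0.0,
                     threshold: float = STABILITY_THRESHOLD,
                     n2_mode: str = "below") -> list[StabilityDiagnosis]:
    """Run the stable-layer + Richardson diagnosis over a profile time series."""
    out = []
    for profile in sorted(profiles, key=lambda pr: pr.time):
        z_grid, rho = density_profile(profile, salinity_g_l)
        h = detect_stable_surface_layer(z_grid, rho, threshold)
        if h is None:
            out.append(StabilityDiagnosis(
                time=profile.time, depth_grid_m=z_grid, rho_kg_m3=rho,
                drho_dz=np.diff(rho) / np.diff(z_grid),
                stable_layer_thickness_m=None))
        else:
            out.append(richardson_diagnosis(profile, h, salinity_g_l, threshold, n2_mode))
    return out


def diagnosis_table(diagnoses) -> pd.DataFrame:
    """Flatten a list of :class:`StabilityDiagnosis` into one row per profile."""
    rows = []
    for d in diagnoses:
        rows.append({
            "time": d.time,
            "stable_layer_thickness_m": d.stable_layer_thickness_m,
            "alpha_per_c": d.alpha_per_c,
            "cp_j_kg_c": d.cp_j_kg_c,
            "q_w_m2": d.q_w_m2,
            "buoyancy_flux_m2_s3": d.buoyancy_flux_m2_s3,
            "w_star_m_s": d.w_star_m_s,
            "n_squared_s2": d.n_squared_s2,
            "richardson": d.richardson,
            "convective": d.convective,
        })
    return pd.DataFrame(rows)
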