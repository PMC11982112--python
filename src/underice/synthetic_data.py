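"""Synthetic IFCB campaigns with known ground truth.

Emulates a winter deployment of an imaging-in-flow cytometer moored under
lake ice: ~25-min sampling cadence from a 5-mL syringe at a ladder of
depths (with ~5× higher frequency at the shallow depths), grayscale ROI
images of six diatom morphotypes with seasonal abundance trajectories,
inversely stratified temperature profiles, snow/ice-attenuated spectral
irradiance with a diel cycle, and a mid-season flash-lamp step that inflates
the frequency of chloroplast-fragment images.

Every quantity downstream stages estimate (class, biovolume, abundance
trajectory, stable-layer/convection outcome) is known analytically here, so
the whole pipeline is testable without any field data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import draw

from .hydrophysics import WaterColumnProfile

SHAPE_FAMILIES = (
    "star_colony",
    "needle",
    "cylinder_with_chloroplasts",
    "ribbon_colony",
    "zigzag_colony",
    "disk",
)

MIN_RENDERED_EXTENT_UM = 10.0  # IFCB trigger threshold for whole organisms
IRRADIANCE_WAVELENGTHS_NM = (398.76, 420.0, 450.0, 490.0, 520.0, 550.0,
                             580.0, 610.0, 650.0, 700.04)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TaxonModel:
    """Generative model of one taxon's morphology and seasonal abundance.

    Sizes are lognormal in µm (median, log-sigma). ``abundance_trajectory``
    maps time (days since campaign start) to the expected number of images
    per sample at the reference (surface) depth; ``depth_scale_m`` applies
    an exponential attenuation exp(−depth/scale) on top of it.
    ``frustule_loss_prob`` is the chance an individual is imaged only as its
    chloroplast blobs (the thin-frustule artifact); ground-truth biovolume
    remains that of the full organism.
    """

    name: str
    shape_family: str
    length_median_um: float
    length_sigma: float
    width_median_um: float
    width_sigma: float
    colony_cells: tuple[int, int] = (1, 1)
    frustule_loss_prob: float = 0.0
    abundance_trajectory: Callable[[float], float] = lambda t: 1.0
    depth_scale_m: float = 15.0

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if not 0.0 <= self.frustule_loss_prob <= 1.0:
            raise ValueError("frustule_loss_prob must be in [0, 1]")
        if self.length_sigma < 0 or self.width_sigma < 0:
            raise ValueError("size spreads must be non-negative")
        if self.length_median_um <= 0 or self.width_median_um <= 0:
            raise ValueError("size distributions must be strictly positive")
        lo, hi = self.colony_cells
        if lo < 1 or hi < lo:
            raise ValueError("colony_cells must satisfy 1 <= lo <= hi")

    def expected_images(self, t_days: float, depth_m: float) -> float:
        lam = float(self.abundance_trajectory(t_days)) * math.exp(-depth_m / self.depth_scale_m)
        if lam < 0:
            raise ValueError("abundance trajectory must be non-negative")
        return lam


@dataclass
class CampaignConfig:
    """Sampling geometry of one deployment."""

    start: pd.Timestamp
    end: pd.Timestamp
    depths_m: Sequence[float] = (2.0, 4.0, 10.0, 15.0)
    periods_min: Sequence[float] = (25.0, 25.0, 25.0, 125.0)
    syringe_volume_ml: float = 5.0
    flash_step_time: Optional[pd.Timestamp] = None
    flash_step_factor: float = 1.0
    rng_seed: int = 0
    pixel_scale_um: float = 1.0
    background_mean: float = 30.0
    background_sigma: float = 6.0

    def __post_init__(self) -> None:
        self.start, self.end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if self.syringe_volume_ml <= 0:
            raise ValueError("syringe volume must be positive")
        if list(self.depths_m) != sorted(self.depths_m):
            raise ValueError("depths must be sorted ascending")
        if len(self.depths_m) != len(self.periods_min):
            raise ValueError("one sampling period per depth required")
        if any(p <= 0 for p in self.periods_min):
            raise ValueError("sampling periods must be positive")
        if self.flash_step_time is not None:
            self.flash_step_time = pd.Timestamp(self.flash_step_time)

    def sample_times(self, depth_m: float) -> pd.DatetimeIndex:
        """Samples start at campaign start and recur every period; the last
        partial interval is dropped (a sample needs its full draw window)."""
        period = pd.Timedelta(minutes=float(
            self.periods_min[list(self.depths_m).index(depth_m)]))
        times = []
        t = self.start
        while t + period <= self.end:
            times.append(t)
            t = t + period
        if len(set(times)) != len(times):
            raise ValueError("overlapping sample timestamps at one depth")
        return pd.DatetimeIndex(times)


@dataclass
class ScenarioConfig:
    """Environmental scenario: stratification shape plus light climate.

    Temperature is piecewise linear through (0, surface), (knee, knee_t),
    (bottom_depth, bottom_t). Spectral irradiance is flat across channels at
    ``e0_noon`` (µW cm⁻² nm⁻¹) just below the ice at noon, modulated by a
    diel half-sine, a seasonal envelope, and exp(−k_d·z) with depth.
    """

    name: str
    surface_t_c: float
    knee_depth_m: float
    knee_t_c: float
    bottom_t_c: float
    bottom_depth_m: float = 17.0
    e0_noon_uw_cm2_nm: float = 1.0
    k_d_per_m: float = 0.6
    seasonal_min_frac: float = 0.6
    conductivity_s_per_m: float = 0.005

    def __post_init__(self) -> None:
        for t in (self.surface_t_c, self.knee_t_c, self.bottom_t_c):
            if not 0.0 <= t <= 30.0:
                raise ValueError("temperatures must lie within [0, 30] °C")
        if self.e0_noon_uw_cm2_nm < 0:
            raise ValueError("irradiance must be non-negative")

    def temperature(self, z):
        zs = [0.0, self.knee_depth_m, self.bottom_depth_m]
        ts = [self.surface_t_c, self.knee_t_c, self.bottom_t_c]
        return np.interp(np.asarray(z, float), zs, ts)

    def surface_irradiance(self, time: pd.Timestamp, t0: Optional[pd.Timestamp] = None) -> float:
        """µW cm⁻² nm⁻¹ just under the ice: diel half-sine × seasonal envelope."""
        hour = time.hour + time.minute / 60.0
        diel = max(0.0, math.sin(math.pi * (hour - 6.0) / 12.0))
        if t0 is None:
            seasonal = 1.0
        else:
            t_days = (time - pd.Timestamp(t0)) / pd.Timedelta(days=1)
            seasonal = self.seasonal_min_frac + (1 - self.seasonal_min_frac) * \
                0.5 * (1 + math.cos(2 * math.pi * (t_days % 365) / 365))
        return self.e0_noon_uw_cm2_nm * diel * seasonal


def scenario_stable_winter() -> ScenarioConfig:
    """Thick snow over ice: inverse stratification, weak light.

    Strong near-surface density gradient (stable layer) over a weakly
    stratified interior; irradiance too low for the buoyancy flux to beat
    the remaining stratification, so convection is never diagnosed.
    """
    return ScenarioConfig("stable_winter", surface_t_c=0.8, knee_depth_m=3.0,
                          knee_t_c=2.6, bottom_t_c=3.5,
                          e0_noon_uw_cm2_nm=0.8, k_d_per_m=0.6)


def scenario_clear_ice_heating() -> ScenarioConfig:
    """Clear, snow-free ice: strong midday light over a near-mixed interior.

    A thin cold stable layer hugs the ice; below it the column is almost
    isothermal at ~2 °C (α < 0), so midday radiative heating produces a
    positive buoyancy flux against negligible stratification and convection
    is diagnosed.
    """
    return ScenarioConfig("clear_ice_heating", surface_t_c=1.0, knee_depth_m=2.5,
                          knee_t_c=2.0, bottom_t_c=2.03,
                          e0_noon_uw_cm2_nm=40.0, k_d_per_m=0.5,
                          seasonal_min_frac=0.9)


def scenario_isothermal_autumn() -> ScenarioConfig:
    """Pre-ice, wind-mixed column: uniform temperature, no stable layer."""
    return ScenarioConfig("isothermal_autumn", surface_t_c=6.0, knee_depth_m=3.0,
                          knee_t_c=6.0, bottom_t_c=6.0,
                          e0_noon_uw_cm2_nm=20.0, k_d_per_m=0.5)


def load_config_yaml(path) -> tuple[CampaignConfig, ScenarioConfig]:
    """Campaign + scenario from a YAML file.

    ``scenario`` may be a named preset (string) or a mapping of
    :class:`ScenarioConfig` fields; ``campaign`` maps
    :class:`CampaignConfig` fields.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scenario = raw["scenario"]
    scenario = (get_scenario(scenario) if isinstance(scenario, str)
                else ScenarioConfig(**scenario))
    return CampaignConfig(**raw["campaign"]), scenario


def get_scenario(name: str) -> ScenarioConfig:
    factories = {
        "stable_winter": scenario_stable_winter,
        "clear_ice_heating": scenario_clear_ice_heating,
        "isothermal_autumn": scenario_isothermal_autumn,
    }
    try:
        return factories[name]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}") from None


# ---------------------------------------------------------------------------
# trajectories and default taxa
# ---------------------------------------------------------------------------

def gaussian_bump(peak_day: float, width_days: float, base: float, peak: float):
    """Seasonal abundance pulse: base + (peak−base)·exp(−Δt²/2w²)."""
    def traj(t_days: float) -> float:
        return base + (peak - base) * math.exp(-0.5 * ((t_days - peak_day) / width_days) ** 2)
    return traj


def declining(start_value: float, end_value: float, span_days: float):
    """Exponential decline from start to end over the season."""
    rate = math.log(end_value / start_value) / span_days
    return lambda t_days: start_value * math.exp(rate * t_days)


def dip_recovery(base: float, dip_day: float, dip_frac: float, width_days: float):
    """Flat trajectory with a transient fractional dip (e.g. 30%) mid-season."""
    def traj(t_days: float) -> float:
        return base * (1 - dip_frac * math.exp(-0.5 * ((t_days - dip_day) / width_days) ** 2))
    return traj


def default_taxa(season_days: float = 28.0) -> list[TaxonModel]:
    """Six winter diatom morphotypes with distinct shapes and trajectories."""
    d = season_days
    return [
        TaxonModel("Asterionella", "star_colony", 55.0, 0.10, 3.5, 0.08,
                   colony_cells=(4, 8), depth_scale_m=60.0,
                   abundance_trajectory=gaussian_bump(0.35 * d, 0.25 * d, 1.2, 9.0)),
        TaxonModel("cf_Synedra", "needle", 75.0, 0.10, 3.0, 0.08,
                   depth_scale_m=25.0,
                   abundance_trajectory=gaussian_bump(0.1 * d, 0.3 * d, 1.0, 8.0)),
        TaxonModel("Urosolenia", "cylinder_with_chloroplasts", 32.0, 0.12, 7.0, 0.08,
                   frustule_loss_prob=0.5, depth_scale_m=8.0,
                   abundance_trajectory=declining(10.0, 1.2, d)),
        TaxonModel("Fragilaria", "ribbon_colony", 35.0, 0.10, 4.0, 0.08,
                   colony_cells=(3, 7), depth_scale_m=40.0,
                   abundance_trajectory=gaussian_bump(0.7 * d, 0.25 * d, 1.0, 6.0)),
        TaxonModel("Tabellaria", "zigzag_colony", 40.0, 0.10, 6.0, 0.08,
                   colony_cells=(3, 6), depth_scale_m=40.0,
                   abundance_trajectory=gaussian_bump(0.5 * d, 0.22 * d, 1.0, 5.0)),
        TaxonModel("round_diatoms", "disk", 18.0, 0.10, 18.0, 0.10,
                   depth_scale_m=30.0,
                   abundance_trajectory=gaussian_bump(0.9 * d, 0.3 * d, 1.0, 7.0)),
    ]


# ---------------------------------------------------------------------------
# ROI rendering
# ---------------------------------------------------------------------------

def _rect_polygon(cx, cy, length, width, angle_rad):
    """Corner coordinates (rows, cols) of a rotated rectangle."""
    dx, dy = math.cos(angle_rad), math.sin(angle_rad)
    nx, ny = -dy, dx
    hl, hw = length / 2.0, width / 2.0
    corners = []
    for sl, sw in ((-1, -1), (-1, 1), (1, 1), (1, -1)):
        corners.append((cy + sl * hl * dy + sw * hw * ny,
                        cx + sl * hl * dx + sw * hw * nx))
    rr = np.array([c[0] for c in corners])
    cc = np.array([c[1] for c in corners])
    return rr, cc


def _cylinder_volume(length_um: float, width_um: float) -> float:
    return math.pi * (width_um / 2.0) ** 2 * length_um


def _render_primitives(prims, pixel_scale: float, rng: np.random.Generator,
                       bg_mean: float, bg_sigma: float,
                       object_mean: float = 170.0, object_sigma: float = 14.0):
    """Rasterise rectangle/ellipse primitives (µm coords) into an 8-bit ROI."""
    all_r, all_c = [], []
    for kind, params in prims:
        if kind == "rect":
            rr, cc = _rect_polygon(*params)
        else:  # ellipse: (cx, cy, r_x, r_y)
            cx, cy, rx, ry = params
            rr, cc = np.array([cy - ry, cy + ry]), np.array([cx - rx, cx + rx])
        all_r.append(rr / pixel_scale)
        all_c.append(cc / pixel_scale)
    rmin = min(r.min() for r in all_r)
    cmin = min(c.min() for c in all_c)
    margin = 6
    rmax = max(r.max() for r in all_r) - rmin
    cmax = max(c.max() for c in all_c) - cmin
    shape = (int(math.ceil(rmax)) + 2 * margin + 1, int(math.ceil(cmax)) + 2 * margin + 1)
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("non-positive image dimensions")
    mask = np.zeros(shape, dtype=bool)
    for kind, params in prims:
        if kind == "rect":
            rr, cc = _rect_polygon(*params)
            rr = rr / pixel_scale - rmin + margin
            cc = cc / pixel_scale - cmin + margin
            pr, pc = draw.polygon(rr, cc, shape=shape)
        else:
            cx, cy, rx, ry = params
            pr, pc = draw.ellipse((cy / pixel_scale) - rmin + margin,
                                  (cx / pixel_scale) - cmin + margin,
                                  max(ry / pixel_scale, 1.0),
                                  max(rx / pixel_scale, 1.0), shape=shape)
        mask[pr, pc] = True
    image = rng.normal(bg_mean, bg_sigma, shape)
    image[mask] = rng.normal(object_mean, object_sigma, int(mask.sum()))
    return np.clip(image, 0, 255).astype(np.uint8)


def _chloroplast_fragments(rng, length, width):
    """2–4 small elliptical blobs strung along where the cell axis would be."""
    n = int(rng.integers(2, 5))
    prims = []
    for i in range(n):
        cx = (i + 0.5) / n * length
        cy = rng.normal(0.0, width / 4.0)
        r = rng.uniform(1.5, 3.0)
        prims.append(("ellipse", (cx, cy, r, r * rng.uniform(0.6, 1.0))))
    return prims


def generate_roi(taxon: TaxonModel, rng: np.random.Generator,
                 pixel_scale_um: float = 1.0,
                 background_mean: float = 30.0, background_sigma: float = 6.0,
                 force_fragment: Optional[bool] = None):
    """Render one ROI; returns (image, true_class, true_biovolume_um3).

    The true biovolume is computed analytically from the generative solid
    (cylinders for elongate cells, a sphere for disks), summed over colony
    cells. A frustule-loss draw renders only chloroplast blobs but keeps the
    full-organism biovolume as ground truth.
    """
    if pixel_scale_um <= 0:
        raise ValueError("pixel scale must be positive")
    length = float(rng.lognormal(math.log(taxon.length_median_um), taxon.length_sigma))
    width = float(rng.lognormal(math.log(taxon.width_median_um), taxon.width_sigma))
    width = min(width, length)
    fragment = (force_fragment if force_fragment is not None
                else bool(rng.random() < taxon.frustule_loss_prob))
    if not fragment:
        length = max(length, MIN_RENDERED_EXTENT_UM + 0.5)
    n_cells = int(rng.integers(taxon.colony_cells[0], taxon.colony_cells[1] + 1))
    fam = taxon.shape_family

    if fam == "disk":
        radius = length / 2.0
        prims = [("ellipse", (0.0, 0.0, radius, radius))]
        biovolume = 4.0 / 3.0 * math.pi * radius**3
    elif fam == "needle":
        prims = [("rect", (0.0, 0.0, length, width, rng.uniform(0, math.pi)))]
        biovolume = _cylinder_volume(length, width)
    elif fam == "cylinder_with_chloroplasts":
        biovolume = _cylinder_volume(length, width)
        if fragment:
            prims = _chloroplast_fragments(rng, length, width)
        else:
            prims = [("rect", (0.0, 0.0, length, width, rng.uniform(0, math.pi)))]
    elif fam == "star_colony":
        # rods joined at one end, fanned around a common origin
        base = rng.uniform(0, 2 * math.pi)
        prims = []
        for i in range(n_cells):
            ang = base + 2 * math.pi * i / n_cells + rng.normal(0, 0.12)
            cx = length / 2.0 * math.cos(ang)
            cy = length / 2.0 * math.sin(ang)
            prims.append(("rect", (cx, cy, length, width, ang)))
        biovolume = n_cells * _cylinder_volume(length, width)
    elif fam == "ribbon_colony":
        # cells stacked side by side, long axes parallel
        ang = rng.uniform(0, math.pi)
        nx, ny = -math.sin(ang), math.cos(ang)
        prims = []
        for i in range(n_cells):
            off = (i - (n_cells - 1) / 2.0) * width * 1.05
            prims.append(("rect", (off * nx, off * ny, length, width, ang)))
        biovolume = n_cells * _cylinder_volume(length, width)
    elif fam == "zigzag_colony":
        # cells chained end to end at alternating angles
        base = rng.uniform(0, math.pi)
        zig = math.radians(40.0)
        prims, x, y = [], 0.0, 0.0
        for i in range(n_cells):
            ang = base + (zig if i % 2 == 0 else -zig)
            cx = x + length / 2.0 * math.cos(ang)
            cy = y + length / 2.0 * math.sin(ang)
            prims.append(("rect", (cx, cy, length, width, ang)))
            x += length * math.cos(ang)
            y += length * math.sin(ang)
        biovolume = n_cells * _cylinder_volume(length, width)
    else:  # pragma: no cover - guarded in TaxonModel
        raise ValueError(fam)

    image = _render_primitives(prims, pixel_scale_um, rng,
                               background_mean, background_sigma)
    return image, taxon.name, float(biovolume)


# ---------------------------------------------------------------------------
# campaigns and profiles
# ---------------------------------------------------------------------------

@dataclass
class CampaignData:
    """In-memory synthetic campaign: samples, per-image manifest, truth."""

    samples: pd.DataFrame       # sample_id, time, depth_m, volume_ml
    manifest: pd.DataFrame      # sample_id, time, depth_m, volume_ml, image_id, image_path
    ground_truth: pd.DataFrame  # sample_id, image_id, image_path, true_class, true_biovolume_um3
    images: dict                # image_id -> uint8 array
    pixel_scale_um: float = 1.0

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for image_id, arr in self.images.items():
            Image.fromarray(arr, mode="L").save(out / "images" / f"{image_id}.png")
        self.samples.to_csv(out / "samples.csv", index=False)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def generate_campaign(campaign: CampaignConfig, scenario: ScenarioConfig,
                      taxa: Sequence[TaxonModel],
                      out_dir=None) -> CampaignData:
    """Simulate every syringe draw of a campaign; deterministic per seed.

    Per sample and taxon, the expected image count is the taxon's abundance
    trajectory at that time × exponential depth attenuation, split into
    whole-organism and chloroplast-fragment draws by ``frustule_loss_prob``;
    after ``flash_step_time`` the fragment rate is multiplied by
    ``flash_step_factor`` (the flash-lamp intensity step).
    """
    rng = np.random.default_rng(campaign.rng_seed)
    sample_rows, manifest_rows, truth_rows = [], [], []
    images: dict[str, np.ndarray] = {}
    seen_ids: set[str] = set()
    for depth in campaign.depths_m:
        for t in campaign.sample_times(depth):
            sample_id = f"D{depth:05.1f}m_{t:%Y%m%dT%H%M}".replace(".", "p")
            if sample_id in seen_ids:
                raise ValueError(f"overlapping sample timestamps at {depth} m")
            seen_ids.add(sample_id)
            sample_rows.append({"sample_id": sample_id, "time": t,
                                "depth_m": depth,
                                "volume_ml": campaign.syringe_volume_ml})
            t_days = (t - campaign.start) / pd.Timedelta(days=1)
            flash = (campaign.flash_step_time is not None
                     and t >= campaign.flash_step_time)
            k = 0
            for taxon in taxa:
                lam = taxon.expected_images(t_days, depth)
                lam_frag = lam * taxon.frustule_loss_prob * \
                    (campaign.flash_step_factor if flash else 1.0)
                lam_whole = lam * (1.0 - taxon.frustule_loss_prob)
                for lam_part, as_fragment in ((lam_whole, False), (lam_frag, True)):
                    if lam_part <= 0:
                        continue
                    for _ in range(int(rng.poisson(lam_part))):
                        image, cls, biovol = generate_roi(
                            taxon, rng, campaign.pixel_scale_um,
                            campaign.background_mean, campaign.background_sigma,
                            force_fragment=as_fragment if
                            taxon.frustule_loss_prob > 0 else None)
                        image_id = f"{sample_id}_{k:04d}"
                        k += 1
                        images[image_id] = image
                        path = f"images/{image_id}.png"
                        manifest_rows.append({
                            "sample_id": sample_id, "time": t, "depth_m": depth,
                            "volume_ml": campaign.syringe_volume_ml,
                            "image_id": image_id, "image_path": path})
                        truth_rows.append({
                            "sample_id": sample_id, "image_id": image_id,
                            "image_path": path, "true_class": cls,
                            "true_biovolume_um3": biovol})
    samples = pd.DataFrame(sample_rows).sort_values(
        ["time", "depth_m"], kind="stable").reset_index(drop=True)
    manifest = pd.DataFrame(manifest_rows,
                            columns=["sample_id", "time", "depth_m", "volume_ml",
                                     "image_id", "image_path"])
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "image_id", "image_path",
                                  "true_class", "true_biovolume_um3"])
    data = CampaignData(samples, manifest, truth, images,
                        campaign.pixel_scale_um)
    if out_dir is not None:
        data.write(out_dir)
    return data


def generate_profiles(scenario: ScenarioConfig, times,
                      depths_m=None, t0=None) -> list[WaterColumnProfile]:
    """One environmental cast per requested time, per the scenario.

    Depths default to 1.0–17.0 m at 0.5 m (the first valid density point of
    the emulated mooring sits at 1 m). Irradiance channels share a flat
    spectrum attenuated as exp(−k_d·z), zero at night.
    """
    times = sorted(pd.Timestamp(t) for t in times)
    if depths_m is None:
        depths_m = np.arange(1.0, 17.01, 0.5)
    depths_m = np.asarray(depths_m, float)
    t0 = times[0] if t0 is None else pd.Timestamp(t0)
    profiles = []
    for t in times:
        e0 = scenario.surface_irradiance(t, t0)
        decay = np.exp(-scenario.k_d_per_m * depths_m)
        ed = {lam: e0 * decay for lam in IRRADIANCE_WAVELENGTHS_NM}
        temp = scenario.temperature(depths_m)
        cond = scenario.conductivity_s_per_m * (1.0 + 0.02 * (temp - temp[0]))
        profiles.append(WaterColumnProfile(
            time=t, depth_m=depths_m, temperature_c=temp,
            conductivity_s_per_m=cond, pressure_dbar=depths_m, ed=ed))
    return profiles
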