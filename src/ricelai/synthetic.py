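"""Seedable synthetic UAV field campaigns for hybrid rice.

Emulates the structure of a paddy breeding trial: 48 plots of distinct hybrid
rice cultivars, flown 13 times across the season with a 12-band multispectral
camera, a canopy DSM and a pre-transplant bare-soil DSM, eight grey
calibration canvases in view, and destructive LAI sampling per plot and date.

The generator reproduces the statistical features the downstream analysis
relies on, without radiative-transfer modelling:

* **Trajectories** — LAI follows a double logistic peaking about 10 days
  before each cultivar's heading date and declining afterwards; canopy height
  follows a logistic that keeps rising until about 5 days after heading, then
  declines slightly as panicles droop.
* **Spectral hysteresis** — canopy reflectance mixes a soil endmember and a
  canopy endmember through a Beer-Lambert gap fraction exp(-k * LAI). After
  heading the canopy endmember blends in a panicle/senescent spectrum
  (logistic "panicle fraction" of days since heading), raising visible
  reflectance and lowering NIR at equal LAI — so every NIR/visible index is
  depressed post-heading, the hysteresis the height-product models remove.
* **Artefacts** — the first flight can carry water specular "bad" pixels
  (DN > 250 in all bands) concentrated in a configurable number of plots,
  mirroring a just-transplanted flooded paddy.

All randomness flows from explicit integer seeds; identical inputs give
bit-identical scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CANVAS_REFLECTANCES, CalibrationModel
from .exceptions import LayoutError
from .indices import WAVELENGTHS_NM

logger = logging.getLogger(__name__)

# Observed ranges of the emulated trial, used as simulation bounds.
HEADING_DAT_RANGE = (59, 73)       # days after transplanting
LAI_MAX_RANGE = (2.76, 8.53)       # unitless
HEIGHT_FINAL_RANGE = (0.82, 1.13)  # m

#: Default flight dates (days after transplanting) of the 13 campaigns,
#: derived from weekly flights between late June and early September with a
#: June 9 transplanting.
DEFAULT_CAMPAIGN_DATS = (17, 23, 27, 35, 43, 48, 53, 58, 63, 68, 74, 81, 86)

#: Beer-Lambert canopy extinction coefficient for the gap fraction.
K_EXTINCTION = 0.6

# Endmember spectra at the 12 band centres (490..950 nm). Values are
# generator constants chosen to reproduce the qualitative pre/post-heading
# contrasts of a rice canopy (visible up >= 1.5-2x after heading at equal
# LAI; NIR close-to-slightly-lower), not measurements. The soil endmember is
# a dark, recently flooded paddy surface.
SOIL_ENDMEMBER = np.array(
    [0.050, 0.060, 0.070, 0.075, 0.050, 0.050, 0.070, 0.100,
     0.130, 0.140, 0.150, 0.150]
)
LEAF_ENDMEMBER = np.array(
    [0.040, 0.070, 0.100, 0.090, 0.030, 0.030, 0.080, 0.250,
     0.500, 0.500, 0.480, 0.450]
)
PANICLE_ENDMEMBER = np.array(
    [0.095, 0.150, 0.260, 0.270, 0.105, 0.109, 0.240, 0.360,
     0.460, 0.460, 0.450, 0.430]
)

# Destructive sampling constants: bundles cut per plot and planting density.
N_BUNDLES = 3
PLANT_DENSITY = 22.5  # bundles / m^2

#: LAI peaks this many days before heading; height this many days after.
LAI_PEAK_LEAD_DAYS = 10
HEIGHT_PEAK_LAG_DAYS = 5

_SOIL_ELEVATION = 30.0  # m, flat paddy base elevation


@dataclass(frozen=True)
class CultivarParams:
    """Phenology parameters of one cultivar driving the simulation."""

    cultivar_id: str
    heading_dat: int       # days after transplanting
    lai_max: float         # peak LAI, unitless
    height_final: float    # m
    green_up_rate: float   # 1/day
    senescence_rate: float # 1/day


@dataclass(frozen=True)
class PlotROI:
    """0-based, half-open pixel rectangle of one plot's observation area."""

    plot_id: str
    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def expected_pixel_count(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass(frozen=True)
class SamplingRecord:
    """Destructive LAI sampling of one plot on one date."""

    plot_id: str
    dat: int
    leaf_areas: tuple[float, ...]  # m^2 per bundle
    n_bundles: int = N_BUNDLES
    plant_density: float = PLANT_DENSITY


@dataclass(frozen=True)
class GridLayout:
    """Raster layout: plots on a grid with a row of canvas panels below."""

    n_plots: int = 48
    n_cols: int = 8
    plot_shape: tuple[int, int] = (20, 40)  # rows, cols (~800 px, as flown)
    pad: int = 4
    canvas_shape: tuple[int, int] = (10, 10)

    @property
    def n_rows(self) -> int:
        return -(-self.n_plots // self.n_cols)

    def raster_shape(self) -> tuple[int, int]:
        ph, pw = self.plot_shape
        h = self.pad + self.n_rows * (ph + self.pad)
        w = self.pad + self.n_cols * (pw + self.pad)
        canvas_w = self.pad + len(CANVAS_REFLECTANCES) * (
            self.canvas_shape[1] + self.pad
        )
        if canvas_w > w:
            raise LayoutError(
                "canvas panel row does not fit the plot grid width"
            )
        h += self.canvas_shape[0] + self.pad
        return h, w

    def plot_roi(self, i: int, plot_id: str) -> PlotROI:
        if i >= self.n_plots:
            raise LayoutError(f"plot index {i} exceeds layout ({self.n_plots})")
        ph, pw = self.plot_shape
        r = i // self.n_cols
        c = i % self.n_cols
        row0 = self.pad + r * (ph + self.pad)
        col0 = self.pad + c * (pw + self.pad)
        return PlotROI(plot_id, row0, col0, row0 + ph, col0 + pw)

    def canvas_roi(self, j: int) -> PlotROI:
        ch, cw = self.canvas_shape
        row0 = self.pad + self.n_rows * (self.plot_shape[0] + self.pad)
        col0 = self.pad + j * (cw + self.pad)
        return PlotROI(f"canvas_{j}", row0, col0, row0 + ch, col0 + cw)


@dataclass(frozen=True)
class RenderOptions:
    """Noise and artefact settings for scene rendering."""

    pixel_noise_cv: float = 0.03     # per-pixel Gaussian CV per band
    spectrum_noise_cv: float = 0.01  # per-plot spectrum jitter
    f_jitter_sd: float = 0.25       # post-heading senescence-pace jitter
    nir_jitter_sd: float = 0.30     # post-heading NIR architecture jitter
    dsm_noise_sd: float = 0.005     # m, per-pixel DSM noise
    lai_noise_sd: float = 0.05      # destructive-sampling bundle CV
    water_bad_plots: int = 0        # plots hit by water specular pixels
    bad_pixels_per_plot: int = 120  # saturated pixels per affected plot

    def noiseless(self) -> "RenderOptions":
        return replace(self, pixel_noise_cv=0.0, spectrum_noise_cv=0.0,
                       f_jitter_sd=0.0, nir_jitter_sd=0.0,
                       dsm_noise_sd=0.0, lai_noise_sd=0.0)


@dataclass
class CampaignScene:
    """One flight date: DN raster, DSM pair, panel/plot ROIs, ground truth."""

    dat: int
    dn: np.ndarray        # (12, rows, cols) uint8
    dsm: np.ndarray       # (rows, cols) float32, surface elevation (m)
    dsm_soil: np.ndarray  # (rows, cols) float32, pre-transplant elevation
    canvas_panels: list[tuple[PlotROI, float]]
    plot_rois: list[PlotROI]
    truth: pd.DataFrame   # plot_id, cultivar_id, true_lai, true_height, stage
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM


def default_true_calibration() -> CalibrationModel:
    """Plausible per-band sensor response used to invert reflectance to DN."""
    n = len(WAVELENGTHS_NM)
    gain = np.linspace(0.0035, 0.0045, n)
    offset = np.full(n, 0.01)
    return CalibrationModel(gain=gain, offset=offset)


def generate_cultivars(n: int, seed: int) -> list[CultivarParams]:
    """Draw cultivar phenology parameters uniformly within the trial bounds."""
    if n < 1:
        raise ValueError(f"need at least one cultivar, got n={n}")
    rng = np.random.default_rng(seed)
    heading = rng.integers(HEADING_DAT_RANGE[0], HEADING_DAT_RANGE[1] + 1,
                           size=n)
    lai_max = rng.uniform(*LAI_MAX_RANGE, size=n)
    height_final = rng.uniform(*HEIGHT_FINAL_RANGE, size=n)
    # Transplanted rice greens up over weeks and loses leaf area gradually
    # through ripening, so both time scales are slow (tau 6-20 days).
    green_up = rng.uniform(0.10, 0.16, size=n)
    senescence = rng.uniform(0.05, 0.10, size=n)
    return [
        CultivarParams(
            cultivar_id=f"cv{i:02d}",
            heading_dat=int(heading[i]),
            lai_max=float(lai_max[i]),
            height_final=float(height_final[i]),
            green_up_rate=float(green_up[i]),
            senescence_rate=float(senescence[i]),
        )
        for i in range(n)
    ]


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def simulate_trajectories(
    cultivar: CultivarParams, dats
) -> tuple[np.ndarray, np.ndarray]:
    """True (LAI, height) of one cultivar at the given flight dates.

    LAI is a double logistic (green-up times senescence) normalised to peak
    at ``lai_max`` exactly ``LAI_PEAK_LEAD_DAYS`` before heading, declining
    gradually afterwards; height is a Gompertz curve still rising at heading,
    peaking ``HEIGHT_PEAK_LAG_DAYS`` after it, then declining linearly by
    0.15 %/day (panicle droop), floored at 5 % below peak.
    """
    dats = np.atleast_1d(np.asarray(dats, dtype=float))
    if dats.size > 1 and np.any(np.diff(dats) <= 0):
        raise ValueError("flight dates must be strictly ascending")
    if np.any(dats < 0):
        raise ValueError("flight dates must be non-negative")

    peak = cultivar.heading_dat - LAI_PEAK_LEAD_DAYS
    tau_u = 1.0 / cultivar.green_up_rate
    tau_d = 1.0 / cultivar.senescence_rate
    a = peak - 18.0  # green-up midpoint
    # Senescence midpoint placed so the product's maximum sits at `peak`:
    # d/dt log L = sigma(-(t-a)/tau_u)/tau_u - sigma((t-b)/tau_d)/tau_d = 0.
    c = (tau_d / tau_u) * _logistic(-(peak - a) / tau_u)
    b = peak - tau_d * np.log(c / (1.0 - c))

    def unit(t):
        return _logistic((t - a) / tau_u) * _logistic(-(t - b) / tau_d)

    # Baseline-subtract so the transplanting day starts at exactly zero LAI
    # (the raw double logistic has a small tail at t = 0 for slow green-up).
    u0 = unit(0.0)
    lai = cultivar.lai_max * np.maximum(unit(dats) - u0, 0.0) \
        / (unit(peak) - u0)

    # Height: Gompertz growth (fast during tillering, slow near heading) so
    # the canopy leads LAI, still rising through heading; peak 5 days after
    # heading, then a slight linear droop as grains fill.
    h_mid = cultivar.heading_dat - 35.0
    tau_h = 12.0
    t_hpeak = cultivar.heading_dat + HEIGHT_PEAK_LAG_DAYS

    def gompertz(t):
        return cultivar.height_final * np.exp(-np.exp(-(t - h_mid) / tau_h))

    h_peak = gompertz(t_hpeak)
    decline = np.maximum(0.95, 1.0 - 0.0015 * (dats - t_hpeak))
    height = np.where(dats <= t_hpeak, gompertz(dats), h_peak * decline)
    return lai, height


def panicle_fraction(dat_minus_heading: float) -> float:
    """Fraction of the canopy endmember contributed by panicle/senescent
    material; zero before heading, logistic in days since heading after it."""
    d = float(dat_minus_heading)
    if d < 0:
        return 0.0
    return float(_logistic((d - 5.0) / 3.0))


_NIR_BAND_SLICE = slice(8, 12)  # 800-950 nm


def simulate_spectrum(
    lai: float,
    dat_minus_heading: float,
    seed: int,
    noise_cv: float = 0.01,
    f_jitter_sd: float = 0.25,
    nir_jitter_sd: float = 0.30,
) -> np.ndarray:
    """12-band canopy reflectance for one plot state.

    Two-endmember mixing with a Beer-Lambert gap fraction:
    rho = soil * exp(-k*LAI) + canopy(stage) * (1 - exp(-k*LAI)), where the
    canopy endmember shifts from leaf to panicle/senescent material after
    heading. Post-heading samples additionally carry seeded jitter in the
    panicle fraction (plots senesce at different paces) and a common
    multiplicative fluctuation of the NIR bands (droopy panicles rearrange
    the canopy architecture), both scaled by canopy cover so the zero-LAI
    limit stays exactly the soil endmember. Small multiplicative Gaussian
    noise on top, seeded.
    """
    if lai < 0:
        raise ValueError(f"LAI must be non-negative, got {lai}")
    rng = np.random.default_rng(seed)
    gap = np.exp(-K_EXTINCTION * lai)
    f = panicle_fraction(dat_minus_heading)
    if dat_minus_heading >= 0 and f_jitter_sd > 0:
        f = float(np.clip(f + f_jitter_sd * rng.standard_normal(), 0.0, 1.0))
    canopy = (1.0 - f) * LEAF_ENDMEMBER + f * PANICLE_ENDMEMBER
    rho = SOIL_ENDMEMBER * gap + canopy * (1.0 - gap)
    if dat_minus_heading >= 0 and nir_jitter_sd > 0:
        sd = nir_jitter_sd * (1.0 - gap)
        rho = rho.copy()
        rho[_NIR_BAND_SLICE] *= np.exp(sd * rng.standard_normal())
    if noise_cv > 0:
        rho = rho * (1.0 + noise_cv * rng.standard_normal(rho.shape))
    return np.clip(rho, 0.0, 1.0)


def simulate_destructive_sampling(
    true_lai: float,
    noise_sd: float,
    seed: int,
    plot_id: str = "",
    dat: int = -1,
) -> SamplingRecord:
    """Per-bundle leaf areas whose implied LAI is unbiased for ``true_lai``.

    Inverts LAI = (sum LA) / n * density: each of the ``N_BUNDLES`` bundles
    gets leaf area true_lai / density, times multiplicative Gaussian noise
    (mean 1, sd ``noise_sd``), floored at 0.
    """
    if true_lai < 0 or noise_sd < 0:
        raise ValueError("true_lai and noise_sd must be non-negative")
    base = true_lai / PLANT_DENSITY
    rng = np.random.default_rng(seed)
    factors = 1.0 + noise_sd * rng.standard_normal(N_BUNDLES)
    las = tuple(float(max(0.0, base * f)) for f in factors)
    return SamplingRecord(plot_id=plot_id, dat=dat, leaf_areas=las)


def render_campaign(
    cultivars: list[CultivarParams],
    dat: int,
    true_calibration: CalibrationModel | None = None,
    layout: GridLayout | None = None,
    options: RenderOptions | None = None,
    seed: int = 0,
) -> CampaignScene:
    """Render one flight date into a DN raster, DSM pair and ground truth."""
    if true_calibration is None:
        true_calibration = default_true_calibration()
    if layout is None:
        layout = GridLayout(n_plots=len(cultivars))
    if options is None:
        options = RenderOptions()
    if len(cultivars) > layout.n_plots:
        raise LayoutError(
            f"layout holds {layout.n_plots} plots, got {len(cultivars)} cultivars"
        )
    rng = np.random.default_rng(seed)
    shape = layout.raster_shape()
    n_bands = true_calibration.n_bands

    # background: bare soil reflectance everywhere
    refl = np.empty((n_bands, *shape), dtype=np.float64)
    refl[:] = SOIL_ENDMEMBER[:, None, None]
    dsm_soil = np.full(shape, _SOIL_ELEVATION, dtype=np.float64)
    dsm = dsm_soil.copy()

    plot_rois: list[PlotROI] = []
    rows = []
    for i, cv in enumerate(cultivars):
        roi = layout.plot_roi(i, f"plot{i:02d}")
        plot_rois.append(roi)
        lai_arr, h_arr = simulate_trajectories(cv, [dat])
        lai, h = float(lai_arr[0]), float(h_arr[0])
        spec_seed = int(rng.integers(0, 2**31 - 1))
        spectrum = simulate_spectrum(
            lai, dat - cv.heading_dat, seed=spec_seed,
            noise_cv=options.spectrum_noise_cv,
            f_jitter_sd=options.f_jitter_sd,
            nir_jitter_sd=options.nir_jitter_sd,
        )
        rs, cs = roi.slices()
        px = spectrum[:, None, None] * np.ones(
            (n_bands, roi.row1 - roi.row0, roi.col1 - roi.col0)
        )
        if options.pixel_noise_cv > 0:
            px = px * (1.0 + options.pixel_noise_cv
                       * rng.standard_normal(px.shape))
        refl[:, rs, cs] = np.clip(px, 0.0, 1.0)
        hpx = np.full(px.shape[1:], h)
        if options.dsm_noise_sd > 0:
            hpx = hpx + options.dsm_noise_sd * rng.standard_normal(hpx.shape)
        dsm[rs, cs] = dsm_soil[rs, cs] + np.maximum(hpx, 0.0)
        rows.append(dict(
            plot_id=roi.plot_id, cultivar_id=cv.cultivar_id,
            true_lai=lai, true_height=h,
            stage="pre-heading" if dat < cv.heading_dat else "post-heading",
            heading_dat=cv.heading_dat,
        ))

    canvas_panels = []
    for j, r in enumerate(CANVAS_REFLECTANCES):
        croi = layout.canvas_roi(j)
        rs, cs = croi.slices()
        refl[:, rs, cs] = r  # panels noiseless by design
        canvas_panels.append((croi, r))

    dn = _reflectance_to_dn(refl, true_calibration)

    # water specular contamination: saturate pixels in selected plots
    if options.water_bad_plots > 0:
        n_hit = min(options.water_bad_plots, len(plot_rois))
        hit = rng.choice(len(plot_rois), size=n_hit, replace=False)
        for i in hit:
            roi = plot_rois[i]
            npx = roi.expected_pixel_count
            n_bad = min(options.bad_pixels_per_plot, npx)
            flat = rng.choice(npx, size=n_bad, replace=False)
            rr = roi.row0 + flat // (roi.col1 - roi.col0)
            cc = roi.col0 + flat % (roi.col1 - roi.col0)
            dn[:, rr, cc] = 255
        logger.info("dat %d: water specular pixels in %d plots", dat, n_hit)

    truth = pd.DataFrame(rows)
    return CampaignScene(
        dat=int(dat), dn=dn,
        dsm=dsm.astype(np.float32), dsm_soil=dsm_soil.astype(np.float32),
        canvas_panels=canvas_panels, plot_rois=plot_rois, truth=truth,
        wavelengths_nm=true_calibration.wavelengths_nm,
    )


def _reflectance_to_dn(refl: np.ndarray, cal: CalibrationModel) -> np.ndarray:
    dn = np.rint((refl - cal.offset[:, None, None]) / cal.gain[:, None, None])
    return np.clip(dn, 0, 255).astype(np.uint8)


@dataclass
class SyntheticCampaign:
    """A full multi-date campaign: scenes, sampling records, and metadata."""

    cultivars: list[CultivarParams]
    scenes: list[CampaignScene]
    sampling: list[SamplingRecord]
    true_calibration: CalibrationModel
    seed: int
    options: RenderOptions = field(default_factory=RenderOptions)


def generate_campaign(
    n_cultivars: int = 48,
    dats=DEFAULT_CAMPAIGN_DATS,
    seed: int = 0,
    options: RenderOptions | None = None,
    first_campaign_water: bool = True,
    water_bad_plots: int = 24,
    layout: GridLayout | None = None,
    true_calibration: CalibrationModel | None = None,
) -> SyntheticCampaign:
    """Generate the default study design: 48 cultivars over 13 flight dates.

    When ``first_campaign_water`` is set, the earliest flight receives water
    specular contamination in ``water_bad_plots`` plots (each exceeding the
    100-bad-pixel validity limit), emulating a just-transplanted flooded
    paddy in which only the remaining plots are usable.
    """
    if options is None:
        options = RenderOptions()
    if true_calibration is None:
        true_calibration = default_true_calibration()
    dats = tuple(int(d) for d in dats)
    rng = np.random.default_rng(seed)
    cultivars = generate_cultivars(n_cultivars, int(rng.integers(2**31 - 1)))
    if layout is None:
        layout = GridLayout(n_plots=n_cultivars)

    scenes = []
    sampling: list[SamplingRecord] = []
    for di, dat in enumerate(dats):
        opt = options
        if first_campaign_water and dat == min(dats):
            opt = replace(options, water_bad_plots=water_bad_plots)
        scene_seed = int(rng.integers(2**31 - 1))
        scene = render_campaign(
            cultivars, dat, true_calibration, layout, opt, seed=scene_seed
        )
        scenes.append(scene)
        for _, row in scene.truth.iterrows():
            rec_seed = int(rng.integers(2**31 - 1))
            sampling.append(simulate_destructive_sampling(
                row.true_lai, options.lai_noise_sd, rec_seed,
                plot_id=row.plot_id, dat=dat,
            ))
    return SyntheticCampaign(
        cultivars=cultivars, scenes=scenes, sampling=sampling,
        true_calibration=true_calibration, seed=seed, options=options,
    )
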