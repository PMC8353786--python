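"""Empirical-line radiometric calibration.

Surface reflectance is assumed linear in the sensor digital number per band,

    rho_lambda = DN_lambda * Gain_lambda + Offset_lambda,

with the per-band gain and offset solved by ordinary least squares over
near-Lambertian calibration canvases of known reflectance placed in the
camera's field of view. Eight canvases at reflectances 0.03-0.80 are the
standard panel set for this sensor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SingularFitError
from .indices import WAVELENGTHS_NM

logger = logging.getLogger(__name__)

#: Known reflectances of the eight calibration canvases.
CANVAS_REFLECTANCES: tuple[float, ...] = (
    0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80
)


@dataclass(frozen=True)
class CanvasReading:
    """Mean DN of one calibration canvas, with its known reflectance.

    The known reflectance is constant across bands (grey panels); ``mean_dn``
    holds the panel-ROI mean digital number per band.
    """

    canvas_id: str
    reflectance: float
    mean_dn: np.ndarray  # shape (n_bands,)

    def __post_init__(self):
        if not 0.0 < self.reflectance < 1.0:
            raise ValueError(
                f"canvas reflectance must be in (0, 1), got {self.reflectance}"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """Per-band linear DN -> reflectance mapping.

    ``gain`` has units of reflectance per DN; ``offset`` is a reflectance.
    ``r_squared`` and ``residual_rms`` summarise the panel fit per band
    (NaN when constructed directly rather than fitted).
    """

    gain: np.ndarray
    offset: np.ndarray
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM
    r_squared: np.ndarray = field(default=None)
    residual_rms: np.ndarray = field(default=None)

    def __post_init__(self):
        gain = np.asarray(self.gain, dtype=float)
        offset = np.asarray(self.offset, dtype=float)
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "offset", offset)
        if gain.shape != (len(self.wavelengths_nm),) or offset.shape != gain.shape:
            raise ValueError(
                f"gain/offset must have one value per band "
                f"({len(self.wavelengths_nm)}), got {gain.shape}/{offset.shape}"
            )
        for name in ("r_squared", "residual_rms"):
            v = getattr(self, name)
            if v is None:
                v = np.full(gain.shape, np.nan)
            object.__setattr__(self, name, np.asarray(v, dtype=float))
        if np.any(gain <= 0):
            warnings.warn(
                "non-positive gain in calibration model: physically implausible "
                "for this sensor", stacklevel=2,
            )

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths_nm)

    def dn_from_reflectance(self, reflectance: np.ndarray) -> np.ndarray:
        """Invert the line to 8-bit DN (used by the scene generator)."""
        rho = np.asarray(reflectance, dtype=float)
        dn = np.rint((rho - self.offset) / self.gain)
        return np.clip(dn, 0, 255).astype(np.uint8)


def fit_calibration(
    readings: list[CanvasReading],
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM,
) -> CalibrationModel:
    """Fit the per-band empirical line over the calibration canvases.

    Per band, (gain, offset) is the OLS solution of
    reflectance = DN * gain + offset over the panel readings.

    Raises
    ------
    SingularFitError
        If fewer than two readings are given, or some band has fewer than
        two distinct DN values (the error names the band).
    """
    if len(readings) < 2:
        raise SingularFitError(
            f"need at least 2 canvas readings, got {len(readings)}"
        )
    n_bands = len(wavelengths_nm)
    dn = np.asarray([np.asarray(r.mean_dn, dtype=float) for r in readings])
    if dn.shape != (len(readings), n_bands):
        raise ValueError(
            f"each reading must carry {n_bands} band means, got {dn.shape}"
        )
    rho = np.asarray([r.reflectance for r in readings], dtype=float)

    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    r2 = np.empty(n_bands)
    rms = np.empty(n_bands)
    for b in range(n_bands):
        x = dn[:, b]
        if np.unique(x).size < 2:
            raise SingularFitError(
                f"band {wavelengths_nm[b]} nm has fewer than 2 distinct DN "
                "values; cannot solve the empirical line"
            )
        A = np.column_stack([x, np.ones_like(x)])
        (gain[b], offset[b]), *_ = np.linalg.lstsq(A, rho, rcond=None)
        resid = rho - (x * gain[b] + offset[b])
        rms[b] = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((rho - rho.mean()) ** 2))
        r2[b] = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    logger.info(
        "fitted empirical line over %d canvases; residual RMS %.2e-%.2e",
        len(readings), rms.min(), rms.max(),
    )
    return CalibrationModel(
        gain=gain, offset=offset, wavelengths_nm=tuple(wavelengths_nm),
        r_squared=r2, residual_rms=rms,
    )


def apply_calibration(
    dn_raster: np.ndarray,
    model: CalibrationModel,
    clamp_negative: bool = True,
) -> np.ndarray:
    """Convert a (bands, rows, cols) DN raster to reflectance.

    Negative reflectances are clamped to 0 (physical floor) with a logged
    count; values above 1 are retained with a warning — they may be genuine
    specular returns that the bad-pixel filter must still see.
    """
    dn = np.asarray(dn_raster)
    if dn.ndim != 3 or dn.shape[0] != model.n_bands:
        raise ValueError(
            f"expected a ({model.n_bands}, rows, cols) raster, got {dn.shape}"
        )
    rho = dn.astype(np.float64) * model.gain[:, None, None] \
        + model.offset[:, None, None]
    if clamp_negative:
        n_neg = int(np.count_nonzero(rho < 0))
        if n_neg:
            logger.info("clamped %d negative reflectance values to 0", n_neg)
            rho = np.clip(rho, 0.0, None)
    n_high = int(np.count_nonzero(rho > 1.0))
    if n_high:
        warnings.warn(
            f"{n_high} reflectance values exceed 1.0 (possible specular "
            "pixels); retained unclamped", stacklevel=2,
        )
    return rho
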