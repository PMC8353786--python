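"""Vegetation indices from 12-band canopy reflectance.

The sensor is a 12-lens multispectral camera with band-pass filters centred at
490-950 nm. Eight indices widely used for LAI estimation are implemented;
blue-band indices are excluded because the sensor's signal-to-noise ratio is
poor near 450 nm and rice reflectance there is very low.

Band roles (which physical band plays green / red / red-edge / NIR) are an
explicit, validated mapping because a 12-band sensor offers several candidates
per spectral region. The default picks the central choice in each region:
green = 550 nm, red = 670 nm, red edge = 720 nm, NIR = 800 nm.

Note on OSAVI: the variant used here is written with the red-edge band,
``(1 + 0.16) * (NIR - RE) / (NIR + RE + 0.16)``. The classical formulation
uses the red band instead; both are available via ``osavi_variant``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, UndefinedValueError

#: Central wavelengths (nm) of the 12-band camera.
WAVELENGTHS_NM: tuple[int, ...] = (
    490, 520, 550, 570, 670, 680, 700, 720, 800, 850, 900, 950
)

#: NIR down-weighting constant of the wide dynamic range vegetation index.
WDRVI_ALPHA = 0.2

INDEX_NAMES: tuple[str, ...] = (
    "NDVI", "EVI2", "WDRVI", "CIgreen", "CIrededge", "NDRE", "MTCI", "OSAVI"
)

DEFAULT_BAND_ROLES: Mapping[str, int] = {
    "green": 550,
    "red": 670,
    "red_edge": 720,
    "nir": 800,
}

_ROLES = ("green", "red", "red_edge", "nir")


@dataclass(frozen=True)
class BandRoleMap:
    """Validated assignment of spectral roles to sensor bands.

    Attributes
    ----------
    roles : mapping of role name to central wavelength (nm)
    band_index : mapping of role name to 0-based band position in the raster
    wavelengths : the raster's band wavelengths, in band order
    """

    roles: Mapping[str, int]
    band_index: Mapping[str, int]
    wavelengths: tuple[int, ...] = field(default=WAVELENGTHS_NM)

    def describe(self) -> str:
        return ", ".join(f"{r}={self.roles[r]}nm" for r in _ROLES)


def resolve_bands(
    band_map: Mapping[str, int] | None = None,
    wavelengths: Sequence[int] = WAVELENGTHS_NM,
) -> BandRoleMap:
    """Validate a role->wavelength request against the sensor band set.

    Parameters
    ----------
    band_map : optional mapping with keys green/red/red_edge/nir; missing keys
        fall back to the defaults.
    wavelengths : the band set of the raster (defaults to the 12-band camera).

    Raises
    ------
    ConfigurationError
        If a requested wavelength is not among the raster's bands.
    """
    wl = tuple(int(w) for w in wavelengths)
    roles = dict(DEFAULT_BAND_ROLES)
    if band_map:
        unknown = set(band_map) - set(_ROLES)
        if unknown:
            raise ConfigurationError(f"unknown band roles: {sorted(unknown)}")
        roles.update({k: int(v) for k, v in band_map.items()})
    band_index = {}
    for role in _ROLES:
        if roles[role] not in wl:
            raise ConfigurationError(
                f"band role {role!r} requests {roles[role]} nm, "
                f"not in the band set {wl}"
            )
        band_index[role] = wl.index(roles[role])
    return BandRoleMap(roles=roles, band_index=band_index, wavelengths=wl)


def _div(num, den, context: str):
    den = np.asarray(den, dtype=float)
    if np.any(den == 0):
        raise UndefinedValueError(f"zero denominator in {context}")
    return num / den


def compute_vi(
    reflectance: Sequence[float] | np.ndarray,
    name: str,
    bands: BandRoleMap | None = None,
    osavi_variant: str = "red_edge",
) -> float:
    """Compute one vegetation index from a 12-band reflectance vector.

    Parameters
    ----------
    reflectance : reflectance per band, in raster band order.
    name : one of NDVI, EVI2, WDRVI, CIgreen, CIrededge, NDRE, MTCI, OSAVI.
    bands : band role assignment; defaults to ``resolve_bands()``.
    osavi_variant : "red_edge" (as used here) or "red" (classical form).

    Raises
    ------
    UndefinedValueError
        If the index's denominator is zero for this sample.
    """
    if bands is None:
        bands = resolve_bands()
    rho = np.asarray(reflectance, dtype=float)
    if rho.shape[-1] != len(bands.wavelengths):
        raise ValueError(
            f"expected {len(bands.wavelengths)} bands, got {rho.shape[-1]}"
        )
    g = rho[..., bands.band_index["green"]]
    r = rho[..., bands.band_index["red"]]
    re = rho[..., bands.band_index["red_edge"]]
    nir = rho[..., bands.band_index["nir"]]

    if name == "NDVI":
        val = _div(nir - r, nir + r, "NDVI")
    elif name == "EVI2":
        val = 2.5 * _div(nir - r, 1.0 + nir + 2.4 * r, "EVI2")
    elif name == "WDRVI":
        a = WDRVI_ALPHA
        val = _div(a * nir - r, a * nir + r, "WDRVI")
    elif name == "CIgreen":
        val = _div(nir, g, "CIgreen") - 1.0
    elif name == "CIrededge":
        val = _div(nir, re, "CIrededge") - 1.0
    elif name == "NDRE":
        val = _div(nir - re, nir + re, "NDRE")
    elif name == "MTCI":
        val = _div(nir - re, re - r, "MTCI")
    elif name == "OSAVI":
        if osavi_variant == "red_edge":
            val = (1 + 0.16) * _div(nir - re, nir + re + 0.16, "OSAVI")
        elif osavi_variant == "red":
            val = (1 + 0.16) * _div(nir - r, nir + r + 0.16, "OSAVI")
        else:
            raise ConfigurationError(
                f"osavi_variant must be 'red_edge' or 'red', got {osavi_variant!r}"
            )
    else:
        raise ConfigurationError(f"unknown vegetation index {name!r}")
    out = float(val) if np.isscalar(val) or val.ndim == 0 else val
    return out


def compute_all_indices(
    reflectance,
    bands: BandRoleMap | None = None,
    osavi_variant: str = "red_edge",
) -> dict[str, float]:
    """All eight indices for one reflectance vector; undefined ones are NaN."""
    out = {}
    for name in INDEX_NAMES:
        try:
            out[name] = compute_vi(reflectance, name, bands, osavi_variant)
        except UndefinedValueError:
            out[name] = math.nan
    return out
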