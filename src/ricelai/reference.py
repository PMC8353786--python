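"""Published whole-season calibration equations for hybrid rice LAI.

The originating 48-cultivar, 13-campaign field experiment reported three
whole-season H x ln(VI + 1) calibrations as its best single-algorithm models:

    LAI = 2.04  * H * ln(CIgreen + 1) + 0.40
    LAI = 9.02  * H * ln(WDRVI  + 1) + 0.55
    LAI = 12.72 * H * ln(OSAVI  + 1) + 0.50

These coefficients serve two purposes here: as ready-to-use predictors for
comparable canopies, and as ground truth for parameter-recovery checks in
which data simulated from an equation are refit and the coefficients must
come back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ReferenceEquation:
    """One published LAI = slope * H * ln(VI + 1) + intercept calibration."""

    index: str
    slope: float
    intercept: float

    def predict(self, h, vi) -> np.ndarray:
        """Predicted LAI from canopy height (m) and the matching index."""
        h = np.asarray(h, dtype=float)
        vi = np.asarray(vi, dtype=float)
        return self.slope * h * np.log1p(vi) + self.intercept


#: The three published whole-season calibrations, keyed by index name.
PUBLISHED_EQUATIONS: dict[str, ReferenceEquation] = {
    "CIgreen": ReferenceEquation("CIgreen", slope=2.04, intercept=0.40),
    "WDRVI": ReferenceEquation("WDRVI", slope=9.02, intercept=0.55),
    "OSAVI": ReferenceEquation("OSAVI", slope=12.72, intercept=0.50),
}

#: Index ranges observed in the originating experiment, used when simulating
#: samples for parameter-recovery checks: (low, high) of the matching VI.
RECOVERY_VI_RANGES: dict[str, tuple[float, float]] = {
    "CIgreen": (0.5, 8.0),
    "WDRVI": (-0.3, 0.7),
    "OSAVI": (0.1, 0.8),
}

#: Canopy height range (m) spanned by the recovery simulations.
RECOVERY_H_RANGE: tuple[float, float] = (0.2, 1.2)

#: Observation noise (LAI units) added when simulating from an equation.
RECOVERY_NOISE_SD = 0.1


def simulate_from_equation(
    index: str, n: int, seed: int, noise_sd: float = RECOVERY_NOISE_SD
):
    """Draw (height, VI, LAI) samples from one published calibration.

    Heights and index values are uniform over the ranges the equations were
    calibrated on; LAI is the equation's prediction plus Gaussian noise.
    """
    eq = PUBLISHED_EQUATIONS[index]
    rng = np.random.default_rng(seed)
    h = rng.uniform(*RECOVERY_H_RANGE, size=n)
    vi = rng.uniform(*RECOVERY_VI_RANGES[index], size=n)
    lai = eq.predict(h, vi) + noise_sd * rng.standard_normal(n)
    return h, vi, lai


def recover_equation(
    index: str, n: int = 600, replicates: int = 20, seed: int = 0
) -> dict[str, float]:
    """Refit a published equation on data simulated from it.

    Runs ``replicates`` independent simulations of ``n`` samples each,
    refits slope and intercept of LAI on H * ln(VI + 1) by OLS, and returns
    the replicate-mean coefficients. An unbiased pipeline returns the
    published values up to Monte-Carlo error.
    """
    from .models import ModelForm, fit_linear, predictor_value

    rng = np.random.default_rng(seed)
    slopes, intercepts = [], []
    for _ in range(replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        h, vi, lai = simulate_from_equation(index, n, rep_seed)
        x = predictor_value(vi, h, ModelForm.H_TIMES_LNVI)
        fit = fit_linear(x, lai)
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
    return {
        "slope": float(np.mean(slopes)),
        "intercept": float(np.mean(intercepts)),
        "n": n,
        "replicates": replicates,
    }
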