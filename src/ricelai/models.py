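"""Linear LAI models on vegetation-index and canopy-height predictors.

Three candidate predictors are compared for whole-season LAI estimation:

* ``VI_ONLY``      x = VI
* ``H_TIMES_VI``   x = H * VI
* ``H_TIMES_LNVI`` x = H * ln(VI + 1)

each entering a univariate ordinary-least-squares line LAI = slope * x +
intercept fitted over all plots, cultivars and dates pooled. The height
product compensates the phenology hysteresis of the VI-LAI relationship:
after panicle exsertion a rice canopy shows higher visible reflectance
(hence lower VI) but greater height at equal LAI, so H * f(VI) tracks LAI
across both stages where VI alone cannot.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import SingularFitError


class ModelForm(enum.Enum):
    """Predictor construction for the univariate LAI line."""

    VI_ONLY = "VI"
    H_TIMES_VI = "H*VI"
    H_TIMES_LNVI = "H*ln(VI+1)"


@dataclass(frozen=True)
class FitResult:
    """OLS line LAI = slope * x + intercept with fit diagnostics."""

    slope: float
    intercept: float
    n_samples: int
    rmse: float
    r2: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def predictor_value(vi, h, form: ModelForm):
    """Build the model predictor from VI and canopy height (m).

    Accepts scalars or arrays. For ``H_TIMES_LNVI`` the index must exceed -1;
    offending samples raise ValueError (callers flag and exclude them).
    """
    vi = np.asarray(vi, dtype=float)
    h = np.asarray(h, dtype=float)
    if form is ModelForm.VI_ONLY:
        out = vi + 0.0
    elif form is ModelForm.H_TIMES_VI:
        out = h * vi
    elif form is ModelForm.H_TIMES_LNVI:
        if np.any(vi <= -1.0):
            raise ValueError(
                "ln(VI + 1) undefined for VI <= -1; sample must be excluded"
            )
        out = h * np.log1p(vi)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown model form {form}")
    return float(out) if out.ndim == 0 else out


def fit_linear(x, y) -> FitResult:
    """Univariate OLS with intercept; attaches residual RMSE and R².

    Raises
    ------
    SingularFitError
        For fewer than 2 samples or a constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got "
                         f"{x.shape} and {y.shape}")
    if x.size < 2:
        raise SingularFitError(f"need at least 2 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularFitError("constant predictor: OLS line is undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return FitResult(
        slope=float(slope), intercept=float(intercept),
        n_samples=int(x.size), rmse=rmse, r2=r2,
    )


def r_squared(x, y) -> float:
    """Squared Pearson correlation; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
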