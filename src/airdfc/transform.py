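"""Box-Cox normalization of right-skewed dwell-time outcomes.

The transform is y -> (y^lambda - 1)/lambda (natural log at lambda = 0),
with lambda chosen by profile maximum likelihood, an optional additive
shift for nonpositive inputs, and standardization to mean 0 / sd 1 of the
fitting sample.  Missing values propagate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TransformSpec:
    lambda_: float
    shift: float = 0.0
    standardize: bool = True
    mean_: float = 0.0
    sd_: float = 1.0


def _raw_boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def box_cox_fit(
    values: np.ndarray,
    shift: float | None = None,
    standardize: bool = True,
    lambda_: float | None = None,
) -> TransformSpec:
    """Fit the transform on non-missing values.

    ``shift`` defaults to 0 for all-positive input, otherwise to the
    smallest offset making the minimum slightly positive.  ``lambda_`` can
    be forced (e.g. 0 for a pure log transform); otherwise it maximizes the
    Box-Cox profile log-likelihood.
    """
    y = np.asarray(values, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 10:
        raise ValueError("need at least 10 non-missing values")
    if shift is None:
        shift = 0.0 if y.min() > 0 else 1e-6 - float(y.min())
    y = y + shift
    if y.min() <= 0:
        raise ValueError("nonpositive values after shift")
    if np.ptp(y) == 0:
        raise ValueError("constant input")
    if lambda_ is None:
        _, lambda_ = stats.boxcox(y)
    z = _raw_boxcox(y, float(lambda_))
    mean_ = float(z.mean())
    sd_ = float(z.std(ddof=0))
    if sd_ == 0:
        raise ValueError("transformed values are constant")
    return TransformSpec(float(lambda_), float(shift), standardize, mean_, sd_)


def box_cox_apply(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply a fitted transform; NaN in -> NaN out."""
    y = np.asarray(values, dtype=float)
    out = np.full(y.shape, np.nan)
    ok = ~np.isnan(y)
    shifted = y[ok] + spec.shift
    if (shifted <= 0).any():
        raise ValueError("value + shift <= 0")
    z = _raw_boxcox(shifted, spec.lambda_)
    if spec.standardize:
        z = (z - spec.mean_) / spec.sd_
    out[ok] = z
    return out


def box_cox_invert(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Closed-form inverse of :func:`box_cox_apply`."""
    z = np.asarray(values, dtype=float)
    out = np.full(z.shape, np.nan)
    ok = ~np.isnan(z)
    w = z[ok]
    if spec.standardize:
        w = w * spec.sd_ + spec.mean_
    if spec.lambda_ == 0.0:
        y = np.exp(w)
    else:
        y = np.power(spec.lambda_ * w + 1.0, 1.0 / spec.lambda_)
    out[ok] = y - spec.shift
    return out
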