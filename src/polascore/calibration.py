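"""Depth-attenuation calibration from a symmetric control reporter.

The control reporter is expressed equally in both daughters, so any
systematic trend of its log intensity ratio with the focal-plane distance
between the two nuclei measures depth-dependent signal attenuation.  An
ordinary least-squares line of log ratio on distance is fitted and a
constant-width two-sided confidence band of half-width ``t_crit * residual_se``
is attached; residuals of polarity-reporter measurements are later classified
against that band.

The band deliberately uses a single residual standard error for all x — a
constant-width band around the fitted line, not a leverage-adjusted pointwise
prediction interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InputMixError,
    InsufficientDataError,
    ModelError,
)
from .measurements_io import LOG_BASE, CellPairMeasurement, Reporter, log_ratio

__all__ = [
    "CalibrationModel",
    "t_critical",
    "fit_depth_regression",
    "predict_log_ratio",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted depth regression plus its classification band.

    Attributes
    ----------
    slope, intercept
        OLS coefficients of log ratio on signed focal-plane distance.
    residual_se
        Regression residual standard error, ``sqrt(SSR / (n - 2))``.
    n, df
        Number of control pairs and residual degrees of freedom (``n - 2``).
    t_crit
        Two-sided ``1 - alpha`` Student-t quantile at ``df``.
    v_upper, v_lower
        Band half-widths, ``+/- t_crit * residual_se``.
    """

    slope: float
    intercept: float
    residual_se: float
    n: int
    df: int
    t_crit: float
    v_upper: float
    v_lower: float
    alpha: float = 0.05
    log_base: float = LOG_BASE

    def __post_init__(self):
        if self.df != self.n - 2:
            raise ModelError(f"df must equal n - 2; got df={self.df}, n={self.n}")
        if self.residual_se < 0:
            raise ModelError("residual_se must be non-negative")
        if not 0 < self.alpha < 1:
            raise ModelError("alpha must be in (0, 1)")
        if abs(self.v_lower + self.v_upper) > 1e-12 * max(1.0, abs(self.v_upper)):
            raise ModelError("v_lower must equal -v_upper")


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-sided ``1 - alpha`` Student-t critical value (the ``1 - alpha/2`` quantile)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def fit_depth_regression(
    control: Sequence[CellPairMeasurement],
    alpha: float = 0.05,
    log_base: float = LOG_BASE,
) -> CalibrationModel:
    """Fit the attenuation line on symmetric-control measurements.

    Parameters
    ----------
    control
        Measurements, all with ``reporter == control_nls``.
    alpha
        Band significance level (default 0.05, i.e. a 95% band).

    Raises
    ------
    InputMixError
        If any measurement comes from a non-control reporter.
    InsufficientDataError
        If fewer than 3 measurements are supplied.
    DegenerateDesignError
        If all distances are identical (slope not estimable).
    """
    n = len(control)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 control pairs, got {n}")
    bad = {m.reporter for m in control if m.reporter != Reporter.control_nls}
    if bad:
        raise InputMixError(
            "calibration input must be control_nls only; found "
            + ", ".join(sorted(r.value for r in bad))
        )
    x = np.array([m.z_distance_um for m in control], dtype=float)
    y = np.array([log_ratio(m, base=log_base) for m in control], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all z distances identical; slope not estimable")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    df = n - 2
    residual_se = float(np.sqrt(np.sum(resid**2) / df))
    t_crit = t_critical(df, alpha)
    v_upper = t_crit * residual_se
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_se=residual_se,
        n=n,
        df=df,
        t_crit=t_crit,
        v_upper=v_upper,
        v_lower=-v_upper,
        alpha=alpha,
        log_base=log_base,
    )


def predict_log_ratio(model: CalibrationModel, z: float) -> float:
    """Expected log ratio of a symmetric pair at signed distance ``z``."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return model.intercept + model.slope * float(z)


_FLOAT_FIELDS = (
    "slope",
    "intercept",
    "residual_se",
    "t_crit",
    "v_upper",
    "v_lower",
    "alpha",
    "log_base",
)
_INT_FIELDS = ("n", "df")


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize the model to a small ``key = value`` text file."""
    lines = [f"{k} = {getattr(model, k)!r}" for k in _FLOAT_FIELDS + _INT_FIELDS]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> CalibrationModel:
    """Load a model written by :func:`save_model`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ModelError(f"{path}: malformed line {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    try:
        kwargs: dict[str, float | int] = {k: float(kv[k]) for k in _FLOAT_FIELDS}
        kwargs.update({k: int(kv[k]) for k in _INT_FIELDS})
    except KeyError as exc:
        raise ModelError(f"{path}: missing model field {exc}") from exc
    return CalibrationModel(**kwargs)  # type: ignore[arg-type]
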