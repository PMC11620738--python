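"""Residual-based polarity calls and per-group summaries.

Each reporter measurement is reduced to a depth-corrected residual
``r = y - y_hat`` (observed minus calibration-predicted log ratio).  Signed
orientation and absolute polarization are called against the calibration
band with strict inequalities:

* signed: ``normal`` if ``r > v_upper``, ``reversed`` if ``r < v_lower``,
  ``symmetric`` otherwise;
* absolute: ``polarized`` iff ``|r| > v_upper``.

Residuals exactly on a boundary are symmetric/unpolarized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, predict_log_ratio
from .errors import ModelError
from .measurements_io import CellPairMeasurement, log_ratio

__all__ = [
    "SignedClass",
    "AbsoluteClass",
    "PolarityCall",
    "GenotypeSummary",
    "score_measurement",
    "score_measurements",
    "summarize",
    "calls_to_frame",
    "plot_violin",
]


class SignedClass(str, Enum):
    normal = "normal"
    reversed = "reversed"
    symmetric = "symmetric"


class AbsoluteClass(str, Enum):
    polarized = "polarized"
    unpolarized = "unpolarized"


@dataclass(frozen=True)
class PolarityCall:
    measurement: CellPairMeasurement
    y: float
    y_hat: float
    residual: float
    signed_class: SignedClass
    absolute_class: AbsoluteClass


@dataclass(frozen=True)
class GenotypeSummary:
    """Class fractions and mean residuals for one (genotype, cell, temperature) group."""

    genotype: str
    cell: str
    temperature_c: float
    n_calls: int
    fraction_normal: float
    fraction_reversed: float
    fraction_symmetric: float
    mean_signed_residual: float
    mean_absolute_residual: float


def score_measurement(
    model: CalibrationModel, m: CellPairMeasurement
) -> PolarityCall:
    """Score one measurement against a fitted calibration."""
    if model.n < 3:
        raise ModelError("calibration model is unfitted or degenerate")
    y = log_ratio(m, base=model.log_base)
    y_hat = predict_log_ratio(model, m.z_distance_um)
    r = y - y_hat
    if r > model.v_upper:
        signed = SignedClass.normal
    elif r < model.v_lower:
        signed = SignedClass.reversed
    else:
        signed = SignedClass.symmetric
    absolute = (
        AbsoluteClass.polarized if abs(r) > model.v_upper else AbsoluteClass.unpolarized
    )
    return PolarityCall(
        measurement=m,
        y=y,
        y_hat=y_hat,
        residual=r,
        signed_class=signed,
        absolute_class=absolute,
    )


def score_measurements(
    model: CalibrationModel, measurements: Iterable[CellPairMeasurement]
) -> list[PolarityCall]:
    return [score_measurement(model, m) for m in measurements]


def _group_key(call: PolarityCall) -> tuple[str, str, float]:
    m = call.measurement
    # exact grouping after normalizing temperature to one decimal
    return (m.genotype, m.cell.value, round(m.temperature_c, 1))


def summarize(calls: Sequence[PolarityCall]) -> list[GenotypeSummary]:
    """One summary per (genotype, cell, temperature) group, in sorted order."""
    if not calls:
        warnings.warn("summarize: no calls supplied; returning empty summary")
        return []
    groups: dict[tuple[str, str, float], list[PolarityCall]] = {}
    for c in calls:
        groups.setdefault(_group_key(c), []).append(c)
    out = []
    for (genotype, cell, temp) in sorted(groups):
        grp = groups[(genotype, cell, temp)]
        n = len(grp)
        residuals = np.array([c.residual for c in grp])
        n_norm = sum(c.signed_class is SignedClass.normal for c in grp)
        n_rev = sum(c.signed_class is SignedClass.reversed for c in grp)
        out.append(
            GenotypeSummary(
                genotype=genotype,
                cell=cell,
                temperature_c=temp,
                n_calls=n,
                fraction_normal=n_norm / n,
                fraction_reversed=n_rev / n,
                fraction_symmetric=(n - n_norm - n_rev) / n,
                mean_signed_residual=float(residuals.mean()),
                mean_absolute_residual=float(np.abs(residuals).mean()),
            )
        )
    return out


def calls_to_frame(calls: Sequence[PolarityCall]) -> pd.DataFrame:
    """Tabulate calls: input schema plus y, y_hat, residual and both classes."""
    rows = []
    for c in calls:
        m = c.measurement
        rows.append(
            {
                "animal_id": m.animal_id,
                "genotype": m.genotype,
                "temperature_c": m.temperature_c,
                "cell": m.cell.value,
                "reporter": m.reporter.value,
                "intensity_proximal": m.intensity_proximal,
                "intensity_distal": m.intensity_distal,
                "z_distance_um": m.z_distance_um,
                "y": c.y,
                "y_hat": c.y_hat,
                "residual": c.residual,
                "signed_class": c.signed_class.value,
                "absolute_class": c.absolute_class.value,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[GenotypeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def plot_violin(
    calls: Sequence[PolarityCall],
    mode: str,
    model: CalibrationModel,
    out_path: str | Path,
    summary_path: str | Path | None = None,
    bw: float = 0.2,
) -> Path:
    """Violin plot of residuals per (genotype, cell, temperature) group.

    ``mode='signed'`` plots residuals with density extended beyond the data
    (cut=2) and reference lines at 0, ``v_upper`` and ``v_lower``;
    ``mode='absolute'`` plots |residual| with the density truncated at the
    data range (cut=0) so the support never extends below zero.  Groups with
    fewer than 2 calls are skipped with a warning.  A deterministic summary
    table is written alongside when ``summary_path`` is given.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    groups: dict[tuple[str, str, float], list[float]] = {}
    for c in calls:
        groups.setdefault(_group_key(c), []).append(
            c.residual if mode == "signed" else abs(c.residual)
        )
    plotted = {}
    for key in sorted(groups):
        if len(groups[key]) < 2:
            warnings.warn(f"plot_violin: skipping single-point group {key}")
            continue
        plotted[key] = groups[key]
    if not plotted:
        raise ValueError("no group has >= 2 calls; nothing to plot")

    labels = ["{}/{}/{:g}C".format(*k) for k in plotted]
    data = pd.DataFrame(
        [(lab, v) for lab, vals in zip(labels, plotted.values()) for v in vals],
        columns=["group", "value"],
    )
    cut = 2 if mode == "signed" else 0
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(plotted)), 4))
    sns.violinplot(
        data=data,
        x="group",
        y="value",
        cut=cut,
        bw_method=bw,
        density_norm="width",
        ax=ax,
    )
    ax.axhline(0.0, color="black", linestyle="--", linewidth=1)
    ax.axhline(model.v_upper, color="red", linestyle="--", linewidth=1)
    if mode == "signed":
        ax.axhline(model.v_lower, color="red", linestyle="--", linewidth=1)
    ax.set_ylabel("residual" if mode == "signed" else "|residual|")
    ax.set_xlabel("")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    if summary_path is not None:
        rows = []
        for (lab, vals) in zip(labels, plotted.values()):
            arr = np.array(vals)
            rows.append(
                {
                    "group": lab,
                    "n": len(arr),
                    "mean": float(arr.mean()),
                    "median": float(np.median(arr)),
                    "sd": float(arr.std(ddof=1)),
                }
            )
        pd.DataFrame(rows).to_csv(summary_path, index=False)
    return out_path
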