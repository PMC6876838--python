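"""Skin-response analysis: scores, ear-swelling time courses, threshold fit.

Longitudinal per-mouse data (triplicate ear-thickness readings and
erythema/desquamation scores over 90 days) are summarised per group, the
maximum of the group-mean swelling curve and the first half-maximum
crossing time t50 are extracted, and the maximum thickness is regressed
on the beam-geometry ratio sigma/ctc.  The intersection of the regression
line with the unirradiated control thickness extrapolates the no-effect
geometry: the ratio sigma_min/ctc below which no measurable swelling is
expected, hence a minimum tolerated beam size sigma_min (and its FWHM)
for a given lattice spacing.

Records travel as a pandas DataFrame with columns
``mouse_id, group_ratio, day, thickness_um_1..3, erythema, desquamation``
(the sham control carries group_ratio 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ERYTHEMA_SCALE",
    "DESQUAMATION_SCALE",
    "RECORD_COLUMNS",
    "GroupSummary",
    "SwellingStats",
    "ThresholdFit",
    "total_score",
    "validate_records",
    "load_records_csv",
    "load_records_xlsx",
    "group_timecourse",
    "summarize_groups",
    "swelling_stats",
    "fit_threshold",
    "per_mouse_metric",
    "compare_groups",
]

#: Allowed erythema scores: no / mild / definite / severe.
ERYTHEMA_SCALE = (0.0, 0.5, 1.5, 3.0)
#: Allowed desquamation scores: no / dry / crust formation / moist.
DESQUAMATION_SCALE = (0.0, 1.0, 2.0, 3.0)

RECORD_COLUMNS = (
    "mouse_id",
    "group_ratio",
    "day",
    "thickness_um_1",
    "thickness_um_2",
    "thickness_um_3",
    "erythema",
    "desquamation",
)

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class GroupSummary:
    """Per-day group means (across mice) of thickness and total score."""

    group_ratio: float
    table: pd.DataFrame  # day, thickness_mean, thickness_sem, score_mean, score_sem
    n_mice: int


@dataclass(frozen=True)
class SwellingStats:
    """Summary of one group's swelling curve.

    ``t50`` is the first (linearly interpolated) day at which the swelling
    mean - baseline reaches half its maximum; undefined (None) for a flat
    curve.
    """

    max_thickness_um: float
    day_of_max: float
    t50_days: float | None
    baseline_um: float


@dataclass(frozen=True)
class ThresholdFit:
    """Linear extrapolation of max thickness vs sigma/ctc to the control level."""

    slope_um: float  # μm per unit sigma/ctc
    intercept_um: float
    r_value: float
    ratio_min: float  # sigma_min / ctc at the control intersection
    sigma_min_um: float
    fwhm_min_um: float
    slope_stderr_um: float


def total_score(erythema: float, desquamation: float) -> float:
    """Total skin score: erythema plus desquamation, range [0, 6]."""
    if erythema not in ERYTHEMA_SCALE:
        raise ValueError(f"erythema {erythema} not on the scale {ERYTHEMA_SCALE}")
    if desquamation not in DESQUAMATION_SCALE:
        raise ValueError(
            f"desquamation {desquamation} not on the scale {DESQUAMATION_SCALE}"
        )
    return erythema + desquamation


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, day window, positive thickness, score lattices."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if ((df["day"] < 0) | (df["day"] > 90)).any():
        raise ValueError("days must lie in [0, 90]")
    thick = df[["thickness_um_1", "thickness_um_2", "thickness_um_3"]]
    if (thick <= 0).any().any():
        raise ValueError("thickness readings must be positive")
    if not df["erythema"].isin(ERYTHEMA_SCALE).all():
        raise ValueError("erythema scores off the allowed scale")
    if not df["desquamation"].isin(DESQUAMATION_SCALE).all():
        raise ValueError("desquamation scores off the allowed scale")
    return df


def load_records_csv(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path))


def load_records_xlsx(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sheet_name: str | None = None,
) -> pd.DataFrame:
    """Read records from a workbook, auto-detecting the data sheet.

    ``column_map`` maps workbook column headers to the canonical
    :data:`RECORD_COLUMNS` names; sheets are scanned until one provides
    every canonical column after renaming.
    """
    book = pd.read_excel(path, sheet_name=None if sheet_name is None else [sheet_name])
    rename = dict(column_map) if column_map else {}
    for name, sheet in book.items():
        df = sheet.rename(columns=rename)
        if all(c in df.columns for c in RECORD_COLUMNS):
            return validate_records(df[list(RECORD_COLUMNS)].copy())
    raise ValueError(f"no sheet in {path} provides columns {RECORD_COLUMNS}")


def _per_mouse_day(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["thickness_um"] = out[
        ["thickness_um_1", "thickness_um_2", "thickness_um_3"]
    ].mean(axis=1)
    out["total_score"] = out["erythema"] + out["desquamation"]
    return out


def group_timecourse(records: pd.DataFrame) -> GroupSummary:
    """Mean +/- SEM time course of one group.

    Per mouse and day the three thickness replicates are averaged first;
    group mean and SEM are then taken across mice.  Days a mouse was not
    measured stay absent (no imputation).  Groups of fewer than two mice
    have no defined SEM and are rejected.
    """
    ratios = records["group_ratio"].unique()
    if len(ratios) != 1:
        raise ValueError("group_timecourse expects records of a single group")
    n_mice = records["mouse_id"].nunique()
    if n_mice < 2:
        raise ValueError("SEM undefined for groups with fewer than 2 mice")
    pm = _per_mouse_day(records)
    agg = pm.groupby("day").agg(
        thickness_mean=("thickness_um", "mean"),
        thickness_sem=("thickness_um", "sem"),
        score_mean=("total_score", "mean"),
        score_sem=("total_score", "sem"),
    )
    table = agg.reset_index().sort_values("day").reset_index(drop=True)
    return GroupSummary(group_ratio=float(ratios[0]), table=table, n_mice=int(n_mice))


def summarize_groups(records: pd.DataFrame) -> dict[float, GroupSummary]:
    """Group time courses keyed by sigma/ctc ratio."""
    return {
        float(r): group_timecourse(g)
        for r, g in records.groupby("group_ratio", sort=True)
    }


def swelling_stats(summary: GroupSummary, baseline_um: float) -> SwellingStats:
    """Maximum of the group-mean curve and the half-maximum time t50.

    The maximum thickness is read off the group-mean curve (the per-group
    maxima occur at different days).  t50 is the first day, linearly
    interpolated between measurement days, at which the swelling
    mean - baseline reaches half of its maximum; it always precedes the
    day of maximum.  Curves that never swell above baseline have no t50.
    """
    tbl = summary.table
    if len(tbl) == 0:
        raise ValueError("empty time course")
    days = tbl["day"].to_numpy(dtype=float)
    mean = tbl["thickness_mean"].to_numpy(dtype=float)
    i_max = int(np.argmax(mean))
    max_thickness = float(mean[i_max])
    day_of_max = float(days[i_max])
    swelling = mean - baseline_um
    s_max = float(swelling[i_max])
    if s_max <= 0:
        return SwellingStats(
            max_thickness_um=max(max_thickness, baseline_um),
            day_of_max=day_of_max,
            t50_days=None,
            baseline_um=baseline_um,
        )
    half = s_max / 2.0
    t50 = None
    for j in range(i_max + 1):
        if swelling[j] >= half:
            if j == 0:
                t50 = float(days[0])
            else:
                s0, s1 = swelling[j - 1], swelling[j]
                d0, d1 = days[j - 1], days[j]
                t50 = float(d0 + (half - s0) / (s1 - s0) * (d1 - d0))
            break
    return SwellingStats(
        max_thickness_um=max_thickness,
        day_of_max=day_of_max,
        t50_days=t50,
        baseline_um=baseline_um,
    )


def fit_threshold(
    points: Iterable[tuple[float, float]],
    control_t0_um: float,
    ctc_um: float,
) -> ThresholdFit:
    """Extrapolate the no-swelling geometry from max thickness vs sigma/ctc.

    Ordinary least squares of the irradiated groups' maximum ear
    thickness on sigma/ctc (the control is excluded — it carries no
    radiation effect and would bend the line).  The fitted line crosses
    the control thickness at ratio_min = (control_t0 - intercept)/slope;
    sigma_min = ratio_min * ctc and FWHM = 2*sqrt(2 ln 2)*sigma_min.
    """
    pts = [(float(r), float(t)) for r, t in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 irradiated groups for the fit")
    if any(r <= 0 for r, _ in pts):
        raise ValueError("control (ratio 0) must be excluded from the fit")
    ratios = np.array([r for r, _ in pts])
    thickness = np.array([t for _, t in pts])
    res = stats.linregress(ratios, thickness)
    if res.slope <= 0:
        raise ValueError("non-positive slope: no swelling threshold to extrapolate")
    ratio_min = (control_t0_um - res.intercept) / res.slope
    sigma_min = ratio_min * ctc_um
    return ThresholdFit(
        slope_um=float(res.slope),
        intercept_um=float(res.intercept),
        r_value=float(res.rvalue),
        ratio_min=float(ratio_min),
        sigma_min_um=float(sigma_min),
        fwhm_min_um=float(_FWHM_PER_SIGMA * sigma_min),
        slope_stderr_um=float(res.stderr),
    )


def per_mouse_metric(records: pd.DataFrame, metric: str = "max_thickness") -> np.ndarray:
    """One scalar per mouse: 'max_thickness' (μm) or 'max_score'."""
    pm = _per_mouse_day(records)
    if metric == "max_thickness":
        return pm.groupby("mouse_id")["thickness_um"].max().to_numpy(dtype=float)
    if metric == "max_score":
        return pm.groupby("mouse_id")["total_score"].max().to_numpy(dtype=float)
    raise ValueError(f"unknown metric {metric!r}")


def compare_groups(
    records: pd.DataFrame,
    ratio_a: float,
    ratio_b: float,
    metric: str = "max_thickness",
) -> float:
    """Two-sided Welch t-test p-value on a per-mouse metric.

    A declared convention for group comparison (unequal variances, one
    value per mouse).  Degenerate zero-variance inputs short-circuit to
    p = 1 when the samples are identical in mean and p = 0 otherwise.
    """
    a = per_mouse_metric(records[records["group_ratio"] == ratio_a], metric)
    b = per_mouse_metric(records[records["group_ratio"] == ratio_b], metric)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 mice per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
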