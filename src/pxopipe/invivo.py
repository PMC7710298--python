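"""PDX tumor-growth analysis: volumes, T/C growth inhibition, mRECIST calls.

Caliper measurements (length x width, mm) are converted to volumes with the
ellipsoid approximation V = L * W^2 / 2.  Treatment effect is summarized two
ways: (1) tumor growth inhibition as the T/C ratio of mean relative growth
(treated V_t/V_0 divided by control V_t/V_0 at a reference day), and (2) a
modified-RECIST class per arm from the best (most negative) percent volume
change and the best running-average percent change, using a configurable
threshold table in the style of the Jackson Laboratory / Gao et al. PDX
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRECIST_DEFAULT_THRESHOLDS",
    "ResponseCall",
    "tumor_volume",
    "volumes_frame",
    "relative_tgi",
    "mrecist_call",
    "regress_auc_tgi",
]

#: Default mRECIST threshold table (percent volume change from baseline).
#: Strict inequalities: a value exactly on a boundary does NOT earn the
#: better class.
MRECIST_DEFAULT_THRESHOLDS = {
    "CR": {"best": -95.0, "avg": -40.0},
    "PR": {"best": -50.0, "avg": -20.0},
    "SD": {"best": 35.0, "avg": 30.0},
}


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid tumor volume L*W^2/2 (mm^3); swaps if width > length."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        length, width = width, length
    return length * width * width / 2.0


def volumes_frame(series: pd.DataFrame) -> pd.DataFrame:
    """Add a ``volume_mm3`` column to a caliper table.

    Expects columns animal_id, arm, day, length_mm, width_mm; days must be
    strictly increasing per animal.
    """
    df = series.copy()
    df["volume_mm3"] = [tumor_volume(l, w)
                        for l, w in zip(df["length_mm"], df["width_mm"])]
    for aid, grp in df.groupby("animal_id"):
        d = grp["day"].to_numpy()
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"days must be strictly increasing for animal {aid!r}")
    return df


def _animal_rel_volume(grp: pd.DataFrame, day: float) -> float:
    """V(day)/V(0) for one animal, linearly interpolating between caliper days."""
    d = grp["day"].to_numpy(dtype=float)
    v = grp["volume_mm3"].to_numpy(dtype=float)
    v0 = v[d.argmin()]
    if d.min() > 0 or v0 <= 0:
        raise ValueError("missing positive baseline (day 0) volume")
    if day < d.min() or day > d.max():
        raise ValueError(f"day {day} outside measured range [{d.min()}, {d.max()}]")
    return float(np.interp(day, d, v)) / float(v0)


def relative_tgi(treated: pd.DataFrame, control: pd.DataFrame, day: float) -> float:
    """T/C: mean relative growth of treated animals over that of controls.

    Both frames are caliper tables (see :func:`volumes_frame`); relative
    growth of each animal is V(day)/V(0) with linear interpolation between
    measurement days.
    """
    out = []
    for df in (treated, control):
        dfv = volumes_frame(df)
        rels = [_animal_rel_volume(grp, day) for _, grp in dfv.groupby("animal_id")]
        out.append(float(np.mean(rels)))
    t, c = out
    if c <= 0:
        raise ValueError("control relative growth must be positive")
    return t / c


@dataclass
class ResponseCall:
    model_id: str
    arm: str
    best_response: float        # most negative % volume change, t >= t_min
    best_avg_response: float    # most negative running mean % change
    call: str                   # CR | PR | SD | PD
    tgi: float | None = None
    thresholds: dict = field(default_factory=lambda: dict(MRECIST_DEFAULT_THRESHOLDS))


def mrecist_call(
    series: pd.DataFrame,
    thresholds: dict | None = None,
    t_min: float = 10.0,
    model_id: str = "",
    arm: str | None = None,
) -> ResponseCall:
    """Modified-RECIST class for one treatment arm.

    The arm-mean percent volume change from baseline is computed at every
    measurement day; ``best_response`` is its minimum over days >= ``t_min``,
    ``best_avg_response`` the minimum over days >= ``t_min`` of the running
    mean of the percent-change series up to that day.  Classes (checked best
    to worst, strict inequalities):

    * CR: best < -95 and avg < -40
    * PR: best < -50 and avg < -20
    * SD: best < 35 and avg < 30
    * PD: otherwise
    """
    thr = thresholds if thresholds is not None else MRECIST_DEFAULT_THRESHOLDS
    dfv = volumes_frame(series)
    if arm is None:
        arms = dfv["arm"].unique()
        if len(arms) != 1:
            raise ValueError("series spans multiple arms; pass arm=")
        arm = str(arms[0])
    else:
        dfv = dfv[dfv["arm"] == arm]
    # per-animal % change trajectories, then arm mean per day
    pct = []
    for aid, grp in dfv.groupby("animal_id"):
        grp = grp.sort_values("day")
        if len(grp) < 2:
            raise ValueError(f"animal {aid!r} has fewer than 2 time points")
        v = grp["volume_mm3"].to_numpy(dtype=float)
        if v[0] <= 0:
            raise ValueError(f"animal {aid!r} baseline volume must be positive")
        pct.append(pd.Series(100.0 * (v / v[0] - 1.0), index=grp["day"].to_numpy()))
    pct_df = pd.DataFrame(pct)
    mean_pct = pct_df.mean(axis=0).sort_index()  # arm-mean % change per day
    days = mean_pct.index.to_numpy(dtype=float)
    vals = mean_pct.to_numpy(dtype=float)
    post = days > 0
    days, vals = days[post], vals[post]
    if days.size == 0:
        raise ValueError("need at least one post-baseline measurement")
    eligible = days >= t_min
    if not eligible.any():
        eligible = np.ones_like(days, dtype=bool)  # short studies: use all days
    best = float(vals[eligible].min())
    running_mean = np.cumsum(vals) / np.arange(1, vals.size + 1)
    best_avg = float(running_mean[eligible].min())

    if best < thr["CR"]["best"] and best_avg < thr["CR"]["avg"]:
        call = "CR"
    elif best < thr["PR"]["best"] and best_avg < thr["PR"]["avg"]:
        call = "PR"
    elif best < thr["SD"]["best"] and best_avg < thr["SD"]["avg"]:
        call = "SD"
    else:
        call = "PD"
    return ResponseCall(model_id=model_id, arm=arm, best_response=best,
                        best_avg_response=best_avg, call=call,
                        thresholds={k: dict(v) for k, v in thr.items()})


def regress_auc_tgi(pairs) -> tuple[float, float, float]:
    """Ordinary least squares of in vivo response on organoid AUC.

    ``pairs`` is an iterable of (auc_norm, response) tuples; returns
    (slope, intercept, R^2).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (auc, response) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in AUC values")
    if np.allclose(y, y[0]):  # flat response: R^2 defined as 0
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
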