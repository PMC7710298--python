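"""Weighted n-parameter logistic dose-response fitting and normalized AUC.

Organoid viability (fraction of untreated) versus log10 molar dose is fitted
with the n-parameter logistic family

    y(x) = B + (T - B) / (1 + 10^{b (x - xmid)})^s

where B is the bottom plateau, T the top plateau, xmid the log10 dose of the
inflection, b the slope per log10 dose (positive = viability falls with dose)
and s an asymmetry factor.  Lower-order variants fix B=0, T=1 and/or s=1; the
variant with the best weighted goodness-of-fit is reported.  Weights follow a
two-stage residual scheme: an unweighted fit provides residuals r_i, the final
fit minimizes sum w_i (y_i - yhat_i)^2 with w_i = 1/|r_i|^p.

The drug-sensitivity summary statistic is the area under the fitted curve
(viability clipped to [0, 1]) over the tested dose range, integrated with
composite Simpson's rule and divided by the range width so that the
normalized AUC lies in [0, 1]; lower AUC = more sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import least_squares

__all__ = [
    "DoseResponsePlate",
    "LogisticFit",
    "AUCRecord",
    "normalize_viability",
    "fit_logistic",
    "predict",
    "auc_simpson",
    "fit_and_auc",
    "read_plates_csv",
    "plates_to_frame",
]


@dataclass
class DoseResponsePlate:
    """Replicate viability observations for one drug on one organoid line.

    ``doses`` and ``viability`` are parallel per-observation vectors
    (replicates appear as repeated dose values); doses are log10 molar.
    """

    line_id: str
    drug: str
    doses: np.ndarray
    viability: np.ndarray
    untreated_mean: float = 1.0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.shape != self.viability.shape:
            raise ValueError("doses and viability must have equal length")
        if not np.all(np.isfinite(self.doses)):
            raise ValueError("all doses must be finite")
        if np.any(self.viability < 0):
            raise ValueError("viability must be non-negative")
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.viability = self.viability[order]

    @property
    def distinct_doses(self) -> np.ndarray:
        return np.unique(self.doses)

    @property
    def dose_range(self) -> tuple[float, float]:
        return float(self.doses.min()), float(self.doses.max())


@dataclass
class LogisticFit:
    """Fitted n-parameter logistic curve."""

    n_params: int
    bottom: float
    top: float
    xmid: float
    slope: float
    asymmetry: float = 1.0
    weight_exponent: float = 2.0
    converged: bool = True
    weighted_gof: float = float("nan")

    def __post_init__(self) -> None:
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")


@dataclass
class AUCRecord:
    line_id: str
    drug: str
    auc_raw: float
    auc_norm: float
    x_range: tuple[float, float]
    fit: LogisticFit | None = field(default=None, repr=False)


def normalize_viability(
    raw: pd.DataFrame | np.ndarray,
    untreated: np.ndarray,
    line_id: str = "",
    drug: str = "",
    doses: np.ndarray | None = None,
) -> DoseResponsePlate:
    """Normalize raw counts/luminescence to the mean of untreated wells.

    ``raw`` may be a long-format DataFrame with columns ``log10_dose`` and
    ``value`` (then ``doses`` is ignored) or a raw value array paired with a
    ``doses`` array of equal length.
    """
    untreated = np.asarray(untreated, dtype=float)
    if untreated.size < 1:
        raise ValueError("need at least one untreated well")
    u_mean = float(untreated.mean())
    if u_mean <= 0:
        raise ValueError("untreated mean must be positive")
    if isinstance(raw, pd.DataFrame):
        doses = raw["log10_dose"].to_numpy(dtype=float)
        values = raw["value"].to_numpy(dtype=float)
    else:
        values = np.asarray(raw, dtype=float)
        if doses is None:
            raise ValueError("doses required when raw is an array")
        doses = np.asarray(doses, dtype=float)
    return DoseResponsePlate(
        line_id=line_id,
        drug=drug,
        doses=doses,
        viability=values / u_mean,
        untreated_mean=u_mean,
    )


def _logistic(x, bottom, top, xmid, slope, s):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (x - xmid))) ** s


def predict(fit: LogisticFit, x) -> np.ndarray | float:
    """Evaluate the fitted curve at log10 dose ``x`` (scalar or array)."""
    return _logistic(np.asarray(x, dtype=float) if np.ndim(x) else float(x),
                     fit.bottom, fit.top, fit.xmid, fit.slope, fit.asymmetry)


# Candidate model orders: which parameters are free.
#   2: xmid, slope          (B=0, T=1, s=1)
#   3: top, xmid, slope     (B=0, s=1)
#   4: bottom, top, xmid, slope  (s=1)
#   5: all five
_FREE = {2: (), 3: ("top",), 4: ("bottom", "top"), 5: ("bottom", "top", "s")}


def _fit_order(x, y, w, n_params, x_lo, x_hi):
    """Weighted least squares for one model order; returns (theta, cost).

    theta = (bottom, dT, xmid, slope, s) with top = bottom + dT so the
    constraint T >= B is built in.  Deterministic multi-start over xmid
    quantiles and slope sign.
    """
    free = _FREE[n_params]
    sw = np.sqrt(w)

    def unpack(p):
        i = 0
        if "bottom" in free:
            bottom = p[i]; i += 1
        else:
            bottom = 0.0
        if "top" in free:
            dT = p[i]; i += 1
        else:
            dT = 1.0 - bottom
        xmid = p[i]; i += 1
        slope = p[i]; i += 1
        if "s" in free:
            s = p[i]; i += 1
        else:
            s = 1.0
        return bottom, dT, xmid, slope, s

    def resid(p):
        bottom, dT, xmid, slope, s = unpack(p)
        return sw * (_logistic(x, bottom, bottom + dT, xmid, slope, s) - y)

    lo, hi = [], []
    if "bottom" in free:
        lo.append(0.0); hi.append(2.0)
    if "top" in free:
        lo.append(0.0); hi.append(2.5)
    lo += [x_lo - 3.0, -15.0]
    hi += [x_hi + 3.0, 15.0]
    if "s" in free:
        lo.append(0.05); hi.append(20.0)
    lo = np.array(lo); hi = np.array(hi)

    span = x_hi - x_lo if x_hi > x_lo else 1.0
    xmid_grid = [x_lo + f * span for f in (0.25, 0.5, 0.75)]
    starts = [(m, 1.0) for m in xmid_grid] + [(x_lo + 0.5 * span, -1.0),
                                              (x_lo + 0.5 * span, 3.0)]

    best = None
    for xm0, b0 in starts:
        p0 = []
        if "bottom" in free:
            p0.append(max(0.0, float(np.min(y))))
        if "top" in free:
            t0 = float(np.max(y))
            p0.append(max(1e-3, t0 - (p0[0] if "bottom" in free else 0.0)))
        p0 += [xm0, b0]
        if "s" in free:
            p0.append(1.0)
        p0 = np.clip(np.array(p0, dtype=float), lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None, np.inf, False
    return unpack(best.x), 2.0 * best.cost, bool(best.success)


def fit_logistic(
    plate: DoseResponsePlate,
    max_params: int = 5,
    weighting: str = "residual",
    weight_exponent: float = 2.0,
) -> LogisticFit:
    """Two-stage weighted logistic fit with model-order selection.

    Candidate orders n in {2..max_params} are each fitted; the order with the
    best weighted goodness-of-fit (weighted R^2, ties broken toward fewer
    parameters) is returned.  ``weighting='none'`` skips the second stage.
    """
    if not 2 <= max_params <= 5:
        raise ValueError("max_params must be in 2..5")
    x = plate.doses
    y = plate.viability
    if plate.distinct_doses.size < max(4, 2):
        raise ValueError("need at least 4 distinct doses for fitting")
    if not np.all(np.isfinite(y)):
        raise ValueError("viability must be finite")
    x_lo, x_hi = plate.dose_range

    results = []
    for n in range(2, max_params + 1):
        if plate.distinct_doses.size < n:
            continue
        ones = np.ones_like(y)
        theta, _, ok1 = _fit_order(x, y, ones, n, x_lo, x_hi)
        if theta is None:
            continue
        w = ones
        if weighting == "residual":
            bottom, dT, xmid, slope, s = theta
            r = _logistic(x, bottom, bottom + dT, xmid, slope, s) - y
            floor = max(1e-6, 1e-3 * float(np.std(y)) if np.std(y) > 0 else 1e-6)
            w = 1.0 / np.maximum(np.abs(r), floor) ** weight_exponent
            w = w / w.mean()
            theta2, _, ok2 = _fit_order(x, y, w, n, x_lo, x_hi)
            if theta2 is not None:
                theta, ok1 = theta2, ok1 and ok2
        bottom, dT, xmid, slope, s = theta
        yhat = _logistic(x, bottom, bottom + dT, xmid, slope, s)
        ybar = float(np.average(y, weights=w))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        gof = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
        results.append((n, theta, gof, ok1))

    if not results:
        return LogisticFit(n_params=max_params, bottom=0.0, top=1.0,
                           xmid=0.5 * (x_lo + x_hi), slope=0.0,
                           converged=False, weighted_gof=float("nan"),
                           weight_exponent=weight_exponent)
    # best gof; within 1e-9 prefer fewer parameters (results are in n order)
    best_gof = max(g for _, _, g, _ in results)
    n, theta, gof, ok = next(r for r in results if r[2] >= best_gof - 1e-9)
    bottom, dT, xmid, slope, s = theta
    return LogisticFit(
        n_params=n, bottom=float(bottom), top=float(bottom + dT),
        xmid=float(xmid), slope=float(slope), asymmetry=float(s),
        weight_exponent=weight_exponent, converged=ok, weighted_gof=float(gof),
    )


def auc_simpson(
    fit: LogisticFit,
    x_range: tuple[float, float],
    n_grid: int = 201,
    line_id: str = "",
    drug: str = "",
    clip: bool = True,
) -> AUCRecord:
    """Composite-Simpson AUC of the fitted curve over ``x_range``.

    Predicted viability is clipped to [0, 1] before integration (so the
    normalized AUC is a dimensionless sensitivity score in [0, 1]); pass
    ``clip=False`` to integrate the raw curve.
    """
    lo, hi = float(x_range[0]), float(x_range[1])
    if not lo < hi:
        raise ValueError("x_range low must be < high")
    if n_grid < 11 or n_grid % 2 == 0:
        raise ValueError("n_grid must be an odd integer >= 11")
    xs = np.linspace(lo, hi, n_grid)
    ys = np.asarray(predict(fit, xs), dtype=float)
    if clip:
        ys = np.clip(ys, 0.0, 1.0)
    raw = float(simpson(ys, x=xs))
    return AUCRecord(line_id=line_id, drug=drug, auc_raw=raw,
                     auc_norm=raw / (hi - lo), x_range=(lo, hi), fit=fit)


def fit_and_auc(plate: DoseResponsePlate, x_range: tuple[float, float] | None = None,
                n_grid: int = 201, **fit_kwargs) -> AUCRecord:
    """Convenience: fit a plate then integrate over its observed dose range."""
    fit = fit_logistic(plate, **fit_kwargs)
    rng = x_range if x_range is not None else plate.dose_range
    return auc_simpson(fit, rng, n_grid=n_grid, line_id=plate.line_id,
                       drug=plate.drug)


def read_plates_csv(path) -> list[DoseResponsePlate]:
    """Read long-format viability CSV: line_id, drug, log10_dose, replicate, viability."""
    df = pd.read_csv(path)
    plates = []
    for (line_id, drug), grp in df.groupby(["line_id", "drug"], sort=True):
        plates.append(DoseResponsePlate(
            line_id=str(line_id), drug=str(drug),
            doses=grp["log10_dose"].to_numpy(dtype=float),
            viability=grp["viability"].to_numpy(dtype=float),
        ))
    return plates


def plates_to_frame(plates: list[DoseResponsePlate]) -> pd.DataFrame:
    rows = []
    for p in plates:
        rep_counter: dict[float, int] = {}
        for d, v in zip(p.doses, p.viability):
            rep_counter[d] = rep_counter.get(d, 0) + 1
            rows.append({"line_id": p.line_id, "drug": p.drug,
                         "log10_dose": d, "replicate": rep_counter[d],
                         "viability": v})
    return pd.DataFrame(rows)
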