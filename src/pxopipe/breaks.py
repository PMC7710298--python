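"""Jenks natural-breaks classification of drug-sensitivity AUC values.

Normalized dose-response AUC values are partitioned into k classes with the
exact Fisher-Jenks dynamic program (minimal total within-class sum of squared
deviations).  Among the resulting k-1 boundaries, the *segregation break* is
the one that best separates in vivo responders (PR/CR) from non-responders
(PD); an organoid model is then called *sensitive* to a regimen if any
component drug's AUC falls below that break, *resistant* only if all
components are at or above it.

Boundary convention: a break value is the smallest value of its upper class,
and belongs to the upper class (AUC >= break classifies as the resistant
side, matching the "at least the threshold is resistant" rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BreaksModel",
    "SensitivityCall",
    "ConcordanceReport",
    "jenks_breaks",
    "gvf",
    "select_class_count",
    "select_segregation_break",
    "classify_sensitivity",
    "concordance",
]


@dataclass
class BreaksModel:
    values: np.ndarray          # sorted ascending
    k: int
    breaks: np.ndarray          # k-1 boundary values, strictly increasing
    gvf: float
    labels: np.ndarray          # class index per *input-order* value
    class_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    segregation_break: float | None = None


def _prefix_sums(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """Within-class SS of sorted v[i:j] (half-open) via prefix sums."""
    n = j - i
    tot = s1[j] - s1[i]
    return (s2[j] - s2[i]) - tot * tot / n


def jenks_breaks(values: Sequence[float], k: int) -> BreaksModel:
    """Exact Fisher-Jenks optimal 1-D partition into ``k`` classes.

    O(k n^2) dynamic program; deterministic.  Cost ties are resolved toward
    the partition with the smallest leftmost break.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(arr).size < k:
        raise ValueError(f"need at least k={k} distinct values, have {np.unique(arr).size}")
    order = np.argsort(arr, kind="stable")
    v = arr[order]
    s1, s2 = _prefix_sums(v)

    # cost[c][j]: minimal SS of partitioning v[:j] into c classes
    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            # last class is v[i:j]; iterate i ascending so equal costs keep
            # the smallest i -> smallest leftmost break overall
            for i in range(c - 1, j):
                if cost[c - 1, i] == INF:
                    continue
                cand = cost[c - 1, i] + _sse(s1, s2, i, j)
                if cand < best - 1e-12:
                    best, best_i = cand, i
            cost[c, j] = best
            split[c, j] = best_i

    # reconstruct class start indices
    starts = []
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        starts.append(i)
        j = i
    starts = starts[::-1]  # k class start positions in sorted order; starts[0]=0

    breaks = np.array([v[s] for s in starts[1:]], dtype=float)
    sdam = _sse(s1, s2, 0, n)
    sdcm = float(cost[k, n])
    g = 1.0 if sdam <= 0 else 1.0 - sdcm / sdam

    labels_sorted = np.empty(n, dtype=int)
    bounds = starts + [n]
    sizes = []
    for c in range(k):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
        sizes.append(bounds[c + 1] - bounds[c])
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    return BreaksModel(values=v, k=k, breaks=breaks, gvf=float(np.clip(g, 0.0, 1.0)),
                       labels=labels, class_sizes=np.array(sizes))


def gvf(values: Sequence[float], breaks: Sequence[float]) -> float:
    """Goodness-of-variance fit 1 - SS_within / SS_total for a partition
    defined by threshold ``breaks`` (value >= break -> upper class)."""
    v = np.asarray(list(values), dtype=float)
    b = np.asarray(list(breaks), dtype=float)
    total = float(np.sum((v - v.mean()) ** 2))
    if total <= 0:
        return 1.0
    labels = np.searchsorted(np.sort(b), v, side="right")
    within = 0.0
    for c in np.unique(labels):
        grp = v[labels == c]
        within += float(np.sum((grp - grp.mean()) ** 2))
    return 1.0 - within / total


def select_class_count(
    values: Sequence[float],
    k_max: int = 8,
    gain_threshold: float = 0.05,
    gvf_target: float = 0.9,
) -> int:
    """Smallest class count whose refinement no longer pays.

    Returns the smallest k such that gvf(k) >= ``gvf_target`` or the marginal
    gain gvf(k+1) - gvf(k) < ``gain_threshold``; k_max if neither triggers.
    """
    v = np.asarray(list(values), dtype=float)
    n_distinct = np.unique(v).size
    k_cap = min(k_max, n_distinct)
    gvfs = {k: jenks_breaks(v, k).gvf
            for k in range(1, min(k_cap + 1, n_distinct) + 1)}
    for k in range(1, k_cap + 1):
        if gvfs[k] >= gvf_target:
            return k
        if k + 1 in gvfs and gvfs[k + 1] - gvfs[k] < gain_threshold:
            return k
    return k_cap


def select_segregation_break(
    model: BreaksModel,
    responder_labels: Sequence[bool],
) -> float:
    """Pick the Jenks boundary best separating responders from non-responders.

    ``responder_labels`` align with ``model.values`` (sorted order); True =
    in vivo responder (PR/CR).  A value is correctly separated when responders
    lie below the boundary and non-responders at/above it.  Ties go to the
    lower boundary.  If all labels are identical the lowest boundary is
    returned with a warning.
    """
    resp = np.asarray(list(responder_labels), dtype=bool)
    if resp.size != model.values.size:
        raise ValueError("responder_labels must align with model.values")
    if model.breaks.size == 0:
        raise ValueError("model has no interior breaks (k=1)")
    if resp.all() or (~resp).all():
        warnings.warn("all in vivo labels identical; returning lowest break",
                      stacklevel=2)
        model.segregation_break = float(model.breaks[0])
        return model.segregation_break
    best_b, best_correct = None, -1
    for b in model.breaks:  # ascending; strict > keeps the lower tie
        correct = int(np.sum(resp & (model.values < b))
                      + np.sum(~resp & (model.values >= b)))
        if correct > best_correct:
            best_b, best_correct = float(b), correct
    model.segregation_break = best_b
    return best_b


@dataclass
class SensitivityCall:
    model_id: str
    regimen: tuple[str, ...]
    component_aucs: dict[str, float]
    threshold: float
    call: str = field(init=False)

    def __post_init__(self) -> None:
        self.call = ("sensitive"
                     if min(self.component_aucs.values()) < self.threshold
                     else "resistant")


def classify_sensitivity(
    component_aucs: Mapping[str, float],
    threshold: float,
    model_id: str = "",
) -> SensitivityCall:
    """Sensitive iff any component drug's AUC is below ``threshold``;
    resistant only if every component is at or above it."""
    if not component_aucs:
        raise ValueError("regimen must have at least one component")
    missing = [d for d, a in component_aucs.items() if a is None or not np.isfinite(a)]
    if missing:
        raise ValueError(f"missing AUC for components: {missing}")
    return SensitivityCall(model_id=model_id,
                           regimen=tuple(component_aucs),
                           component_aucs=dict(component_aucs),
                           threshold=float(threshold))


@dataclass
class ConcordanceReport:
    responders_correct: int
    responders_total: int
    nonresponders_correct: int
    nonresponders_total: int

    @property
    def overall_correct(self) -> int:
        return self.responders_correct + self.nonresponders_correct

    @property
    def overall_total(self) -> int:
        return self.responders_total + self.nonresponders_total

    @property
    def overall_fraction(self) -> float:
        return self.overall_correct / self.overall_total


_RESPONDER_CLASSES = {"PR", "CR"}
_NONRESPONDER_CLASSES = {"PD"}


def concordance(
    calls: Mapping[str, SensitivityCall],
    in_vivo: Mapping[str, str],
) -> ConcordanceReport:
    """Score organoid sensitivity calls against in vivo response classes.

    ``in_vivo`` maps the same model/regimen keys to mRECIST classes; PR/CR
    are responders (correct call = sensitive), PD non-responders (correct =
    resistant); SD arms are excluded from scoring.  Key mismatches raise.
    """
    unmatched = sorted(set(calls) ^ set(in_vivo))
    if unmatched:
        raise ValueError(f"unmatched model/regimen keys: {unmatched}")
    if not calls:
        raise ValueError("empty call set")
    rc = rt = nc = nt = 0
    for key, call in calls.items():
        cls = in_vivo[key]
        if cls in _RESPONDER_CLASSES:
            rt += 1
            rc += call.call == "sensitive"
        elif cls in _NONRESPONDER_CLASSES:
            nt += 1
            nc += call.call == "resistant"
        elif cls != "SD":
            raise ValueError(f"unknown in vivo class {cls!r} for {key!r}")
    return ConcordanceReport(rc, rt, nc, nt)
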