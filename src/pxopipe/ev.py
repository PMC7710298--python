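"""Extracellular-vesicle proteomics enrichment and clinical blot statistics.

The discovery arm takes an EV protein intensity matrix (proteins x samples,
samples labelled tumor-organoid line or exocrine reference) and applies the
fold-change/prevalence enrichment filter: keep proteins detected in at least
``prevalence`` of the tumor lines whose mean tumor intensity is at least
``fold`` times the mean reference intensity.  Supporting steps: log2 +
quantile normalization and an SVD-based PCA of the normalized matrix.

The validation arm takes a Western-blot intensity table (markers x patients,
including a CD9 loading-control row): marker signals are divided by CD9 per
patient and rescaled so the per-marker cohort median is 100; cohorts are then
compared with the two-sample Kolmogorov-Smirnov test (exact for small
cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log_quantile_normalize",
    "enrichment_filter",
    "pca_svd",
    "PCAResult",
    "cd9_rescale",
    "ks_two_sample",
    "KSResult",
    "cohort_ks_report",
]


def log_quantile_normalize(matrix: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """log2(x+1) transform then quantile-normalize columns.

    Every column (sample) is mapped onto the mean sorted profile; tied values
    within a column receive the average of the quantile values they span
    (average-rank convention), so columns that are permutations of each other
    become identical multisets.  Zeros stay at the minimum rank.
    """
    df = matrix.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    if log:
        df = np.log2(df + 1.0)
    if df.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op",
                      stacklevel=2)
        return df
    x = df.to_numpy()
    sorted_cols = np.sort(x, axis=0)
    mean_profile = sorted_cols.mean(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)  # average ranks, 1-based
    # interpolate the mean profile at (possibly fractional) ranks
    out = np.interp(ranks, np.arange(1, x.shape[0] + 1), mean_profile)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def enrichment_filter(
    matrix: pd.DataFrame,
    roles: Mapping[str, str],
    fold: float = 2.0,
    prevalence: int = 4,
    detection_floor: float | None = None,
    per_line: bool = False,
) -> list[str]:
    """Fold-change + prevalence filter for tumor-EV-enriched proteins.

    Keep a protein if (a) it is detected (intensity >= ``detection_floor``,
    default the smallest nonzero intensity in the matrix) in at least
    ``prevalence`` tumor lines, and (b) its mean tumor intensity is at least
    ``fold`` times its mean reference intensity (linear scale; reference
    zeros are replaced by the floor).  ``per_line=True`` instead requires the
    fold criterion in each detected line individually.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    tumor_cols = [s for s, r in roles.items() if r == "tumor"]
    ref_cols = [s for s, r in roles.items() if r == "reference"]
    if not ref_cols:
        raise ValueError("no reference samples in roles")
    if prevalence > len(tumor_cols):
        raise ValueError("prevalence exceeds number of tumor lines")
    x = matrix[tumor_cols].to_numpy(dtype=float)
    ref = matrix[ref_cols].to_numpy(dtype=float)
    if detection_floor is None:
        nz = matrix.to_numpy()[matrix.to_numpy() > 0]
        detection_floor = float(nz.min()) if nz.size else 1.0
    detected = (x >= detection_floor).sum(axis=1)
    ref_mean = np.where(ref, ref, detection_floor).mean(axis=1)
    keep = detected >= prevalence
    if per_line:
        fold_ok = ((x >= fold * ref_mean[:, None]) | (x < detection_floor)).all(axis=1)
        fold_ok &= ((x >= detection_floor) & (x >= fold * ref_mean[:, None])).any(axis=1)
    else:
        fold_ok = x.mean(axis=1) >= fold * ref_mean
    keep &= fold_ok
    return [str(p) for p in matrix.index[keep]]


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained_variance_ratio: np.ndarray


def pca_svd(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of samples by singular value decomposition.

    Columns of ``matrix`` are samples (observations), rows features.  Features
    are centered and, if ``scale``, divided by their standard deviation
    (constant features are left unscaled).  Scores are U*S.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    if not np.any(x):
        raise ValueError("matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s ** 2
    ratio = var / var.sum()
    comps = [f"PC{i+1}" for i in range(s.size)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comps),
        explained_variance_ratio=ratio,
    )


def cd9_rescale(blot: pd.DataFrame, cd9_row: str = "CD9") -> pd.DataFrame:
    """Normalize marker blot intensities to CD9, median-rescaled to 100.

    Each marker row is divided by the CD9 row (per patient), then divided by
    its cohort-wide median and multiplied by 100, so every marker's median
    over the whole patient cohort is 100.
    """
    if cd9_row not in blot.index:
        raise ValueError(f"blot table lacks the {cd9_row!r} loading-control row")
    cd9 = blot.loc[cd9_row].astype(float)
    if (cd9 <= 0).any():
        raise ValueError("CD9 row must be strictly positive")
    markers = blot.drop(index=cd9_row).astype(float)
    ratios = markers / cd9
    med = ratios.median(axis=1)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"non-positive median ratio for markers: {bad}")
    return ratios.div(med, axis=0) * 100.0


class KSResult(NamedTuple):
    statistic: float
    pvalue: float
    mode: str


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def _ks_exact_p(n: int, m: int, d: float) -> float:
    """P(D >= d) under the null for continuous data, by counting the
    monotone lattice paths from (0,0) to (n,m) that stay strictly inside
    |i/n - j/m| < d; p = 1 - inside / C(n+m, n).

    O(n*m) dynamic program in floats scaled to path *probabilities* to avoid
    overflow: each cell holds the fraction of the C(n+m,n) orderings passing
    through it.
    """
    # strict inequality with a tolerance so the observed D itself counts as
    # "reached" (P(D >= d_obs) includes equality)
    eps = 1e-12
    prev = np.zeros(m + 1)
    prev[0] = 1.0
    # number of paths through (i, j) ~ C(i+j, i); work with log-free scaled
    # DP: scale column-by-column by binomial weights via recurrence on counts
    # kept as float64 (n*m <= 1e4 keeps counts < C(200,100) ~ 9e58, within
    # float range)
    inside = np.zeros((n + 1, m + 1))
    inside[0, 0] = 1.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i / n - j / m) >= d - eps:
                inside[i, j] = 0.0
                continue
            acc = 0.0
            if i > 0:
                acc += inside[i - 1, j]
            if j > 0:
                acc += inside[i, j - 1]
            inside[i, j] = acc
    from math import comb

    total = comb(n + m, n)
    return float(min(1.0, max(0.0, 1.0 - inside[n, m] / total)))


def ks_two_sample(x: Sequence[float], y: Sequence[float],
                  mode: str = "auto") -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``mode='exact'`` computes P(D >= d_obs) by lattice-path enumeration
    (feasible for n*m <= 1e4; assumes continuous data -- with cross-sample
    ties it falls back to the asymptotic p with a warning), ``'asymptotic'``
    uses the Kolmogorov limiting distribution, ``'auto'`` selects exact for
    small samples.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size * y.size <= 10_000 else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    d = _ks_d(x, y)
    if d == 0.0:
        return KSResult(0.0, 1.0, mode)
    if mode == "exact" and np.intersect1d(x, y).size:
        warnings.warn("cross-sample ties: exact KS enumeration assumes "
                      "continuous data, using asymptotic p", stacklevel=2)
        mode = "asymptotic"
    if mode == "exact":
        p = _ks_exact_p(x.size, y.size, d)
    else:
        p = float(stats.ks_2samp(x, y, alternative="two-sided",
                                 method="asymp").pvalue)
    return KSResult(d, p, mode)


def cohort_ks_report(
    rescaled: pd.DataFrame,
    cohorts: Mapping[str, str],
    group_a: str,
    group_b: str,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-marker KS comparison of two patient cohorts on a rescaled blot table."""
    a_cols = [p for p, c in cohorts.items() if c == group_a]
    b_cols = [p for p, c in cohorts.items() if c == group_b]
    if not a_cols or not b_cols:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    for marker in rescaled.index:
        r = ks_two_sample(rescaled.loc[marker, a_cols], rescaled.loc[marker, b_cols],
                          mode=mode)
        rows.append({"marker": marker, "D": r.statistic, "pvalue": r.pvalue,
                     "mode": r.mode,
                     "median_" + group_a: float(rescaled.loc[marker, a_cols].median()),
                     "median_" + group_b: float(rescaled.loc[marker, b_cols].median())})
    return pd.DataFrame(rows).set_index("marker")
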