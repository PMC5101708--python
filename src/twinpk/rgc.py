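"""Repeated-measures genetic component (rGC).

With a drug given repeatedly to the same subjects, the between-subject
variance Vb of the occasion means and the mean within-subject variance
Vw bound the heritable-plus-familial fraction of variability:

    rGC = (Vb − Vw) / Vb

Because the two siblings of a twin pair are not independent, the
statistic is computed on random one-sibling-per-pair subsets; the mean
over (by default 50) such resamples is the point estimate and the
2.5/97.5 percentiles of the resample values give the 95 % interval.

Vb is the raw sample variance of per-subject occasion means (no
subtraction of Vw/n_occ), following the original formulation; rGC may
therefore be negative when Vw > Vb, and negative values are reported,
not truncated.

`RepeatedMeasuresGC` follows the scikit-learn estimator protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "RGCResult",
    "within_between_variance",
    "rgc_from_variances",
    "compute_rgc",
    "RepeatedMeasuresGC",
]


@dataclass
class RGCResult:
    vb: float
    vw: float
    rgc: float
    ci_95: tuple[float, float]
    n_resamples: int
    n_skipped: int = 0
    per_resample_values: list[float] = field(default_factory=list)


def within_between_variance(
    values_by_subject: dict[str, np.ndarray]
) -> tuple[float, float]:
    """(vw, vb) for a set of subjects with repeated measurements.

    vw = mean over subjects of the per-subject sample variance (ddof=1;
    subjects with <2 occasions are excluded from vw but their
    available-occasion mean still enters vb); vb = sample variance
    (ddof=1) of per-subject means.
    """
    means, wvars = [], []
    for vals in values_by_subject.values():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            continue
        means.append(v.mean())
        if v.size >= 2:
            wvars.append(v.var(ddof=1))
    if len(means) < 2 or not wvars:
        raise ValueError(
            "need >=2 subjects with means and >=1 subject with >=2 occasions"
        )
    return float(np.mean(wvars)), float(np.var(means, ddof=1))


def rgc_from_variances(vb: float, vw: float) -> float:
    """The Kalow genetic component (Vb − Vw)/Vb; requires vb > 0."""
    if vb <= 0:
        raise ValueError("vb must be positive")
    return (vb - vw) / vb


def compute_rgc(
    data: pd.DataFrame,
    value_col: str,
    n_resamples: int = 50,
    seed: int | None = 0,
) -> RGCResult:
    """rGC with random-sibling resampling.

    ``data`` is long-format with columns subject_id, pair_id, occasion
    and ``value_col``.  Each replicate keeps one randomly chosen sibling
    per pair; replicates where vb = 0 are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    pairs: dict[str, list[tuple[str, np.ndarray]]] = {}
    for (pid, sid), g in data.groupby(["pair_id", "subject_id"], sort=True):
        pairs.setdefault(str(pid), []).append((str(sid), g[value_col].to_numpy()))
    if not pairs:
        raise ValueError("no paired data")
    values, vws, vbs = [], [], []
    skipped = 0
    for _ in range(n_resamples):
        subset = {}
        for pid, members in pairs.items():
            sid, vals = members[rng.integers(0, len(members))]
            subset[sid] = vals
        try:
            vw, vb = within_between_variance(subset)
            values.append(rgc_from_variances(vb, vw))
            vws.append(vw)
            vbs.append(vb)
        except (ValueError, ZeroDivisionError):
            skipped += 1
    if not values:
        raise ValueError("every resample was degenerate (vb = 0)")
    arr = np.asarray(values)
    return RGCResult(
        vb=float(np.mean(vbs)),
        vw=float(np.mean(vws)),
        rgc=float(arr.mean()),
        ci_95=(float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        n_resamples=n_resamples,
        n_skipped=skipped,
        per_resample_values=[float(v) for v in arr],
    )


class RepeatedMeasuresGC(BaseEstimator):
    """Scikit-learn style estimator for the repeated-measures genetic
    component.

    Parameters
    ----------
    n_resamples : number of one-sibling-per-pair resamples (default 50)
    seed : RNG seed for sibling selection
    """

    def __init__(self, n_resamples: int = 50, seed: int = 0):
        self.n_resamples = n_resamples
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None, value_col: str = "value"):
        res = compute_rgc(X, value_col, self.n_resamples, self.seed)
        self.result_ = res
        self.vb_, self.vw_ = res.vb, res.vw
        self.rgc_, self.ci_95_ = res.rgc, res.ci_95
        return self
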