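"""Nonparametric ROC analysis and the paired (DeLong-type) AUC comparison.

The AUC is the Mann-Whitney probability that a random case outscores a random
control, with ties counted one half; it is computed from midranks in
O(n log n).  Per-case and per-control *placement values*

    V10_i = mean_j psi(case_i, control_j),   V01_j = mean_i psi(case_i, control_j),
    psi = 1 if case > control, 0.5 if equal, 0 otherwise,

both average to the AUC, and their sample variances (and, for two paired
scores on the same participants, covariances) give the asymptotic variance of
the AUC and of a paired AUC difference.  The paired z-test on
``delta / sqrt(var_delta)`` compares the discriminatory ability of two scores
measured on the same cohort — here the raw and the genetically corrected
biomarker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    cases, controls = s[y == 1], s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes must be present")
    return cases, controls


def placement_values(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-case (V10) and per-control (V01) placement values via midranks.

    ``mean(V10) == mean(V01) == auc_midrank(scores, labels)``.
    """
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    r_all = rankdata(np.concatenate([cases, controls]))
    v10 = (r_all[:m] - rankdata(cases)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(controls)) / m
    return v10, v01


def auc_midrank(scores, labels) -> float:
    """Mann-Whitney AUC (ties as 1/2) from midranks."""
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    r_all = rankdata(np.concatenate([cases, controls]))
    return float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class RocResult:
    """AUC with placement-value variance, normal CI and a Youden operating
    point."""
    auc: float
    var_auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int


@dataclass
class RocComparison:
    """Paired comparison of two scores' AUCs on the same participants."""
    auc_a: float
    auc_b: float
    delta: float                 # auc_b - auc_a
    var_delta: float
    z: float
    p: float
    relative_change_pct: float   # 100 * delta / auc_a


def auc_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with the placement-value variance ``var(V10)/m + var(V01)/n`` and a
    normal-approximation CI clipped to [0, 1]."""
    v10, v01 = placement_values(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls for a variance")
    auc = float(v10.mean())
    var = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    z = float(norm.ppf(0.5 + level / 2))
    half = z * math.sqrt(var)
    thr, sens, spec = youden_operating_point(scores, labels)
    return RocResult(auc=auc, var_auc=var,
                     ci_low=max(0.0, auc - half), ci_high=min(1.0, auc + half),
                     threshold=thr, sensitivity=sens, specificity=spec,
                     n_cases=m, n_controls=n)


def delong_compare(scores_a, scores_b, labels,
                   method: str = "asymptotic", n_boot: int = 2000,
                   rng: np.random.Generator | None = None) -> RocComparison:
    """Paired nonparametric test of ``AUC_b - AUC_a`` for two scores measured
    on the same participants.

    ``method="asymptotic"`` uses the placement-value variance/covariance and a
    two-sided normal p; ``method="bootstrap"`` resamples participants to
    estimate the standard error of the difference (useful at small n).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors differ in length")
    v10a, v01a = placement_values(a, labels)
    v10b, v01b = placement_values(b, labels)
    m, n = len(v10a), len(v01a)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_b - auc_a

    if method == "asymptotic":
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
        var_delta = float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                          + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
        var_delta = max(var_delta, 0.0)
    elif method == "bootstrap":
        rng = np.random.default_rng() if rng is None else rng
        y = np.asarray(labels)
        deltas = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, len(y), len(y))
            while y[idx].min() == y[idx].max():
                idx = rng.integers(0, len(y), len(y))
            deltas[i] = auc_midrank(b[idx], y[idx]) - auc_midrank(a[idx], y[idx])
        var_delta = float(deltas.var(ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")

    if var_delta == 0.0:
        z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = delta / math.sqrt(var_delta)
        p = float(2 * norm.sf(abs(z)))
    return RocComparison(auc_a=auc_a, auc_b=auc_b, delta=delta,
                         var_delta=var_delta, z=z, p=p,
                         relative_change_pct=100.0 * delta / auc_a)


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    A participant is called positive when ``score >= threshold``; ties in J
    are broken toward the higher threshold (higher specificity).
    """
    cases, controls = _split(scores, labels)
    cand = np.unique(np.concatenate([cases, controls]))
    cs, ks = np.sort(cases), np.sort(controls)
    # P(case >= t) and P(control < t) for every candidate threshold
    sens = 1.0 - np.searchsorted(cs, cand, side="left") / len(cs)
    spec = np.searchsorted(ks, cand, side="left") / len(ks)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]   # last argmax -> highest threshold
    return float(cand[best]), float(sens[best]), float(spec[best])


def relative_improvement(auc_a: float, auc_b: float) -> float:
    """Relative AUC change 100*(auc_b - auc_a)/auc_a, one decimal."""
    if auc_a <= 0:
        raise ValueError("reference AUC must be > 0")
    return round(100.0 * (auc_b - auc_a) / auc_a, 1)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve coordinates (fpr, tpr, threshold), thresholds descending,
    with the trivial (0,0) and (1,1) endpoints."""
    cases, controls = _split(scores, labels)
    cand = np.unique(np.concatenate([cases, controls]))[::-1]
    cs, ks = np.sort(cases), np.sort(controls)
    tpr = 1.0 - np.searchsorted(cs, cand, side="left") / len(cs)
    fpr = 1.0 - np.searchsorted(ks, cand, side="left") / len(ks)
    return pd.DataFrame({
        "threshold": np.concatenate([[math.inf], cand]),
        "fpr": np.concatenate([[0.0], fpr]),
        "tpr": np.concatenate([[0.0], tpr]),
    })
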