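"""Method-agreement regression and paired nonparametric tests.

Agreement between two ways of measuring the same parameter (two fitting
methods, or two acquisitions) is summarised by unweighted OLS of one on
the other with nested categorical bands:

* excellent: 0.9 <= slope <= 1.1 and R^2 > 0.9
* good:      0.8 <= slope <= 1.2 and R^2 > 0.7
* moderate:  0.7 <= slope <= 1.3 and R^2 > 0.5
* poor:      otherwise

Paired comparisons (injured vs healthy, or method-A delta vs method-B
delta) use the Wilcoxon signed-rank test: zero differences dropped,
midranks for ties, test statistic W = min(W+, W-), exact null
distribution for up to 25 effective pairs and a continuity- and
tie-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import ROIStats, SensitivityDelta

__all__ = [
    "AgreementResult",
    "PairedTestResult",
    "classify_agreement",
    "linreg_agreement",
    "wilcoxon_signed_rank",
    "cohort_compare",
    "compare_deltas",
]

_EXACT_MAX_N = 25


@dataclass(frozen=True)
class AgreementResult:
    slope: float
    intercept: float
    r_squared: float
    category: str
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    significant: bool
    degenerate: bool = False
    mode: str = "exact"  # 'exact' or 'approx'


def classify_agreement(slope: float, r_squared: float) -> str:
    """Nested agreement bands, evaluated best-first (total on all inputs)."""
    if 0.9 <= slope <= 1.1 and r_squared > 0.9:
        return "excellent"
    if 0.8 <= slope <= 1.2 and r_squared > 0.7:
        return "good"
    if 0.7 <= slope <= 1.3 and r_squared > 0.5:
        return "moderate"
    return "poor"


def linreg_agreement(x, y) -> AgreementResult:
    """Unweighted OLS ``y = slope * x + intercept`` with its agreement band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return AgreementResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        category=classify_agreement(float(fit.slope), r2),
        n=int(x.size),
    )


def _exact_wplus_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2*W+ (doubled midranks)."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_signed_rank(a, b, alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test of ``a`` vs ``b``.

    Zero differences are dropped (classical Wilcoxon rule). The exact
    two-sided p for n_effective <= 25 is
    ``P(W+ <= w) + P(W+ >= T - w)`` with ``w = min(W+, W-)`` under the
    sign-flip null; larger samples use the normal approximation with
    continuity and tie corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be vectors of equal length")
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return PairedTestResult(0.0, 1.0, 0, False, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    total = n * (n + 1) / 2.0
    if n <= _EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_wplus_counts(ranks2)
        w2 = int(np.rint(2 * w))
        t2 = int(ranks2.sum())
        n_assign = counts.sum()
        p = (counts[: w2 + 1].sum() + counts[t2 - w2 :].sum()) / n_assign
        p = float(min(p, 1.0))
        mode = "exact"
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (abs(w - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        mode = "approx"
    return PairedTestResult(
        statistic=w, p_value=p, n_effective=n, significant=bool(p < alpha), mode=mode
    )


def cohort_compare(
    pairs: Sequence[tuple[ROIStats, ROIStats]], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired injured-vs-healthy tests, one row per shared parameter.

    ``pairs`` holds one (injured, healthy) ROIStats tuple per subject.
    Subjects missing a parameter on either side are dropped for that
    parameter.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two subjects")
    params: list[str] = []
    for inj, heal in pairs:
        for k in inj.values:
            if k in heal.values and k not in params:
                params.append(k)
    rows = []
    for p in params:
        a = [inj.values[p] for inj, heal in pairs if p in inj.values and p in heal.values]
        b = [heal.values[p] for inj, heal in pairs if p in inj.values and p in heal.values]
        res = wilcoxon_signed_rank(a, b, alpha=alpha)
        rows.append(
            {
                "parameter": p,
                "n": len(a),
                "n_effective": res.n_effective,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "mode": res.mode,
            }
        )
    return pd.DataFrame(rows)


def compare_deltas(
    deltas_a: Sequence[SensitivityDelta],
    deltas_b: Sequence[SensitivityDelta],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired test of the sensitivity measure between two methods.

    Tests, per parameter, whether delta(injured-healthy) differs between
    method A and method B across subjects (the primary outcome of a
    method-acceleration comparison).
    """
    if len(deltas_a) != len(deltas_b):
        raise ValueError("the two delta sequences must pair up subject-wise")
    params: list[str] = []
    for da, db in zip(deltas_a, deltas_b):
        for k in da.deltas:
            if k in db.deltas and k not in params:
                params.append(k)
    rows = []
    for p in params:
        a = [da.deltas[p] for da, db in zip(deltas_a, deltas_b) if p in da.deltas and p in db.deltas]
        b = [db.deltas[p] for da, db in zip(deltas_a, deltas_b) if p in da.deltas and p in db.deltas]
        res = wilcoxon_signed_rank(a, b, alpha=alpha)
        rows.append(
            {
                "parameter": p,
                "n": len(a),
                "n_effective": res.n_effective,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "mode": res.mode,
            }
        )
    return pd.DataFrame(rows)
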