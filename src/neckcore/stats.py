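"""Paired nonparametric testing and the EMG-versus-effort exponential fit.

The comparison of each force manipulation to its baseline condition uses
the one-tailed paired Wilcoxon signed-rank test, with the exact null
distribution (enumerated by dynamic programming over rank subset sums)
for n ≤ 25 effective pairs without ties, and a tie- and
continuity-corrected normal approximation otherwise.  Familywise error
over the eight muscles is controlled with the Holm step-down
(sequentially rejective Bonferroni) adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats

from .signal_model import ValidationError

EXACT_CUTOFF = 25  # largest n for which the exact null distribution is used


@dataclass
class WilcoxonResult:
    """One-tailed paired signed-rank test result."""

    n_effective: int  # pairs with nonzero difference
    w_plus: float  # sum of ranks of positive differences
    p_one_tailed: float
    direction: str  # "greater": manipulation > control; "less": <
    method: str  # "exact" | "normal_approx" | "degenerate"

    def __post_init__(self) -> None:
        max_w = self.n_effective * (self.n_effective + 1) / 2
        if not 0 <= self.w_plus <= max_w:
            raise ValidationError("W+ outside [0, n(n+1)/2]")
        if not 0 < self.p_one_tailed <= 1:
            raise ValidationError("p-value outside (0, 1]")


@dataclass
class CorrectedFamily:
    """Holm step-down adjusted p-values for one family of comparisons."""

    raw_p: np.ndarray
    adjusted_p: np.ndarray
    alpha: float
    reject: np.ndarray
    family_size: int


@dataclass
class ExpFit:
    """Least-squares fit of y = a·exp(b·x)."""

    a: float
    b: float
    rss: float
    n: int
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


def _exact_sf(n: int, w: float) -> float:
    """P(W+ >= w) under the signed-rank null, by subset-sum counting.

    Each rank 1..n independently joins W+ with probability 1/2; the count
    of sign assignments reaching each W+ value is built by convolution.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = 2.0**n
    w_ceil = int(math.ceil(w - 1e-9))
    return float(counts[w_ceil:].sum() / total)


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]] | np.ndarray,
    direction: str = "greater",
    exact_cutoff: int = EXACT_CUTOFF,
) -> WilcoxonResult:
    """One-tailed paired Wilcoxon signed-rank test.

    ``pairs`` holds (control, manipulation) values; differences are
    manipulation − control.  Zero differences are dropped (Wilcoxon's
    original treatment); tied absolute differences are mid-ranked.  The
    exact distribution is used for ``n_effective <= exact_cutoff`` without
    ties; otherwise a normal approximation with tie correction and a 0.5
    continuity correction.  With all differences zero the test is
    degenerate and p = 1.
    """
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValidationError("pairs must be an (n, 2) array of (control, manipulation)")
    d = arr[:, 1] - arr[:, 0]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 1.0, direction, "degenerate")
    ranks = spstats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if direction == "less":
        # small W+ is extreme; by symmetry test W- = n(n+1)/2 - W+ as "greater"
        w_stat = n * (n + 1) / 2 - w_plus
    else:
        w_stat = w_plus
    if n <= exact_cutoff and not has_ties:
        p = _exact_sf(n, w_stat)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
        if var <= 0:
            return WilcoxonResult(n, w_plus, 1.0, direction, "degenerate")
        z = (w_stat - mean - 0.5) / math.sqrt(var)  # continuity-corrected upper tail
        p = float(spstats.norm.sf(z))
        method = "normal_approx"
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return WilcoxonResult(n, w_plus, p, direction, method)


def holm_bonferroni(raw_p: list[float] | np.ndarray, alpha: float = 0.05) -> CorrectedFamily:
    """Holm step-down adjustment mapped back to the input order.

    adjusted_(i) = max_{j<=i} min(1, (m−j+1)·p_(j)) over ascending raw
    p-values; rejection proceeds while adjusted < alpha.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(stepped)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return CorrectedFamily(
        raw_p=p,
        adjusted_p=adjusted,
        alpha=alpha,
        reject=adjusted < alpha,
        family_size=m,
    )


def ratio_table(
    per_subject: dict[str, dict[str, tuple[float, float]]],
    direction: str = "greater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Condition-comparison summary table over a muscle family.

    ``per_subject[muscle][subject] = (baseline_value, manipulation_value)``
    where the values are identically processed per-subject metrics (e.g.
    mean cycle integrals).  Rows report N, mean ± SD of the per-subject
    manipulation/baseline ratios, the raw one-tailed signed-rank p and the
    Holm-adjusted p over the family.  Subjects with a non-positive
    baseline are excluded; muscles with N < 2 are flagged (no test).
    """
    rows = []
    testable: list[str] = []
    raw_ps: list[float] = []
    for muscle, pairs in per_subject.items():
        ratios = []
        test_pairs = []
        excluded = 0
        for _subject, (base, manip) in pairs.items():
            if base <= 0:
                excluded += 1
                continue
            ratios.append(manip / base)
            test_pairs.append((base, manip))
        n = len(ratios)
        row = {
            "muscle": muscle,
            "n": n,
            "mean_ratio": float(np.mean(ratios)) if n else float("nan"),
            "sd_ratio": float(np.std(ratios, ddof=1)) if n > 1 else float("nan"),
            "n_excluded": excluded,
            "raw_p": float("nan"),
            "adjusted_p": float("nan"),
            "reject": False,
            "tested": n >= 2,
        }
        if n >= 2:
            res = wilcoxon_signed_rank(test_pairs, direction=direction)
            row["raw_p"] = res.p_one_tailed
            testable.append(muscle)
            raw_ps.append(res.p_one_tailed)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("muscle")
    if raw_ps:
        fam = holm_bonferroni(raw_ps, alpha=alpha)
        frame.loc[testable, "adjusted_p"] = fam.adjusted_p
        frame.loc[testable, "reject"] = fam.reject
    return frame.reset_index()


def fit_exponential(x: np.ndarray, y: np.ndarray) -> ExpFit:
    """Untransformed nonlinear least squares for y = a·exp(b·x).

    Initialized from a log-linear regression on the y > 0 points.  Fitting
    the untransformed residuals matches a least-squares fit *to y* (a
    log-space regression would re-weight the errors).  On non-convergence
    the log-linear parameters are returned flagged unconverged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least three (x, y) points")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValidationError("fit inputs must be finite")
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        b0, log_a0 = np.polyfit(x[pos], np.log(y[pos]), 1)
        a0 = math.exp(log_a0)
    else:
        a0, b0 = max(float(np.mean(y)), 1e-12), 0.0
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=(a0, b0), maxfev=20000
        )
        a, b = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a, b, converged = a0, b0, False
    rss = float(np.sum((y - a * np.exp(b * x)) ** 2))
    return ExpFit(a=a, b=b, rss=rss, n=int(x.size), converged=converged)
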