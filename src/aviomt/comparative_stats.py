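"""Group comparisons, correlations and curve fits for transmittance metrics.

Implements the comparative toolbox used on the species table: per-group
summaries of lambda_T0.5, two-group tests with a Shapiro-Wilk normality
gate (t-test when both groups look normal, Wilcoxon rank-sum otherwise),
Dunn-Sidak correction for families of tests, Spearman rank correlation,
and least-squares curve fits (linear, quadratic, and two-term exponential
a*exp(b*x) + c*exp(d*x)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .species import SpeciesTable


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
    family_size: int
    corrected_alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


@dataclass(frozen=True)
class FitResult:
    family: str  # "linear" | "poly2" | "two_term_exponential"
    coefficients: tuple[float, ...]
    rss: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] * x + c[1]
        if self.family == "poly2":
            return c[0] * x ** 2 + c[1] * x + c[2]
        if self.family == "two_term_exponential":
            return c[0] * np.exp(c[1] * x) + c[2] * np.exp(c[3] * x)
        raise ValueError(f"unknown family {self.family!r}")


def dunn_sidak_alpha(family_size: int, alpha: float = 0.05) -> float:
    """Per-comparison alpha for a family of tests: 1 - (1 - alpha)^(1/n)."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / family_size)


def summarize_groups(table: SpeciesTable, grouping: Sequence[str] | None = None,
                     by: str = "group_label", value: str = "lambda_t50") -> pd.DataFrame:
    """Per-group n, mean, sample sd, min and max of a species-table column."""
    df = table.df
    labels = list(grouping) if grouping is not None else sorted(df[by].dropna().unique())
    rows = []
    for label in labels:
        vals = df.loc[df[by] == label, value].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {label!r} is empty")
        rows.append({
            "group": label, "n": vals.size, "mean": vals.mean(),
            "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
            "min": vals.min(), "max": vals.max(),
        })
    return pd.DataFrame(rows).set_index("group")


def compare_groups(a: Sequence[float], b: Sequence[float], family_size: int = 1,
                   names: tuple[str, str] = ("a", "b"), alpha: float = 0.05,
                   normality_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Both groups are screened with Shapiro-Wilk at ``normality_alpha``; when
    both pass (and both have n >= 3, the minimum for the test), an unpaired
    two-tailed t-test is used, otherwise a two-tailed Wilcoxon rank-sum test.
    The rank-sum test uses exact enumeration for small tie-free samples
    (both n < 8) and the tie-corrected normal approximation otherwise.
    The reported corrected alpha applies the Dunn-Sidak adjustment for the
    comparison family.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")

    def _normal(v: np.ndarray) -> bool:
        if v.size < 3 or np.ptp(v) == 0:
            return False
        return stats.shapiro(v).pvalue > normality_alpha

    if _normal(x) and _normal(y):
        test = "t"
        res = stats.ttest_ind(x, y)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        test = "wilcoxon"
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size < 8 and y.size < 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        group_a=names[0], group_b=names[1], n_a=x.size, n_b=y.size,
        mean_a=float(x.mean()), mean_b=float(y.mean()),
        sd_a=float(x.std(ddof=1)), sd_b=float(y.std(ddof=1)),
        test=test, statistic=statistic, p_value=p,
        family_size=family_size, corrected_alpha=dunn_sidak_alpha(family_size, alpha),
    )


def correlate_spearman(x: Sequence[float], y: Sequence[float]) -> dict:
    """Tie-corrected Spearman rank correlation on complete pairs.

    Pairs with a missing value in either variable are dropped; the count of
    pairs actually used is reported as ``n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(x.size)}


def _fit_two_term_exponential(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, ...], float]:
    """Nonlinear least squares for a*exp(b*x) + c*exp(d*x) with multi-start.

    Starts are seeded deterministically: a log-linear fit of |y| gives one
    rate estimate; sign patterns and scale multiples of that rate span the
    start list. The best converged fit by residual sum of squares wins.
    """
    span = np.ptp(x)
    if span == 0:
        raise ValueError("x values are constant")
    # log-linear seed for the dominant rate
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(x[pos], np.log(y[pos]), 1)[0]
    else:
        slope = 0.0
    base_rates = sorted({abs(slope), 1.0 / span, 0.1 / span}) or [1.0 / span]

    def model(p, xv):
        return p[0] * np.exp(p[1] * xv) + p[2] * np.exp(p[3] * xv)

    def resid(p):
        return model(p, x) - y

    best = None
    yshift = float(np.mean(y))
    for r1 in base_rates:
        for s1 in (+1.0, -1.0):
            for r2 in base_rates:
                for s2 in (+1.0, -1.0):
                    b0, d0 = s1 * r1, s2 * r2
                    # linear solve for amplitudes given the rates
                    basis = np.column_stack([np.exp(b0 * x), np.exp(d0 * x)])
                    try:
                        amps, *_ = np.linalg.lstsq(basis, y, rcond=None)
                    except np.linalg.LinAlgError:
                        amps = np.array([yshift, 0.0])
                    p0 = np.array([amps[0], b0, amps[1], d0])
                    if not np.all(np.isfinite(p0)):
                        continue
                    try:
                        sol = optimize.least_squares(resid, p0, method="lm",
                                                     max_nfev=5000)
                    except (ValueError, RuntimeError):
                        continue
                    rss = float(np.sum(sol.fun ** 2))
                    if np.all(np.isfinite(sol.x)) and (best is None or rss < best[1]):
                        best = (tuple(float(v) for v in sol.x), rss)
    if best is None:
        raise RuntimeError("two-term exponential fit did not converge from any start")
    return best


def fit_curve(x: Sequence[float], y: Sequence[float], family: str) -> FitResult:
    """Least-squares fit of one of the supported curve families."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n_coef = {"linear": 2, "poly2": 3, "two_term_exponential": 4}
    if family not in n_coef:
        raise ValueError(f"unknown family {family!r}")
    if x.size <= n_coef[family]:
        raise ValueError(f"need more than {n_coef[family]} points for {family}")
    if family == "linear":
        coef = np.polyfit(x, y, 1)
        rss = float(np.sum((np.polyval(coef, x) - y) ** 2))
        return FitResult("linear", tuple(float(c) for c in coef), rss, x.size)
    if family == "poly2":
        coef = np.polyfit(x, y, 2)
        rss = float(np.sum((np.polyval(coef, x) - y) ** 2))
        return FitResult("poly2", tuple(float(c) for c in coef), rss, x.size)
    coef, rss = _fit_two_term_exponential(x, y)
    return FitResult("two_term_exponential", coef, rss, x.size)
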