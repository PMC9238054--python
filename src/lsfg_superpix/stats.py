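"""Cohort-level statistics on paired-eye flow measures.

The study design is cross-sectional with each patient's fellow
(untreated) eye as an internal control, so the statistics are:

* paired two-tailed t-tests of irradiated vs fellow eyes,
* per-patient differences (irradiated minus fellow) with the count of
  patients whose flow decreased,
* ordinary least-squares regression of each measure on time from
  treatment, per eye group, and
* a Spearman rank-correlation matrix over the outcome measures and the
  treatment covariates, with pairwise-complete handling of missing dose
  and distance records.

No multiple-testing correction is applied by default (matrix significance
is flagged at alpha = 0.01); a Bonferroni option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "SpearmanMatrix",
    "average_scans",
    "paired_t",
    "paired_differences",
    "linreg_vs_time",
    "spearman_matrix",
]


@dataclass(frozen=True)
class StatResult:
    """One test or fit: the statistic, its two-tailed p, and context.

    ``kind`` is ``paired_t`` (statistic = t), ``linreg`` (statistic =
    slope per month) or ``spearman`` (statistic = rho).  ``direction`` is
    the sign of the effect (sign of the mean difference, slope, or rho).
    """

    kind: str
    statistic: float
    p_value: float
    n: int
    direction: int
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.n >= 3 and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def average_scans(values, allow_missing: bool = False) -> float:
    """Per-eye measure: the arithmetic mean of the three repeat scans.

    With ``allow_missing`` a short (>=1) list is averaged with a warning
    left to the caller's logger; otherwise exactly 3 finite values are
    required.
    """
    vals = list(values)
    arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
    if not allow_missing and (len(vals) != 3 or arr.size != 3):
        raise ValueError(f"expected exactly 3 finite scan values, got {vals}")
    if arr.size == 0:
        raise ValueError("no finite scan values to average")
    return float(arr.mean())


def paired_t(irr, fellow) -> StatResult:
    """Paired two-tailed t-test of irradiated vs fellow eyes.

    Pairs are aligned by position (one entry per patient).  With zero
    variance of the differences the t statistic is undefined: an all-zero
    difference vector is rejected, while identical nonzero differences are
    reported with p = 0 (the degenerate limit).
    """
    irr = np.asarray(irr, dtype=float)
    fellow = np.asarray(fellow, dtype=float)
    if irr.shape != fellow.shape or irr.ndim != 1:
        raise ValueError("irradiated and fellow measures must be equal-length vectors")
    n = irr.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = irr - fellow
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        if mean_d == 0.0:
            raise ValueError("all paired differences are zero: t undefined")
        return StatResult("paired_t", float(np.sign(mean_d) * np.inf), 0.0, n,
                          int(np.sign(mean_d)))
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return StatResult("paired_t", float(t), float(p), n, int(np.sign(mean_d)))


def paired_differences(
    irr, fellow, fellow_minus_irradiated: bool = False
) -> tuple[np.ndarray, int]:
    """Per-patient deltas (irradiated - fellow) and the count below zero."""
    irr = np.asarray(irr, dtype=float)
    fellow = np.asarray(fellow, dtype=float)
    if irr.shape != fellow.shape:
        raise ValueError("misaligned irradiated/fellow vectors")
    deltas = fellow - irr if fellow_minus_irradiated else irr - fellow
    return deltas, int((deltas < 0).sum())


def linreg_vs_time(time_months, y) -> StatResult:
    """OLS fit of a flow measure on time from treatment (months).

    Returns the slope (per month) with its two-tailed p for H0: slope = 0
    on n - 2 degrees of freedom.  A constant response gives slope 0 and
    p = 1; an exactly collinear response is reported as the zero-residual
    degenerate limit p = 0.
    """
    x = np.asarray(time_months, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("time and measure must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("time from treatment is constant: slope undefined")
    if np.ptp(y) == 0:
        return StatResult("linreg", 0.0, 1.0, n, 0, intercept=float(y[0]))
    fit = sps.linregress(x, y)
    slope, p = float(fit.slope), float(fit.pvalue)
    resid = y - (fit.intercept + fit.slope * x)
    if np.sum(resid**2) <= 1e-12 * np.sum((y - y.mean()) ** 2):
        p = 0.0
    return StatResult("linreg", slope, p, n, int(np.sign(slope)),
                      intercept=float(fit.intercept))


@dataclass
class SpearmanMatrix:
    """Symmetric rank-correlation matrix with per-pair p-values and n."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.01

    def significant(self) -> pd.DataFrame:
        """Boolean mask of off-diagonal correlations with p < alpha."""
        sig = self.p < self.alpha
        np.fill_diagonal(sig.values, False)
        return sig

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format table (one row per unordered variable pair)."""
        cols = list(self.rho.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append({
                    "var_a": a, "var_b": b,
                    "rho": self.rho.loc[a, b], "p_value": self.p.loc[a, b],
                    "n": self.n.loc[a, b],
                    "significant": bool(self.p.loc[a, b] < self.alpha),
                })
        return pd.DataFrame(rows)


def spearman_matrix(
    table: pd.DataFrame,
    alpha: float = 0.01,
    min_n: int = 4,
    bonferroni: bool = False,
    degenerate: str = "raise",
) -> SpearmanMatrix:
    """Spearman rank correlations (two-tailed) between all column pairs.

    Ties receive mid-ranks; p-values use the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom,
    adequate at cohort sizes of a few dozen.  Missing values are dropped
    pairwise, so sparsely recorded covariates (dose, distance) reduce n
    only for their own pairs.  A constant column makes its pairs
    undefined: with ``degenerate="raise"`` (default) that is an error,
    with ``degenerate="nan"`` the affected pairs carry rho = p = NaN and
    are never flagged significant.
    """
    if degenerate not in ("raise", "nan"):
        raise ValueError(f"degenerate must be 'raise' or 'nan', got {degenerate!r}")
    cols = list(table.columns)
    m = len(cols)
    rho = pd.DataFrame(np.eye(m), index=cols, columns=cols, dtype=float)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols, dtype=float)
    n_df = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for a in cols:
        n_df.loc[a, a] = int(table[a].notna().sum())
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = table[[a, b]].dropna()
            n = len(pair)
            if n < min_n:
                raise ValueError(
                    f"pair ({a}, {b}): only {n} complete observations (min {min_n})"
                )
            constant = [col for col in (a, b) if pair[col].nunique() < 2]
            if constant:
                if degenerate == "raise":
                    raise ValueError(
                        f"variable {constant[0]} is constant: rho undefined"
                    )
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                n_df.loc[a, b] = n_df.loc[b, a] = n
                continue
            r, pv = sps.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = float(r)
            p.loc[a, b] = p.loc[b, a] = float(pv)
            n_df.loc[a, b] = n_df.loc[b, a] = n
    if bonferroni:
        n_tests = m * (m - 1) // 2
        off = ~np.eye(m, dtype=bool)
        p.values[off] = np.minimum(1.0, p.values[off] * n_tests)
    return SpearmanMatrix(rho=rho, p=p, n=n_df, alpha=alpha)
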