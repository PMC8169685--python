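"""Hypothesis tests for multivariate VMR comparisons.

The two workhorses are the classical two-sample Hotelling T-squared test
(used when the pooled sample size comfortably exceeds the window dimension)
and a high-dimensional two-sample mean test for the p > n regime, built
from a max-type statistic over per-coordinate standardized mean differences
and calibrated by a Gaussian multiplier bootstrap.  Univariate helpers
(Welch's t, Pearson chi-square on 2x2 tables, one-way ANOVA with
FDR-corrected pairwise t-tests) cover the supporting comparisons.

Hotelling's T-squared is converted to an F statistic via

    F = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * T^2 ~ F_{p, n1+n2-p-1}

under the null that the two mean vectors are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateTableError,
    DimensionError,
    DomainError,
    InsufficientSampleError,
    SingularCovarianceError,
    UndefinedStatisticError,
)
from .plate_io import WindowMatrix

__all__ = [
    "TestResult",
    "hotelling_t2",
    "hd_two_sample_test",
    "welch_t",
    "pearson_chi2_2x2",
    "anova_pairwise_fdr",
]


@dataclass
class TestResult:
    """Statistic, degrees of freedom and p-value of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df1: float | None = None
    df2: float | None = None
    n1: int | None = None
    n2: int | None = None
    dim: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise UndefinedStatisticError(
                f"{self.method}: statistic is not finite ({self.statistic})"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise UndefinedStatisticError(
                f"{self.method}: p-value {self.p_value} outside [0, 1]"
            )

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df1": self.df1,
            "df2": self.df2,
            "n1": self.n1,
            "n2": self.n2,
            "dim": self.dim,
        }
        out.update(self.info)
        return out


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, WindowMatrix):
        return x.values
    arr = np.asarray(x, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise DimensionError("samples must be 1- or 2-dimensional arrays")
    if not np.isfinite(arr).all():
        raise DomainError("samples contain non-finite values")
    return arr


def hotelling_t2(a, b, *, ridge: float = 0.0) -> TestResult:
    """Two-sample Hotelling T-squared test on equal-dimension samples.

    ``T^2`` is the pooled-covariance Mahalanobis distance between the two
    mean vectors scaled by ``n1*n2/(n1+n2)``.  A singular pooled covariance
    raises :class:`SingularCovarianceError` unless ``ridge > 0``, in which
    case ``ridge * I`` is added and reported in the result.  When the
    dimension exceeds ``n1 + n2 - 2`` the statistic does not exist; use
    :func:`hd_two_sample_test` instead.
    """
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape[1] != B.shape[1]:
        raise DimensionError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    n1, n2, p = A.shape[0], B.shape[0], A.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientSampleError("need at least 2 observations per group")
    if p > n1 + n2 - 2:
        raise DimensionError(
            f"dimension p={p} exceeds n1+n2-2={n1 + n2 - 2}; the pooled "
            "covariance cannot be inverted - use hd_two_sample_test for the "
            "p > n regime"
        )
    if ridge < 0:
        raise DomainError("ridge must be >= 0")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((n1 - 1) * np.cov(A, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(B, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    if ridge > 0:
        S = S + ridge * np.eye(p)
    from scipy.linalg import LinAlgError, cho_factor, cho_solve

    try:
        factor = cho_factor(S, lower=True)
        sol = cho_solve(factor, d)
    except (LinAlgError, ValueError) as exc:
        raise SingularCovarianceError(
            "pooled covariance is singular; supply ridge > 0 to regularize"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    if t2 < 0:
        raise SingularCovarianceError(
            "pooled covariance is numerically indefinite; supply ridge > 0"
        )
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    p_value = float(stats.f.sf(f_stat, df1, df2))
    info = {"F": f_stat}
    if ridge > 0:
        info["ridge"] = ridge
    return TestResult(
        method="hotelling_t2",
        statistic=t2,
        p_value=p_value,
        df1=df1,
        df2=df2,
        n1=n1,
        n2=n2,
        dim=p,
        info=info,
    )


def _studentized_max(
    A: np.ndarray, B: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Max over coordinates of |standardized mean difference|.

    ``A``/``B`` may carry a leading batch axis; observations are on the
    second-to-last axis.  Coordinates with zero variance contribute 0 when
    the mean difference is also zero and +inf otherwise.
    """
    diff = A.mean(axis=-2) - B.mean(axis=-2)
    var = A.var(axis=-2, ddof=1) / n1 + B.var(axis=-2, ddof=1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / np.sqrt(var)
    t = np.where(var > 0, t, np.where(np.abs(diff) > 0, np.inf, 0.0))
    return t.max(axis=-1)


def hd_two_sample_test(
    a, b, n_boot: int = 1000, *, seed: int, method: str = "permutation"
) -> TestResult:
    """High-dimensional nonparametric two-sample mean test (valid for p > n).

    The statistic is the maximum over coordinates of the absolute
    standardized mean difference

        T_HD = max_j |xbar_1j - xbar_2j| / sqrt(s_1j^2/n1 + s_2j^2/n2)

    Its null distribution is approximated by ``n_boot`` resamples.  The
    default calibration permutes group labels and recomputes the fully
    studentized statistic, which is exactly uniform under exchangeability
    of the two samples - the relevant null both for mean comparison and
    for the replicate-similarity criterion.  ``method="multiplier"``
    instead uses the Gaussian multiplier bootstrap of the group-centered
    data with fixed denominators; it targets the same limit but is
    noticeably anticonservative at n ~ 24.  The p-value is
    ``(1 + #{T* >= T_HD}) / (n_boot + 1)`` and is reproducible bit-for-bit
    given the data, ``n_boot``, ``method`` and ``seed``.
    """
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape[1] != B.shape[1]:
        raise DimensionError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    n1, n2, p = A.shape[0], B.shape[0], A.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientSampleError("need at least 2 observations per group")
    if n_boot < 200:
        raise DomainError(f"n_boot must be >= 200, got {n_boot}")
    if method not in ("permutation", "multiplier"):
        raise DomainError("method must be 'permutation' or 'multiplier'")
    rng = np.random.default_rng(seed)

    t_obs = float(_studentized_max(A, B, n1, n2))

    if method == "permutation":
        Z = np.vstack([A, B])
        idx = np.argsort(rng.random((n_boot, n1 + n2)), axis=1)
        ZP = Z[idx]  # n_boot x (n1+n2) x p
        t_null = _studentized_max(ZP[:, :n1, :], ZP[:, n1:, :], n1, n2)
    else:
        denom = np.sqrt(A.var(axis=0, ddof=1) / n1 + B.var(axis=0, ddof=1) / n2)
        C1 = A - A.mean(axis=0)
        C2 = B - B.mean(axis=0)
        E1 = rng.standard_normal((n_boot, n1))
        E2 = rng.standard_normal((n_boot, n2))
        boot_diff = (E1 @ C1) / n1 - (E2 @ C2) / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(boot_diff) / denom
        t = np.where(denom > 0, t, np.where(np.abs(boot_diff) > 0, np.inf, 0.0))
        t_null = t.max(axis=1)

    p_value = float((1 + np.count_nonzero(t_null >= t_obs)) / (n_boot + 1))
    return TestResult(
        method="hd_two_sample",
        statistic=t_obs,
        p_value=p_value,
        n1=n1,
        n2=n2,
        dim=p,
        info={"n_boot": n_boot, "seed": seed, "resampling": method},
    )


def welch_t(a, b) -> TestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(a, float).ravel()
    y = np.asarray(b, float).ravel()
    if x.size < 2 or y.size < 2:
        raise InsufficientSampleError("need at least 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise UndefinedStatisticError(
            "both groups have zero variance; the Welch statistic is undefined"
        )
    if np.array_equal(x, y):
        return TestResult(
            method="welch_t", statistic=0.0, p_value=1.0,
            df1=float(2 * (x.size - 1)), n1=x.size, n2=y.size,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    se2_1, se2_2 = v1 / x.size, v2 / y.size
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (x.size - 1) + se2_2**2 / (y.size - 1)
    )
    return TestResult(
        method="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df1=float(df),
        n1=x.size,
        n2=y.size,
    )


def pearson_chi2_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    No continuity correction is applied.  All margins must be positive and
    counts must be non-negative integers.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise DegenerateTableError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.mod(t, 1) == 0):
        raise DegenerateTableError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("table has a zero margin")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(
        method="pearson_chi2",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df1=float(res.dof),
        info={"n": int(t.sum())},
    )


def anova_pairwise_fdr(
    groups: Mapping[str, Sequence[float]],
) -> dict:
    """One-way ANOVA plus all pairwise t-tests with Benjamini-Hochberg FDR.

    Pairwise comparisons use the classical pooled-variance two-sample t;
    adjusted p-values follow the BH step-up procedure over all pairs.
    Returns ``{"anova": TestResult, "pairwise": [TestResult, ...]}`` where
    each pairwise result's ``p_value`` is BH-adjusted (raw value in
    ``info["p_raw"]``).
    """
    if len(groups) < 2:
        raise InsufficientSampleError("need at least 2 groups")
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, float).ravel()
        if arr.size < 2:
            raise InsufficientSampleError(
                f"group {name!r} has fewer than 2 observations"
            )
        arrays[str(name)] = arr
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise UndefinedStatisticError(
            "all observations are identical; the ANOVA F is undefined"
        )
    f_res = stats.f_oneway(*arrays.values())
    k = len(arrays)
    n_total = pooled.size
    anova = TestResult(
        method="oneway_anova",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        df1=float(k - 1),
        df2=float(n_total - k),
        info={"n_groups": k, "n_total": int(n_total)},
    )
    pairs = list(combinations(sorted(arrays), 2))
    raw = []
    stats_list = []
    for g1, g2 in pairs:
        res = stats.ttest_ind(arrays[g1], arrays[g2], equal_var=True)
        raw.append(float(res.pvalue))
        stats_list.append(float(res.statistic))
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = [
        TestResult(
            method="pairwise_t_fdr",
            statistic=stat,
            p_value=float(adj),
            df1=float(arrays[g1].size + arrays[g2].size - 2),
            n1=arrays[g1].size,
            n2=arrays[g2].size,
            info={"pair": (g1, g2), "p_raw": praw},
        )
        for (g1, g2), stat, praw, adj in zip(pairs, stats_list, raw, adjusted)
    ]
    return {"anova": anova, "pairwise": pairwise}
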