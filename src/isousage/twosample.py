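"""Two-group tests of equal mean isoform usage on ilr coordinates.

Per-sample usage estimates theta_hat_ij are modelled hierarchically:
ilr(theta_hat_ij) ~ N(ilr(theta_i), Sigma_i + Upsilon_i) on R^(K-1),
with a group-specific marginal covariance — the multivariate
Behrens-Fisher setting.  Three published tests are provided:

* KY   — Hotelling-type statistic with Krishnamoorthy-Yu approximate
         degrees of freedom (modified Nel-van der Merwe); requires the
         covariance estimate of the mean difference to be invertible,
         hence dimension < sample sizes.  At K = 2 it reduces exactly
         to Welch's t-test.
* CQ   — Chen-Qin cross-product statistic with leave-one/two-out trace
         variance estimators; no covariance inversion, valid when the
         dimension exceeds the sample sizes.
* SKK  — Srivastava-Katayama-Koizumi diagonally-standardised statistic
         with a trace-of-correlation variance estimator and
         small-sample correction; also inversion-free.  Unlike KY/CQ,
         its value depends on the ilr basis chosen.

A label-permutation calibration is available for SKK and CQ, whose
normal-reference p-values are anti-conservative at small group sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import compositional as comp

__all__ = [
    "GroupSamples",
    "TestResult",
    "group_mean_usage",
    "ky_test",
    "cq_test",
    "skk_test",
    "welch_test",
    "permutation_pvalue",
    "adjust_pvalues",
    "DifferentialUsage",
    "DifferentialUsageResults",
]


@dataclass
class GroupSamples:
    """ilr-transformed per-sample usage for the two groups (rows = samples)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("groups must share the ilr dimension")
        if self.X.shape[0] < 2 or self.Y.shape[0] < 2:
            raise ValueError("each group needs at least two samples")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("non-finite ilr coordinates")

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@dataclass
class TestResult:
    """Outcome of one two-group test for one gene."""

    method: str
    statistic: float
    p_value: float
    gene_id: str | None = None
    p_adjusted: float | None = None
    df: dict = field(default_factory=dict)
    group_means: tuple[np.ndarray, np.ndarray] | None = None
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def group_mean_usage(samples, basis=None) -> np.ndarray:
    """Group mean usage composition: the Aitchison (geometric) mean.

    Computed as ilr_inverse of the arithmetic mean of ilr coordinates;
    samples must be strictly positive (apply zero replacement first).
    """
    return comp.compositional_mean(samples, basis)


def _mean_cov(M: np.ndarray):
    n = M.shape[0]
    return M.mean(axis=0), np.cov(M, rowvar=False, ddof=1).reshape(M.shape[1], -1), n


def ky_test(g: GroupSamples, gene_id: str | None = None) -> TestResult:
    """Krishnamoorthy-Yu approximate-df Hotelling-type test.

    T^2 = d' S~^{-1} d with S~ = S1/n1 + S2/n2;  T^2 (nu-p+1)/(nu p)
    is referred to F(p, nu-p+1) with nu from the modified
    Nel-van der Merwe trace formula.  Singular S~ (dimension >= sample
    size) yields a flagged inapplicable result.
    """
    xbar, S1, n1 = _mean_cov(g.X)
    ybar, S2, n2 = _mean_cov(g.Y)
    p = g.dim
    St1, St2 = S1 / n1, S2 / n2
    St = St1 + St2
    d = xbar - ybar
    try:
        Sinv = np.linalg.inv(St)
    except np.linalg.LinAlgError:
        return TestResult("KY", np.nan, np.nan, gene_id, flags=["ky_inapplicable"])
    cond = np.linalg.cond(St)
    if not np.isfinite(cond) or cond > 1e12:
        return TestResult("KY", np.nan, np.nan, gene_id, flags=["ky_inapplicable"])
    T2 = float(d @ Sinv @ d)
    A1, A2 = St1 @ Sinv, St2 @ Sinv
    denom = (
        (np.trace(A1 @ A1) + np.trace(A1) ** 2) / (n1 - 1)
        + (np.trace(A2 @ A2) + np.trace(A2) ** 2) / (n2 - 1)
    )
    nu = (p + p**2) / denom if denom > 0 else np.inf
    if T2 == 0.0:
        return TestResult("KY", 0.0, 1.0, gene_id, df={"nu": nu, "p": p})
    F = T2 * (nu - p + 1) / (nu * p)
    pval = float(stats.f.sf(F, p, nu - p + 1))
    return TestResult("KY", T2, pval, gene_id, df={"nu": float(nu), "p": p})


def welch_test(g: GroupSamples, gene_id: str | None = None) -> TestResult:
    """Welch's two-sample t-test (1-dimensional ilr coordinates, i.e. K = 2)."""
    if g.dim != 1:
        raise ValueError("Welch's t-test applies to 1-dimensional coordinates")
    t, pval = stats.ttest_ind(g.X[:, 0], g.Y[:, 0], equal_var=False)
    return TestResult("Welch", float(t), float(pval), gene_id)


def cq_test(g: GroupSamples, gene_id: str | None = None) -> TestResult:
    """Chen-Qin two-sample mean test (no covariance inversion).

    The statistic sums between-observation cross-products within and
    across groups; its null variance is estimated with the
    leave-one/two-out trace estimators of tr(Sigma_i^2) and
    tr(Sigma_1 Sigma_2).  Upper-tail normal p-value.
    """
    X, Y = g.X, g.Y
    n1, n2 = X.shape[0], Y.shape[0]
    GX, GY, GXY = X @ X.T, Y @ Y.T, X @ Y.T
    T = (
        (GX.sum() - np.trace(GX)) / (n1 * (n1 - 1))
        + (GY.sum() - np.trace(GY)) / (n2 * (n2 - 1))
        - 2.0 * GXY.sum() / (n1 * n2)
    )
    tr1 = _cq_tr_sigma2(X)
    tr2 = _cq_tr_sigma2(Y)
    tr12 = _cq_tr_cross(X, Y)
    var = (
        2.0 / (n1 * (n1 - 1)) * tr1
        + 2.0 / (n2 * (n2 - 1)) * tr2
        + 4.0 / (n1 * n2) * tr12
    )
    if var <= 0:
        return TestResult(
            "CQ", 0.0, 1.0, gene_id, flags=["degenerate_variance"], extra={"T": float(T)}
        )
    Q = float(T / math.sqrt(var))
    return TestResult(
        "CQ", Q, float(stats.norm.sf(Q)), gene_id, extra={"T": float(T), "var": float(var)}
    )


def _cq_tr_sigma2(X: np.ndarray) -> float:
    """Leave-two-out estimator of tr(Sigma^2) (Chen-Qin).

    The estimator centres each cross-term on the mean of the remaining
    n-2 observations, so it needs n >= 3; at n = 2 the plug-in
    trace of the squared sample covariance is used instead.
    """
    n = X.shape[0]
    if n < 3:
        S = np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], -1)
        return float(np.sum(S * S))
    total = X.sum(axis=0)
    acc = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            mean_jk = (total - X[j] - X[k]) / (n - 2)
            acc += (X[k] @ (X[j] - mean_jk)) * (X[j] @ (X[k] - mean_jk))
    return acc / (n * (n - 1))


def _cq_tr_cross(X: np.ndarray, Y: np.ndarray) -> float:
    """Leave-one-out estimator of tr(Sigma_1 Sigma_2) (Chen-Qin)."""
    n1, n2 = X.shape[0], Y.shape[0]
    totX, totY = X.sum(axis=0), Y.sum(axis=0)
    acc = 0.0
    for j in range(n1):
        mean_j = (totX - X[j]) / (n1 - 1)
        for k in range(n2):
            mean_k = (totY - Y[k]) / (n2 - 1)
            acc += (Y[k] @ (X[j] - mean_j)) * (X[j] @ (Y[k] - mean_k))
    return acc / (n1 * n2)


def skk_test(g: GroupSamples, gene_id: str | None = None) -> TestResult:
    """Srivastava-Katayama-Koizumi diagonally-standardised mean test.

    q = d' D^{-1} d with D = diag(S1/n1 + S2/n2); standardised as
    (q - p) / sqrt(2 tr(R^2) c_{p,n}) with R the correlation-form
    matrix D^{-1/2} S~ D^{-1/2} and small-sample correction
    c_{p,n} = 1 + tr(R^2) p^{-3/2}.  Upper-tail normal p-value.  The
    value of q — hence the test — depends on the ilr basis, unlike
    KY/CQ.
    """
    xbar, S1, n1 = _mean_cov(g.X)
    ybar, S2, n2 = _mean_cov(g.Y)
    St = S1 / n1 + S2 / n2
    diag = np.diag(St).copy()
    keep = diag > 0
    flags = []
    if not keep.all():
        if not keep.any():
            return TestResult(
                "SKK", np.nan, np.nan, gene_id, flags=["all_zero_variance"]
            )
        flags.append("zero_variance_dims_dropped")
    d = (xbar - ybar)[keep]
    St = St[np.ix_(keep, keep)]
    diag = diag[keep]
    p = d.size
    q = float(d @ (d / diag))
    Dinvsqrt = 1.0 / np.sqrt(diag)
    R = St * Dinvsqrt[:, None] * Dinvsqrt[None, :]
    trR2 = float(np.sum(R * R))
    cpn = 1.0 + trR2 / p**1.5
    stat = (q - p) / math.sqrt(2.0 * trR2 * cpn)
    return TestResult(
        "SKK",
        float(stat),
        float(stats.norm.sf(stat)),
        gene_id,
        flags=flags,
        extra={"q": q, "tr_R2": trR2, "c_pn": cpn},
    )


_STAT_FNS = {"SKK": skk_test, "CQ": cq_test, "KY": ky_test}


def permutation_pvalue(
    method: str,
    g: GroupSamples,
    B: int = 10000,
    seed: int | None = None,
    gene_id: str | None = None,
) -> TestResult:
    """Group-label permutation p-value for SKK or CQ (or KY).

    When the number of distinct label splits is at most B, all splits
    are enumerated and p = #{splits with statistic >= observed}/n_splits
    (the observed split counts itself, so p >= 1/n_splits).  Otherwise
    B random splits are drawn and p = (1 + #{>= observed}) / (1 + B).
    Ties count as >=.
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    stat_fn = _STAT_FNS[method.upper()]
    obs = stat_fn(g)
    pooled = np.vstack([g.X, g.Y])
    n1 = g.X.shape[0]
    n = pooled.shape[0]
    n_splits = math.comb(n, n1)

    def stat_for(idx: tuple[int, ...]) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        return stat_fn(GroupSamples(pooled[mask], pooled[~mask])).statistic

    if n_splits <= B:
        stats_perm = [
            stat_for(idx) for idx in itertools.combinations(range(n), n1)
        ]
        count = sum(s >= obs.statistic - 1e-12 for s in stats_perm)
        pval = count / n_splits
        mode = {"mode": "exhaustive", "n_splits": n_splits}
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(B):
            idx = tuple(rng.choice(n, size=n1, replace=False))
            if stat_for(idx) >= obs.statistic - 1e-12:
                count += 1
        pval = (1 + count) / (1 + B)
        mode = {"mode": "sampled", "B": B}
    return TestResult(
        f"{method.upper()}-perm",
        obs.statistic,
        float(pval),
        gene_id,
        flags=obs.flags + ["permutation"],
        extra={**obs.extra, **mode},
    )


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' (FWER) or 'BH' (FDR).

    NaN entries (untestable genes) are passed through unadjusted and do
    not count toward the family size.
    """
    pvals = np.asarray(pvals, dtype=float)
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}[
        method.lower()
    ]
    out = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        out[ok] = multipletests(pvals[ok], method=key)[1]
    return out


@dataclass
class DifferentialUsageResults:
    """Two-group differential-usage outcome for one gene."""

    model: "DifferentialUsage"
    result: TestResult
    group_means: tuple[np.ndarray, np.ndarray] | None
    kept_isoforms: list
    dropped_isoforms: list
    testable: bool
    reason: str | None = None

    @property
    def statistic(self) -> float:
        return self.result.statistic

    @property
    def p_value(self) -> float:
        return self.result.p_value

    @property
    def method(self) -> str:
        return self.result.method

    def summary(self) -> str:
        gid = self.result.gene_id or "?"
        if not self.testable:
            return f"Differential usage — gene {gid}: untestable ({self.reason})"
        lines = [
            f"Differential usage — gene {gid}",
            f"  method: {self.method}   statistic: {self.statistic:.4f}"
            f"   p-value: {self.p_value:.4g}",
            f"  isoforms tested: {len(self.kept_isoforms)}"
            + (f"   dropped (all-zero): {self.dropped_isoforms}" if self.dropped_isoforms else ""),
        ]
        m0, m1 = self.group_means
        lines.append(f"  {'isoform':<20}{'group0':>10}{'group1':>10}")
        for iid, a, b in zip(self.kept_isoforms, m0, m1):
            lines.append(f"  {str(iid):<20}{a:>10.4f}{b:>10.4f}")
        if self.result.flags:
            lines.append(f"  flags: {', '.join(self.result.flags)}")
        return "\n".join(lines)


class DifferentialUsage:
    """Two-group comparison of usage compositions for one gene.

    Applies the testing pipeline: drop isoforms that are zero in every
    sample of both groups, replace remaining zeros by ``eps``, map to
    ilr coordinates under a fixed orthonormal basis, then run the
    selected multivariate Behrens-Fisher test.

    Parameters
    ----------
    group0, group1 : (J_i, K) arrays of per-sample usage compositions
    isoform_ids : optional labels (defaults to 0..K-1)
    eps : zero-replacement value (default 1e-4)
    basis : optional (K-1, K) orthonormal contrast matrix
    """

    def __init__(self, group0, group1, isoform_ids=None, eps: float = 1e-4, basis=None):
        self.raw0 = np.atleast_2d(np.asarray(group0, dtype=float))
        self.raw1 = np.atleast_2d(np.asarray(group1, dtype=float))
        if self.raw0.shape[0] < 2 or self.raw1.shape[0] < 2:
            raise ValueError("at least two samples per group are required")
        K = self.raw0.shape[1]
        self.isoform_ids = list(isoform_ids) if isoform_ids is not None else list(range(K))
        self.eps = eps
        self.basis = basis
        self.gene_id: str | None = None

    @classmethod
    def from_estimates(cls, estimates0, estimates1, eps: float = 1e-4, basis=None):
        """Build from per-sample :class:`IsoformUsageResults` lists."""
        g0 = np.array([r.theta for r in estimates0])
        g1 = np.array([r.theta for r in estimates1])
        obj = cls(g0, g1, isoform_ids=estimates0[0].isoform_ids, eps=eps, basis=basis)
        obj.gene_id = estimates0[0].gene_id
        return obj

    def fit(
        self,
        method: str = "SKK",
        permutation_B: int | None = None,
        seed: int | None = None,
    ) -> DifferentialUsageResults:
        g0, g1, kept, dropped = comp.drop_all_zero_isoforms(self.raw0, self.raw1)
        kept_ids = [self.isoform_ids[i] for i in kept]
        dropped_ids = [self.isoform_ids[i] for i in dropped]
        if kept.size < 2:
            res = TestResult(method.upper(), np.nan, np.nan, self.gene_id,
                             flags=["untestable"])
            return DifferentialUsageResults(
                self, res, None, kept_ids, dropped_ids,
                testable=False, reason="fewer than two expressed isoforms",
            )
        g0 = comp.replace_zeros(g0, self.eps)
        g1 = comp.replace_zeros(g1, self.eps)
        K = kept.size
        basis = self.basis if self.basis is not None else comp.helmert_basis(K)
        if basis.shape != (K - 1, K):
            basis = comp.helmert_basis(K)
        g = GroupSamples(comp.ilr(g0, basis), comp.ilr(g1, basis))
        method_u = method.upper()
        if method_u == "WELCH":
            res = welch_test(g, self.gene_id)
        elif permutation_B:
            res = permutation_pvalue(method_u, g, permutation_B, seed, self.gene_id)
        else:
            res = _STAT_FNS[method_u](g, self.gene_id)
        means = (group_mean_usage(g0, basis), group_mean_usage(g1, basis))
        if dropped_ids:
            res.flags.append("isoforms_dropped")
        res.group_means = means
        return DifferentialUsageResults(
            self, res, means, kept_ids, dropped_ids, testable=True
        )
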