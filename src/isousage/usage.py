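"""Maximum-likelihood isoform-usage estimation (EM step).

For one gene in one sample, the N' usable read pairs define the mixture
log-likelihood

    l(p) = sum_n log sum_k p_k a_{nk},

over mixture weights p on the simplex, where a_{nk} are the per-read
terms from :mod:`isousage.alignments`.  EM with the source isoform as
the latent variable maximises l(p); the usage composition theta is then
recovered through the effective lengths Z_k:

    theta_k  ∝  p_k / Z_k,        Z_k = sum_l f(l) (l_k - l + 1)_+

— the inversion of the sampling bias by which longer isoforms attract
proportionally more fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import (
    CompatibilityMatrix,
    FragmentLengthDistribution,
    ReadFilters,
    build_compatibility,
    effective_length,
    likelihood_matrix,
    load_read_pairs,
    log_likelihood,
)
from .annotation import GeneModel

__all__ = [
    "em_fit",
    "p_to_theta",
    "IsoformUsageModel",
    "IsoformUsageResults",
    "estimate_gene_sample_usage",
]


def em_fit(
    A: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-6,
    maxiter: int = 1000,
):
    """EM for mixture weights p given the N' x K term matrix A.

    E-step: responsibilities w_{nk} = p_k a_{nk} / sum_j p_j a_{nj};
    M-step: p_k <- mean_n w_{nk}.  Convergence when max|Δp| < tol.
    The log-likelihood is non-decreasing across iterations.

    Returns ``(p_hat, loglik, n_iter, converged)``.
    """
    N, K = A.shape
    if N == 0:
        raise ValueError("empty compatibility matrix")
    if K == 1:
        return np.array([1.0]), log_likelihood([1.0], A), 0, True
    p = np.full(K, 1.0 / K) if start is None else np.asarray(start, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("start point must lie on the simplex")
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        mix = A @ p
        if np.any(mix <= 0):
            raise ValueError(
                "a read pair has zero likelihood under every isoform; "
                "check compatibility filtering"
            )
        W = A * p[None, :] / mix[:, None]
        p_new = W.mean(axis=0)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return p, log_likelihood(p, A), it, converged


def p_to_theta(p_hat: np.ndarray, effective_lengths) -> np.ndarray:
    """Convert mixture weights to usage: theta_k = (p_k/Z_k) / sum_j (p_j/Z_j)."""
    p = np.asarray(p_hat, dtype=float)
    Z = np.asarray(effective_lengths, dtype=float)
    if np.any((p > 1e-12) & (Z <= 0)):
        raise ValueError("isoform with positive weight but zero effective length")
    raw = np.divide(p, Z, out=np.zeros_like(p), where=Z > 0)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all effective lengths are zero; gene excluded")
    return raw / total


@dataclass
class IsoformUsageResults:
    """MLE of one gene's isoform usage in one sample."""

    model: "IsoformUsageModel"
    theta: np.ndarray
    p_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_reads: int
    flags: list[str] = field(default_factory=list)

    @property
    def gene_id(self) -> str:
        return self.model.gene_id

    @property
    def isoform_ids(self) -> list[str]:
        return self.model.isoform_ids

    def summary(self) -> str:
        lines = [
            f"Isoform usage MLE — gene {self.gene_id}",
            f"  reads used: {self.n_reads}   log-lik: {self.loglik:.4f}",
            f"  EM iterations: {self.n_iter}   converged: {self.converged}",
        ]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        lines.append(f"  {'isoform':<20}{'theta':>10}{'p':>10}")
        for iid, th, p in zip(self.isoform_ids, self.theta, self.p_hat):
            lines.append(f"  {iid:<20}{th:>10.4f}{p:>10.4f}")
        return "\n".join(lines)


class IsoformUsageModel:
    """Fragment-length-aware mixture model for one gene in one sample.

    Parameters
    ----------
    compat : CompatibilityMatrix
        Implied fragment lengths l_k^n for the gene's usable read pairs.
    fld : FragmentLengthDistribution
        The sample-wide fragment length distribution f(.).
    isoform_lengths : sequence of int
        Transcript lengths l_k, in the compatibility matrix's isoform
        order.
    """

    def __init__(self, compat: CompatibilityMatrix, fld, isoform_lengths):
        self.compat = compat
        self.fld = fld
        self.isoform_lengths = np.asarray(isoform_lengths, dtype=np.int64)
        if self.isoform_lengths.size != compat.K:
            raise ValueError("isoform_lengths must match the matrix's K")
        self.effective_lengths = np.array(
            [effective_length(int(l), fld) for l in self.isoform_lengths]
        )
        A = likelihood_matrix(compat, fld, self.isoform_lengths)
        # a pair can be structurally compatible yet carry zero density when
        # its implied lengths fall outside f's (truncated) support for every
        # isoform; such pairs are uninformative and are dropped like
        # unassignable ones
        usable = A.sum(axis=1) > 0
        self.n_zero_density = int((~usable).sum())
        self.A = A[usable]

    @classmethod
    def from_alignments(
        cls,
        bam,
        gene: GeneModel,
        fld: FragmentLengthDistribution,
        filters: ReadFilters | None = None,
    ) -> "IsoformUsageModel":
        pairs, _ = load_read_pairs(bam, gene, filters)
        compat = build_compatibility(pairs, gene)
        return cls(compat, fld, [iso.length for iso in gene.isoforms])

    @classmethod
    def from_pairs(cls, pairs, gene: GeneModel, fld) -> "IsoformUsageModel":
        compat = build_compatibility(pairs, gene)
        return cls(compat, fld, [iso.length for iso in gene.isoforms])

    @property
    def gene_id(self) -> str:
        return self.compat.gene_id

    @property
    def isoform_ids(self) -> list[str]:
        return self.compat.isoform_ids

    def loglike(self, p) -> float:
        return log_likelihood(p, self.A)

    def fit(
        self,
        start: np.ndarray | None = None,
        tol: float = 1e-6,
        maxiter: int = 1000,
        n_random_starts: int = 1,
        seed: int = 0,
        min_reads: int = 10,
    ) -> IsoformUsageResults:
        """Run EM (uniform start, plus optional random restarts).

        Restarts guard against ridges created by (near-)identical
        isoforms; the best-likelihood solution is kept.  Genes with
        fewer than ``min_reads`` usable pairs are fitted anyway but
        flagged ``insufficient_reads``.
        """
        flags: list[str] = []
        N, K = self.A.shape
        if N == 0:
            raise ValueError(f"gene {self.gene_id}: no usable reads")
        if N < min_reads:
            flags.append("insufficient_reads")
        if self.n_zero_density:
            flags.append("zero_density_pairs_dropped")
        p, ll, it, conv = em_fit(self.A, start, tol, maxiter)
        if K >= 2 and n_random_starts > 0 and start is None:
            rng = np.random.default_rng(seed)
            for _ in range(n_random_starts):
                p0 = rng.dirichlet(np.ones(K))
                cand = em_fit(self.A, p0, tol, maxiter)
                if cand[1] > ll + 1e-9:
                    p, ll, it, conv = cand
        if not conv:
            flags.append("em_not_converged")
        if K >= 2 and self._near_identical_columns():
            flags.append("non_identifiable")
        theta = p_to_theta(p, self.effective_lengths)
        return IsoformUsageResults(
            model=self,
            theta=theta,
            p_hat=p,
            loglik=ll,
            n_iter=it,
            converged=conv,
            n_reads=N,
            flags=flags,
        )

    def _near_identical_columns(self, rtol: float = 1e-10) -> bool:
        # singular information surface: two isoforms indistinguishable read-wise
        A = self.A
        for i in range(A.shape[1]):
            for j in range(i + 1, A.shape[1]):
                if np.allclose(A[:, i], A[:, j], rtol=rtol, atol=1e-300):
                    return True
        return False


def estimate_gene_sample_usage(
    bam,
    gene: GeneModel,
    fld: FragmentLengthDistribution,
    filters: ReadFilters | None = None,
    **fit_kwargs,
) -> IsoformUsageResults:
    """Load pairs, build compatibility, fit EM, convert p to theta.

    Single-isoform genes short-circuit to theta = (1,).
    """
    model = IsoformUsageModel.from_alignments(bam, gene, fld, filters)
    return model.fit(**fit_kwargs)
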