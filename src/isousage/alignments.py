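"""Paired-end alignment ingestion and per-isoform compatibility.

The estimation step treats each aligned read pair n as an observation of
an unknown source isoform.  For isoform k with transcript length l_k,
``l_k^n`` is the length of the unique fragment of isoform k whose two
ends coincide with the pair's outer ends — or 0 when no such fragment
exists (the pair straddles a junction the isoform lacks, or touches an
intron of the isoform).  The N x K matrix of these implied fragment
lengths, together with the sample-wide fragment length distribution
f(.), determines every per-read likelihood term:

    a_{nk} = f(l_k^n) / (l_k - l_k^n + 1)   if 0 < l_k^n <= l_k else 0

i.e. the fragment length carries probability f(.) and the fragment's
placement is uniform over the l_k - l_k^n + 1 start positions that
produce the same implied length.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats

from .annotation import GeneModel, IsoformModel

logger = logging.getLogger(__name__)

__all__ = [
    "ReadPairAlignment",
    "CompatibilityMatrix",
    "FragmentLengthDistribution",
    "ReadFilters",
    "load_read_pairs",
    "implied_fragment_length",
    "build_compatibility",
    "estimate_fragment_length_distribution",
    "effective_length",
    "per_read_term",
    "likelihood_matrix",
    "log_likelihood",
]


@dataclass(frozen=True)
class ReadPairAlignment:
    """A proper read pair: per-mate aligned genomic blocks (0-based, half-open).

    Blocks are the CIGAR match segments split at N (splice) gaps, sorted
    and non-overlapping within each mate.
    """

    read_id: str
    chrom: str
    blocks_mate1: tuple[tuple[int, int], ...]
    blocks_mate2: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for blocks in (self.blocks_mate1, self.blocks_mate2):
            if not blocks:
                raise ValueError(f"{self.read_id}: mate with no aligned blocks")
            for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
                if s1 < e0:
                    raise ValueError(f"{self.read_id}: unsorted/overlapping blocks")

    @property
    def leftmost(self) -> int:
        return min(self.blocks_mate1[0][0], self.blocks_mate2[0][0])

    @property
    def rightmost(self) -> int:
        return max(self.blocks_mate1[-1][1], self.blocks_mate2[-1][1])


@dataclass
class CompatibilityMatrix:
    """Implied fragment lengths l_k^n for usable pairs of one gene.

    ``lkn`` is N' x K; entry 0 means pair n is incompatible with isoform
    k.  Pairs incompatible with every isoform are dropped before
    construction and tallied in ``n_unassignable``.
    """

    gene_id: str
    isoform_ids: list[str]
    read_ids: list[str]
    lkn: np.ndarray
    n_unassignable: int = 0

    @property
    def n_reads(self) -> int:
        return self.lkn.shape[0]

    @property
    def K(self) -> int:
        return self.lkn.shape[1]


class FragmentLengthDistribution:
    """Discrete fragment (insert) length distribution f(.) on integer support."""

    def __init__(self, support_min: int, pmf: np.ndarray):
        pmf = np.asarray(pmf, dtype=float)
        if pmf.ndim != 1 or pmf.size == 0 or np.any(pmf < 0):
            raise ValueError("pmf must be a non-negative 1-D array")
        total = pmf.sum()
        if total <= 0:
            raise ValueError("pmf must have positive mass")
        self.support_min = int(support_min)
        self._pmf = pmf / total
        self._cdf = np.cumsum(self._pmf)

    @property
    def support_max(self) -> int:
        return self.support_min + self._pmf.size - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.support_min, self.support_max + 1)

    @property
    def probabilities(self) -> np.ndarray:
        return self._pmf.copy()

    @property
    def mean(self) -> float:
        return float(self.support @ self._pmf)

    def pmf(self, lengths) -> np.ndarray:
        """f(l), vectorised; zero outside the support (and for l <= 0)."""
        l = np.asarray(lengths)
        idx = l - self.support_min
        ok = (idx >= 0) & (idx < self._pmf.size)
        out = np.zeros(l.shape, dtype=float)
        out[ok] = self._pmf[idx[ok]]
        return out

    def cdf(self, length: int) -> float:
        idx = int(length) - self.support_min
        if idx < 0:
            return 0.0
        return float(self._cdf[min(idx, self._cdf.size - 1)])

    @classmethod
    def from_lengths(
        cls,
        lengths,
        quantiles: tuple[float, float] = (0.001, 0.999),
        smooth_bw: float | None = None,
    ) -> "FragmentLengthDistribution":
        """Empirical pmf of observed fragment lengths.

        Support is truncated at the given quantiles; ``smooth_bw`` > 0
        applies Gaussian kernel smoothing with that bandwidth (in nt).
        """
        lengths = np.asarray(lengths, dtype=int)
        if lengths.size == 0:
            raise ValueError("no fragment lengths supplied")
        lo = int(np.quantile(lengths, quantiles[0]))
        hi = int(np.quantile(lengths, quantiles[1]))
        lo = max(lo, 1)
        lengths = lengths[(lengths >= lo) & (lengths <= hi)]
        counts = np.bincount(lengths - lo, minlength=hi - lo + 1).astype(float)
        if smooth_bw and smooth_bw > 0:
            grid = np.arange(hi - lo + 1)
            kern = stats.norm.pdf(grid[:, None] - grid[None, :], scale=smooth_bw)
            counts = kern @ counts
        return cls(lo, counts)

    @classmethod
    def from_normal(
        cls, mean: float, sd: float, n_sd: float = 4.0
    ) -> "FragmentLengthDistribution":
        """Discretised normal on [mean - n_sd*sd, mean + n_sd*sd] ∩ [1, ∞)."""
        lo = max(1, int(np.floor(mean - n_sd * sd)))
        hi = int(np.ceil(mean + n_sd * sd))
        grid = np.arange(lo, hi + 1)
        return cls(lo, stats.norm.pdf(grid, loc=mean, scale=sd))

    def __repr__(self):
        return (
            f"FragmentLengthDistribution(support=[{self.support_min}, "
            f"{self.support_max}], mean={self.mean:.1f})"
        )


@dataclass
class ReadFilters:
    """Filters applied when loading read pairs from a BAM/SAM file."""

    min_mapping_quality: int = 0
    primary_only: bool = True
    proper_pair_only: bool = True
    deduplicate: bool = False


def _read_blocks(read: "pysam.AlignedSegment") -> tuple[tuple[int, int], ...]:
    # merge blocks that touch (deletions split get_blocks; splice gaps do not touch)
    merged: list[list[int]] = []
    for s, e in read.get_blocks():
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_read_pairs(
    bam,
    gene: GeneModel,
    filters: ReadFilters | None = None,
) -> tuple[list[ReadPairAlignment], Counter]:
    """Fetch proper read pairs overlapping a gene's span.

    ``bam`` is a path or an open :class:`pysam.AlignmentFile`
    (coordinate-sorted and indexed).  Mates are joined by read name;
    both mates must overlap the gene span on the gene's chromosome.
    Returns the pairs and a counter of exclusions
    (``unpaired_in_region``, ``filtered``, ``duplicate_pair``).
    """
    filters = filters or ReadFilters()
    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    start, end = gene.span
    counters: Counter = Counter()
    first: dict[str, pysam.AlignedSegment] = {}
    pairs: list[ReadPairAlignment] = []
    seen_keys: set = set()
    try:
        for read in af.fetch(gene.chrom, start, end):
            if (
                read.is_unmapped
                or not read.is_paired
                or read.mate_is_unmapped
                or (filters.primary_only and (read.is_secondary or read.is_supplementary))
                or (filters.proper_pair_only and not read.is_proper_pair)
                or read.mapping_quality < filters.min_mapping_quality
            ):
                counters["filtered"] += 1
                continue
            if read.next_reference_id != read.reference_id:
                counters["filtered"] += 1
                continue
            mate = first.pop(read.query_name, None)
            if mate is None:
                first[read.query_name] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            pair = ReadPairAlignment(
                read_id=r1.query_name,
                chrom=gene.chrom,
                blocks_mate1=_read_blocks(r1),
                blocks_mate2=_read_blocks(r2),
            )
            if filters.deduplicate:
                key = (pair.blocks_mate1, pair.blocks_mate2)
                if key in seen_keys:
                    counters["duplicate_pair"] += 1
                    continue
                seen_keys.add(key)
            pairs.append(pair)
    finally:
        if own:
            af.close()
    counters["unpaired_in_region"] += len(first)
    return pairs, counters


def _project_mate(blocks, iso: IsoformModel) -> tuple[int, int] | None:
    """Transcript (start, end) offsets of one mate, or None if incompatible.

    Each block must map contiguously inside the isoform's exon chain and
    consecutive blocks must be transcript-adjacent (their gap is exactly
    an intron of the isoform).
    """
    t_prev_end = None
    t_first = None
    for s, e in blocks:
        ts = iso.genomic_to_transcript(s)
        te = iso.genomic_to_transcript(e - 1)
        if ts is None or te is None or te - ts != (e - 1) - s:
            return None
        if t_prev_end is not None and ts != t_prev_end + 1:
            return None
        if t_first is None:
            t_first = ts
        t_prev_end = te
    return t_first, t_prev_end


def implied_fragment_length(pair: ReadPairAlignment, iso: IsoformModel) -> int:
    """l_k^n: length of the isoform fragment whose ends match the pair, else 0.

    Both mates must align block-by-block onto the isoform (every splice
    gap in the alignment must be an intron of the isoform).  The length
    is the inclusive transcript-coordinate distance between the pair's
    outer ends; it is invariant to swapping the mates and to strand.
    """
    p1 = _project_mate(pair.blocks_mate1, iso)
    if p1 is None:
        return 0
    p2 = _project_mate(pair.blocks_mate2, iso)
    if p2 is None:
        return 0
    return max(p1[1], p2[1]) - min(p1[0], p2[0]) + 1


def build_compatibility(
    pairs: list[ReadPairAlignment], gene: GeneModel
) -> CompatibilityMatrix:
    """Assemble the N' x K implied-fragment-length matrix for a gene.

    Pairs compatible with no isoform are dropped and tallied as
    unassignable.  A gene where every pair is unassignable yields an
    empty matrix (``n_reads == 0``); callers flag it "no usable reads".
    """
    rows, ids = [], []
    n_unassignable = 0
    for pair in pairs:
        row = [implied_fragment_length(pair, iso) for iso in gene.isoforms]
        if any(row):
            rows.append(row)
            ids.append(pair.read_id)
        else:
            n_unassignable += 1
    lkn = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, gene.K), dtype=np.int64)
    )
    return CompatibilityMatrix(gene.gene_id, gene.isoform_ids, ids, lkn, n_unassignable)


def unambiguous_fragment_lengths(compat: CompatibilityMatrix) -> np.ndarray:
    """Implied lengths of pairs whose compatible isoforms all agree on length."""
    out = []
    for row in compat.lkn:
        pos = row[row > 0]
        if pos.size and np.all(pos == pos[0]):
            out.append(int(pos[0]))
    return np.asarray(out, dtype=int)


def estimate_fragment_length_distribution(
    bams,
    gene_models,
    min_fragments: int = 1000,
    quantiles: tuple[float, float] = (0.001, 0.999),
    smooth_bw: float | None = None,
    fallback_mean: float = 250.0,
    fallback_sd: float = 25.0,
    filters: ReadFilters | None = None,
) -> FragmentLengthDistribution:
    """Estimate f(.) from unambiguous read pairs pooled across genes.

    Only pairs whose compatible isoforms all imply the same fragment
    length contribute (e.g. both mates inside an exon shared by every
    isoform, or single-isoform genes), so the estimate does not depend
    on unknown isoform proportions.  Pooling is genome-wide per sample.
    With fewer than ``min_fragments`` usable pairs a discretised normal
    fallback (``fallback_mean``/``fallback_sd``) is returned with a
    warning.
    """
    if isinstance(bams, str):
        bams = [bams]
    genes = gene_models.values() if isinstance(gene_models, dict) else gene_models
    lengths: list[np.ndarray] = []
    for bam in bams:
        own = isinstance(bam, str)
        af = pysam.AlignmentFile(bam) if own else bam
        try:
            for gene in genes:
                pairs, _ = load_read_pairs(af, gene, filters)
                if pairs:
                    lengths.append(
                        unambiguous_fragment_lengths(build_compatibility(pairs, gene))
                    )
        finally:
            if own:
                af.close()
    all_lengths = (
        np.concatenate(lengths) if lengths else np.zeros(0, dtype=int)
    )
    if all_lengths.size < min_fragments:
        warnings.warn(
            f"only {all_lengths.size} unambiguous fragments "
            f"(< {min_fragments}); falling back to discretised "
            f"normal({fallback_mean}, {fallback_sd}^2)"
        )
        return FragmentLengthDistribution.from_normal(fallback_mean, fallback_sd)
    return FragmentLengthDistribution.from_lengths(all_lengths, quantiles, smooth_bw)


def effective_length(l_k: int, fld: FragmentLengthDistribution) -> float:
    """Expected number of valid fragment placements: sum_l f(l) max(l_k-l+1, 0)."""
    support = fld.support
    return float(np.maximum(l_k - support + 1, 0) @ fld.probabilities)


def per_read_term(lkn: int, l_k: int, fld: FragmentLengthDistribution) -> float:
    """a_{nk} = f(l_k^n) / (l_k - l_k^n + 1); 0 when incompatible."""
    if lkn <= 0 or lkn > l_k:
        return 0.0
    return float(fld.pmf(lkn)) / (l_k - lkn + 1)


def likelihood_matrix(
    compat: CompatibilityMatrix, fld: FragmentLengthDistribution, lengths=None
) -> np.ndarray:
    """N' x K matrix of per-read terms a_{nk} (vectorised).

    ``lengths`` are the isoform lengths l_k; by default they must be
    supplied by the caller holding the gene model — pass
    ``[iso.length for iso in gene.isoforms]``.
    """
    if lengths is None:
        raise ValueError("isoform lengths required")
    lk = np.asarray(lengths, dtype=np.int64)[None, :]
    lkn = compat.lkn
    ok = (lkn > 0) & (lkn <= lk)
    A = np.where(ok, fld.pmf(lkn) / np.maximum(lk - lkn + 1, 1), 0.0)
    return A


def log_likelihood(p, A: np.ndarray) -> float:
    """Mixture log-likelihood sum_n log sum_k p_k a_{nk}.

    Returns -inf when some read has zero mixture mass; that signals a
    filtering problem upstream (the read should have been unassignable).
    """
    mix = A @ np.asarray(p, dtype=float)
    if np.any(mix <= 0):
        return -np.inf
    return float(np.log(mix).sum())
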