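"""Synthetic paired-end alignment data with known isoform usage.

The generator runs the estimation model forward under the hierarchical
usage model: per-sample usage compositions are drawn on ilr coordinates
from N(ilr(theta_group), Sigma) and mapped back to the simplex; read
pairs are then placed on isoforms chosen with probability proportional
to theta_k * Z_k (effective length Z_k), with fragment lengths drawn
from f(.) conditioned on fitting the isoform and start positions
uniform over the valid placements.  Alignments are emitted either as
in-memory :class:`ReadPairAlignment` objects (fast, for calibration
studies) or as valid coordinate-sorted SAM/BAM with spliced (N) CIGARs.

Defaults mirror the study design the package is calibrated under:
five samples per group, average per-gene read coverage on a
10-110 grid (100 for the main design), and a discretised-normal
fragment length model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from . import compositional as comp
from .alignments import (
    FragmentLengthDistribution,
    ReadPairAlignment,
    effective_length,
)
from .annotation import ExonInterval, GeneModel, IsoformModel
from .twosample import DifferentialUsage
from .usage import IsoformUsageModel

__all__ = [
    "SimulationConfig",
    "sample_usage_vectors",
    "simulate_read_pairs",
    "write_sam",
    "write_bam_indexed",
    "toy_gene_models",
    "run_calibration_study",
]


def sample_usage_vectors(ilr_mean, Sigma, J: int, rng) -> np.ndarray:
    """Draw J usage compositions: ilr coords ~ N(ilr_mean, Sigma).

    All draws are strictly positive by construction (the ilr inverse
    maps into the open simplex).  ``rng`` is a seed or a Generator.
    """
    rng = np.random.default_rng(rng)
    mean = np.asarray(ilr_mean, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    z = rng.multivariate_normal(mean, Sigma, size=J)
    return comp.ilr_inverse(z)


def simulate_read_pairs(
    gene: GeneModel,
    theta,
    coverage: float,
    fld: FragmentLengthDistribution,
    read_len: int = 50,
    rng=None,
    read_id_prefix: str = "sim",
):
    """Generate aligned read pairs for one gene at known usage ``theta``.

    The pair count is set so the expected per-base depth matches
    ``coverage``: N = round(coverage * sum_k theta_k l_k / (2 read_len)).
    Isoforms too short for every fragment length are excluded from
    placement (flagged in the returned truth table).

    Returns ``(pairs, truth)`` where ``truth`` is a DataFrame with one
    row per pair: source isoform index and drawn fragment length.
    """
    rng = np.random.default_rng(rng)
    theta = np.asarray(theta, dtype=float)
    if theta.size != gene.K:
        raise ValueError("theta must have one part per isoform")
    lengths = np.array([iso.length for iso in gene.isoforms])
    Z = np.array([effective_length(int(l), fld) for l in lengths])
    feasible = Z > 0
    if not feasible.any():
        raise ValueError(f"gene {gene.gene_id}: no isoform can hold any fragment")
    weights = theta * Z * feasible
    if weights.sum() <= 0:
        raise ValueError(f"gene {gene.gene_id}: all expressed isoforms too short")
    p = weights / weights.sum()
    N = max(1, int(round(coverage * float(theta @ lengths) / (2 * read_len))))

    support = fld.support
    probs = fld.probabilities
    pairs: list[ReadPairAlignment] = []
    iso_idx = rng.choice(gene.K, size=N, p=p)
    records = []
    for n, k in enumerate(iso_idx):
        iso = gene.isoforms[k]
        ok = support <= lengths[k]
        pk = probs[ok]
        frag_len = int(rng.choice(support[ok], p=pk / pk.sum()))
        start = int(rng.integers(0, lengths[k] - frag_len + 1))
        mlen = min(read_len, frag_len)
        b1 = tuple(
            (s, e) for s, e in iso.transcript_interval_to_blocks(start, start + mlen)
        )
        b2 = tuple(
            (s, e)
            for s, e in iso.transcript_interval_to_blocks(
                start + frag_len - mlen, start + frag_len
            )
        )
        pairs.append(
            ReadPairAlignment(f"{read_id_prefix}_{gene.gene_id}_{n}", gene.chrom, b1, b2)
        )
        records.append((k, frag_len, start))
    truth = pd.DataFrame(
        records, columns=["isoform_index", "fragment_length", "start"]
    )
    truth.attrs["excluded_isoforms"] = list(np.flatnonzero(~feasible))
    return pairs, truth


def _cigar(blocks) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def _sam_header(chrom_lengths: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(chrom_lengths.items())],
    }


def write_sam(pairs, chrom_lengths: dict[str, int], path: str) -> None:
    """Write pairs as a valid coordinate-sorted SAM (or BAM by extension).

    Output is a pure function of the input pairs: records carry no
    timestamps or program lines, so identical inputs give byte-identical
    files.
    """
    mode = "wb" if path.endswith(".bam") else "w"
    order = sorted(
        range(len(pairs)), key=lambda i: (pairs[i].chrom, pairs[i].leftmost, pairs[i].read_id)
    )
    with pysam.AlignmentFile(path, mode, header=_sam_header(chrom_lengths)) as out:
        records = []
        for i in order:
            pair = pairs[i]
            tid = out.get_tid(pair.chrom)
            tlen = pair.rightmost - pair.leftmost
            for mate_i, (blocks, flag) in enumerate(
                ((pair.blocks_mate1, 99), (pair.blocks_mate2, 147))
            ):
                a = pysam.AlignedSegment()
                a.query_name = pair.read_id
                a.flag = flag
                a.reference_id = tid
                a.reference_start = blocks[0][0]
                a.mapping_quality = 60
                a.cigar = _cigar(blocks)
                other = pair.blocks_mate2 if mate_i == 0 else pair.blocks_mate1
                a.next_reference_id = tid
                a.next_reference_start = other[0][0]
                a.template_length = tlen if mate_i == 0 else -tlen
                qlen = sum(e - s for s, e in blocks)
                a.query_sequence = "A" * qlen
                records.append(a)
        for a in sorted(records, key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag)):
            out.write(a)


def write_bam_indexed(pairs, chrom_lengths: dict[str, int], path: str) -> str:
    """Write a coordinate-sorted, indexed BAM; returns the path."""
    if not path.endswith(".bam"):
        raise ValueError("path must end in .bam")
    write_sam(pairs, chrom_lengths, path)
    pysam.index(path)
    return path


def toy_gene_models() -> dict[str, GeneModel]:
    """Built-in toy genes for simulation studies.

    Five genes with K = 1, 2, 3, 5 isoforms on a synthetic chromosome,
    combining shared and private exons (skipped exons, alternate
    terminal exons) so that isoforms are distinguishable but overlap.
    """

    def iso(tid, gid, chrom, strand, exons):
        return IsoformModel(
            tid, gid, [ExonInterval(chrom, s, e, strand) for s, e in exons]
        )

    genes = {}
    # K=2: skipped middle exon (lengths 700 vs 500)
    genes["toyA"] = GeneModel(
        "toyA",
        [
            iso("toyA.1", "toyA", "chrS", "+", [(1000, 1300), (1500, 1700), (1900, 2100)]),
            iso("toyA.2", "toyA", "chrS", "+", [(1000, 1300), (1900, 2100)]),
        ],
    )
    # K=3: skipped exon + alternate last exon, on the minus strand
    genes["toyB"] = GeneModel(
        "toyB",
        [
            iso("toyB.1", "toyB", "chrS", "-", [(5000, 5400), (5600, 5800), (6000, 6300)]),
            iso("toyB.2", "toyB", "chrS", "-", [(5000, 5400), (6000, 6300)]),
            iso("toyB.3", "toyB", "chrS", "-", [(5000, 5400), (5600, 5800), (6500, 6800)]),
        ],
    )
    # K=5: combinations of two cassette exons and alternate ends
    genes["toyC"] = GeneModel(
        "toyC",
        [
            iso("toyC.1", "toyC", "chrS", "+", [(10000, 10400), (10600, 10800), (11000, 11200), (11400, 11700)]),
            iso("toyC.2", "toyC", "chrS", "+", [(10000, 10400), (10600, 10800), (11400, 11700)]),
            iso("toyC.3", "toyC", "chrS", "+", [(10000, 10400), (11000, 11200), (11400, 11700)]),
            iso("toyC.4", "toyC", "chrS", "+", [(10000, 10400), (11400, 11700)]),
            iso("toyC.5", "toyC", "chrS", "+", [(10000, 10400), (10600, 10800), (11000, 11200), (12000, 12300)]),
        ],
    )
    # K=1: single-isoform control
    genes["toyD"] = GeneModel(
        "toyD", [iso("toyD.1", "toyD", "chrS", "+", [(15000, 15800)])]
    )
    # K=2: alternate first exon
    genes["toyE"] = GeneModel(
        "toyE",
        [
            iso("toyE.1", "toyE", "chrS", "+", [(20000, 20350), (20700, 21100)]),
            iso("toyE.2", "toyE", "chrS", "+", [(20400, 20600), (20700, 21100)]),
        ],
    )
    return genes


def toy_chrom_lengths() -> dict[str, int]:
    return {"chrS": 30000}


@dataclass
class SimulationConfig:
    """Study design for a size/power calibration run.

    ``theta_null`` is the usage shared by both groups under the null;
    under the alternative group 1's ilr mean is shifted by
    ``delta`` * (unit vector along the first ilr coordinate).  Between-
    sample variation is N(., sigma^2 I) on ilr coordinates.
    """

    gene: GeneModel
    theta_null: np.ndarray
    delta: float = 0.0
    sigma: float = 0.15
    J0: int = 5
    J1: int = 5
    coverages: tuple = (10, 30, 50, 70, 90, 110)
    n_reps: int = 100
    alpha: float = 0.05
    method: str = "SKK"
    permutation_B: int | None = None
    read_len: int = 50
    frag_mean: float = 200.0
    frag_sd: float = 20.0
    eps: float = 1e-4
    min_reads: int = 10
    seed: int = 0


def _simulate_group_estimates(gene, thetas, coverage, fld, read_len, rng, min_reads):
    ests = []
    for th in thetas:
        pairs, _ = simulate_read_pairs(
            gene, th, coverage, fld, read_len, rng.integers(2**31)
        )
        model = IsoformUsageModel.from_pairs(pairs, gene, fld)
        ests.append(model.fit(n_random_starts=0, min_reads=min_reads))
    return ests


def run_calibration_study(config: SimulationConfig) -> pd.DataFrame:
    """Empirical rejection rate of the full pipeline per coverage level.

    For each replicate: draw per-sample usage for both groups (same ilr
    mean under the null, means ``delta`` apart along the first ilr axis
    under the alternative), simulate alignments, estimate usage per
    sample by EM, and test at level ``alpha``.  Returns a DataFrame
    with rejection fractions and binomial standard errors.
    """
    gene = config.gene
    fld = FragmentLengthDistribution.from_normal(config.frag_mean, config.frag_sd)
    mu0 = comp.ilr(np.asarray(config.theta_null, dtype=float))
    mu1 = mu0.copy()
    if config.delta:
        mu1[0] += config.delta
    d = mu0.size
    Sigma = config.sigma**2 * np.eye(d)
    rng = np.random.default_rng(config.seed)
    rows = []
    for coverage in config.coverages:
        rejections = 0
        used = 0
        for _ in range(config.n_reps):
            th0 = sample_usage_vectors(mu0, Sigma, config.J0, rng.integers(2**31))
            th1 = sample_usage_vectors(mu1, Sigma, config.J1, rng.integers(2**31))
            e0 = _simulate_group_estimates(
                gene, th0, coverage, fld, config.read_len, rng, config.min_reads
            )
            e1 = _simulate_group_estimates(
                gene, th1, coverage, fld, config.read_len, rng, config.min_reads
            )
            du = DifferentialUsage.from_estimates(e0, e1, eps=config.eps)
            res = du.fit(
                method=config.method,
                permutation_B=config.permutation_B,
                seed=int(rng.integers(2**31)),
            )
            if not res.testable or not np.isfinite(res.p_value):
                continue
            used += 1
            rejections += res.p_value <= config.alpha
        rate = rejections / used if used else np.nan
        se = np.sqrt(rate * (1 - rate) / used) if used else np.nan
        rows.append(
            {
                "gene_id": gene.gene_id,
                "coverage": coverage,
                "scenario": "alternative" if config.delta else "null",
                "method": config.method,
                "n_reps": used,
                "rejection_rate": rate,
                "se": se,
            }
        )
    return pd.DataFrame(rows)
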