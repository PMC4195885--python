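"""Gene/isoform models parsed from GTF annotation.

Internal coordinates are 0-based half-open (the BAM convention); the GTF
reader/writer converts from/to 1-based inclusive at the boundary.

Transcript offsets used for fragment-length arithmetic run along the
genomic forward strand.  Fragment lengths are distances between two
transcript positions and are therefore identical whether offsets are
counted 5'->3' or genomic-forward, so compatibility computations are
strand-symmetric; :meth:`IsoformModel.genomic_to_transcript` exposes the
5'->3' convention via ``five_prime=True`` for callers that need it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import gffutils

logger = logging.getLogger(__name__)

__all__ = [
    "ExonInterval",
    "IsoformModel",
    "GeneModel",
    "parse_annotation",
    "write_gtf",
    "AnnotationError",
]


class AnnotationError(ValueError):
    """Raised for annotation records the gene model cannot represent."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon: 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationError(
                f"exon start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IsoformModel:
    """A transcript isoform: an ordered chain of non-overlapping exons."""

    isoform_id: str
    gene_id: str
    exons: list[ExonInterval]

    # cumulative exon starts in transcript coordinates, genomic-forward
    _cumlen: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"isoform {self.isoform_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"isoform {self.isoform_id} spans multiple chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"isoform {self.isoform_id} has overlapping exons"
                )
        cum = [0]
        for e in self.exons:
            cum.append(cum[-1] + len(e))
        self._cumlen = cum

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Transcript length l_k: sum of exon lengths."""
        return self._cumlen[-1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def genomic_to_transcript(self, pos: int, five_prime: bool = False) -> int | None:
        """Transcript offset of genomic position ``pos``, or None if off-isoform.

        Offsets are genomic-forward by default; with ``five_prime=True``
        they run 5'->3' along the transcript (reversed on the minus
        strand).
        """
        for i, e in enumerate(self.exons):
            if e.start <= pos < e.end:
                t = self._cumlen[i] + (pos - e.start)
                if five_prime and self.strand == "-":
                    return self.length - 1 - t
                return t
        return None

    def transcript_to_genomic(self, t: int, five_prime: bool = False) -> int:
        """Genomic position of transcript offset ``t`` (inverse projection)."""
        if five_prime and self.strand == "-":
            t = self.length - 1 - t
        if not 0 <= t < self.length:
            raise ValueError(f"transcript offset {t} outside [0, {self.length})")
        for i, e in enumerate(self.exons):
            if t < self._cumlen[i + 1]:
                return e.start + (t - self._cumlen[i])
        raise AssertionError("unreachable")

    def transcript_interval_to_blocks(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Project a half-open transcript interval to genomic blocks.

        Returns the sorted list of 0-based half-open genomic intervals
        covered, one per exon touched (adjacent exon pieces are separate
        blocks — they flank introns).
        """
        if not (0 <= t_start < t_end <= self.length):
            raise ValueError("transcript interval outside isoform")
        blocks = []
        for i, e in enumerate(self.exons):
            lo, hi = self._cumlen[i], self._cumlen[i + 1]
            s, t = max(t_start, lo), min(t_end, hi)
            if s < t:
                blocks.append((e.start + (s - lo), e.start + (t - lo)))
        return blocks


@dataclass
class GeneModel:
    """A gene: one or more isoforms on a single chromosome and strand."""

    gene_id: str
    isoforms: list[IsoformModel]

    def __post_init__(self):
        if not self.isoforms:
            raise AnnotationError(f"gene {self.gene_id} has no isoforms")
        ids = [iso.isoform_id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"gene {self.gene_id} has duplicate isoform ids")
        if len({iso.chrom for iso in self.isoforms}) > 1 or len(
            {iso.strand for iso in self.isoforms}
        ) > 1:
            raise AnnotationError(
                f"gene {self.gene_id} spans multiple chromosomes or strands"
            )

    @property
    def K(self) -> int:
        return len(self.isoforms)

    @property
    def chrom(self) -> str:
        return self.isoforms[0].chrom

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(i.span[0] for i in self.isoforms),
            max(i.span[1] for i in self.isoforms),
        )

    @property
    def isoform_ids(self) -> list[str]:
        return [i.isoform_id for i in self.isoforms]


def parse_annotation(
    path: str,
    gene_key: str = "gene_id",
    transcript_key: str = "transcript_id",
) -> dict[str, GeneModel]:
    """Parse a GTF/GFF file into GeneModels keyed by gene id.

    Exon records are grouped by transcript, transcripts by gene, using
    the configurable attribute keys (Ensembl/UCSC dialects both use
    ``gene_id``/``transcript_id``).  GTF 1-based inclusive coordinates
    become 0-based half-open.  Malformed records are skipped with a
    warning; a gene whose exons sit on several chromosomes or strands is
    rejected with :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict[str, list[ExonInterval]]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gid = feat.attributes[gene_key][0]
            tid = feat.attributes[transcript_key][0]
        except KeyError:
            warnings.warn(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                f"{gene_key}/{transcript_key}; skipped"
            )
            continue
        try:
            exon = ExonInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        except AnnotationError as err:
            warnings.warn(f"malformed exon skipped: {err}")
            continue
        by_gene.setdefault(gid, {}).setdefault(tid, []).append(exon)

    genes: dict[str, GeneModel] = {}
    for gid, transcripts in by_gene.items():
        isoforms = [
            IsoformModel(tid, gid, exons) for tid, exons in transcripts.items()
        ]
        genes[gid] = GeneModel(gid, isoforms)
    logger.info("parsed %d genes from %s", len(genes), path)
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "isousage") -> None:
    """Serialise gene models back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            for iso in gene.isoforms:
                for e in iso.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{iso.isoform_id}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t."
                        f"\t{e.strand}\t.\t{attrs}\n"
                    )
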