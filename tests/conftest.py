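import numpy as np
import pysam
import pytest

from isousage.annotation import ExonInterval, GeneModel, IsoformModel
from isousage.alignments import FragmentLengthDistribution


@pytest.fixture
def fld_point300():
    """Point mass at fragment length 300."""
    return FragmentLengthDistribution(300, np.array([1.0]))


@pytest.fixture
def fld_normal():
    return FragmentLengthDistribution.from_normal(200.0, 20.0)


@pytest.fixture
def two_exon_iso():
    """Two 100-nt exons separated by a 100-nt intron, plus strand."""
    return IsoformModel(
        "isoX.1",
        "isoX",
        [ExonInterval("chr1", 100, 200), ExonInterval("chr1", 300, 400)],
    )


@pytest.fixture
def three_iso_gene():
    """Three isoforms: full, exon-2-skipped, alternate last exon."""
    def iso(tid, exons):
        return IsoformModel(tid, "g3", [ExonInterval("chr1", s, e) for s, e in exons])

    return GeneModel(
        "g3",
        [
            iso("g3.1", [(1000, 1300), (1500, 1700), (1900, 2200)]),
            iso("g3.2", [(1000, 1300), (1900, 2200)]),
            iso("g3.3", [(1000, 1300), (1500, 1700), (2400, 2700)]),
        ],
    )


def make_pair(read_id, chrom, blocks1, blocks2):
    from isousage.alignments import ReadPairAlignment

    return ReadPairAlignment(
        read_id, chrom, tuple(map(tuple, blocks1)), tuple(map(tuple, blocks2))
    )


@pytest.fixture
def bam_from_sam(tmp_path):
    """Factory: SAM text -> coordinate-sorted indexed BAM path."""

    def _make(sam_text: str, name: str = "fixture") -> str:
        sam = tmp_path / f"{name}.sam"
        bam = tmp_path / f"{name}.bam"
        sam.write_text(sam_text)
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        return str(bam)

    return _make
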