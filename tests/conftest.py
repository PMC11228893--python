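import numpy as np
import pysam
import pytest

from ribocn.reference_prep import AnalogueRegionSet, GenomicInterval


@pytest.fixture()
def toy_bam(tmp_path):
    """Hand-built indexed BAM: chr1/chr2/chrUn with known read placements.

    chr1: 100 reads, chr2: 50 reads, chrUn_test: 5 reads of which 3 fall
    inside the region [1000, 2000) and 2 outside; one extra read straddles
    two nearby regions on chr1 (positions 5000-5100 over [4950,5050)+[5060,5150)).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": "chr1", "LN": 100_000},
            {"SN": "chr2", "LN": 100_000},
            {"SN": "chrUn_test", "LN": 100_000},
        ],
    }
    placements = []
    placements += [(0, 10_000 + 10 * i) for i in range(99)]
    placements += [(0, 5_000)]  # straddles the two adjacent chr1 regions
    placements += [(1, 20_000 + 10 * i) for i in range(50)]
    placements += [(2, 1_100), (2, 1_500), (2, 1_900)]  # inside [1000,2000)
    placements += [(2, 50_000), (2, 60_000)]  # outside
    placements.sort()
    path = tmp_path / "toy.bam"
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (tid, pos) in enumerate(placements):
            read = pysam.AlignedSegment(bam.header)
            read.query_name = f"r{i}"
            read.reference_id = tid
            read.reference_start = pos
            read.mapping_quality = 60
            read.cigarstring = "100M"
            read.query_sequence = "A" * 100
            read.flag = 0
            bam.write(read)
    pysam.index(str(path))
    return path


@pytest.fixture()
def toy_regions():
    """One region on chrUn_test plus two adjacent regions on chr1."""
    return AnalogueRegionSet(
        [
            GenomicInterval("chrUn_test", 1_000, 2_000),
            GenomicInterval("chr1", 4_950, 5_050),
            GenomicInterval("chr1", 5_060, 5_150),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
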