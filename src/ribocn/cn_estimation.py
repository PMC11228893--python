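"""Per-sample 18S Ratio computation and conversion to rDNA copy-number equivalents.

The proxy statistic is the number of alignment records overlapping any
18S-analogue region divided by the number of records mapped to the numbered
chromosomes (1-22). Multiplying by the total numbered-chromosome span of the
assembly (2,875,001,522 bases for Hg38) and dividing by the 18S subunit size
(1,871 bases) converts the ratio into an approximate diploid copy number.
An independent, prior-published estimator — twice the mean 18S read depth over
the mean filtered-exome depth — is provided for cross-method validation, and a
one-factor regression adjustment removes sequencing-center batch shifts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from scipy import stats

from ribocn.errors import EstimationError, InsufficientDataError, ValidationError
from ribocn.reference_prep import AnalogueRegionSet

#: total span of Hg38 chromosomes 1-22, in bases
HG38_NUMBERED_CHROMOSOME_BASES = 2_875_001_522
#: length of the 18S subunit used for copy-number conversion, in bases
SUBUNIT_18S_BASES = 1_871

_NUMBERED_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


@dataclass(frozen=True)
class ConversionConstants:
    """Genome-size and subunit-size constants of the ratio -> copy-number conversion."""

    genome_bases: int = HG38_NUMBERED_CHROMOSOME_BASES
    subunit_bases: int = SUBUNIT_18S_BASES

    def __post_init__(self):
        if self.genome_bases <= 0 or self.subunit_bases <= 0:
            raise ValidationError("conversion constants must be positive")


@dataclass(frozen=True)
class DepthPair:
    """Mean per-base depths feeding the tailored-assembly estimator."""

    depth_18s: float
    depth_exome: float

    def __post_init__(self):
        if self.depth_18s < 0 or self.depth_exome < 0:
            raise ValidationError("depths must be non-negative")


@dataclass(frozen=True)
class CountingPolicy:
    """Which alignment-record classes participate in counting.

    The default includes secondary/supplementary/duplicate records, mirroring an
    unfiltered ``samtools view -c`` / ``idxstats`` count; ``primary_only()``
    restricts to primary, non-duplicate records.
    """

    include_secondary: bool = True
    include_supplementary: bool = True
    include_duplicates: bool = True

    @classmethod
    def primary_only(cls) -> "CountingPolicy":
        return cls(False, False, False)

    def admits(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if read.is_secondary and not self.include_secondary:
            return False
        if read.is_supplementary and not self.include_supplementary:
            return False
        if read.is_duplicate and not self.include_duplicates:
            return False
        return True


@dataclass
class RatioEstimate:
    """One sample's region count, baseline, ratio and copy-number equivalent."""

    sample_id: str
    region_reads: int
    numbered_reads: int
    ratio: float
    cn_equivalent: float
    center: str = ""
    adjusted_ratio: float | None = None
    flag: str | None = None


def _open_alignment(path: str | Path, reference: str | Path | None) -> pysam.AlignmentFile:
    kwargs = {}
    if reference is not None:
        kwargs["reference_filename"] = str(reference)
    return pysam.AlignmentFile(str(path), **kwargs)


def count_region_reads(
    alignment: str | Path | pysam.AlignmentFile,
    regions: AnalogueRegionSet,
    policy: CountingPolicy = CountingPolicy(),
    reference: str | Path | None = None,
) -> int:
    """Count records overlapping >= 1 analogue region by >= 1 base, each once.

    Count-once-across-regions semantics: a record overlapping several regions
    contributes one. Raises if a region contig is absent from the header.
    """
    own = not isinstance(alignment, pysam.AlignmentFile)
    af = _open_alignment(alignment, reference) if own else alignment
    try:
        header_contigs = set(af.references)
        missing = [c for c in regions.contigs() if c not in header_contigs]
        if missing:
            raise ValidationError(f"region contig(s) absent from alignment header: {missing}")
        seen: set[tuple] = set()
        count = 0
        for iv in regions:
            for read in af.fetch(iv.contig, iv.start, iv.end):
                if not policy.admits(read):
                    continue
                key = (read.query_name, read.reference_id, read.reference_start, read.flag)
                if key in seen:
                    continue
                seen.add(key)
                count += 1
        return count
    finally:
        if own:
            af.close()


def count_numbered_chromosome_reads(
    alignment: str | Path | pysam.AlignmentFile,
    reference: str | Path | None = None,
) -> dict[str, int]:
    """Mapped-record counts per contig, as reported by the alignment index.

    Equivalent to ``samtools idxstats`` mapped-read column. The unmapped column
    is never included.
    """
    own = not isinstance(alignment, pysam.AlignmentFile)
    af = _open_alignment(alignment, reference) if own else alignment
    try:
        stats_ = af.get_index_statistics()
        return {s.contig: s.mapped for s in stats_}
    finally:
        if own:
            af.close()


def is_numbered_chromosome(contig: str) -> bool:
    """True for chromosomes 1-22 in either naming dialect ('chr1' or '1')."""
    return bool(_NUMBERED_RE.match(contig))


def numbered_chromosome_sum(contig_counts: Mapping[str, int]) -> int:
    """Sum mapped counts over chromosomes 1-22; errors if none is present."""
    numbered = {c: n for c, n in contig_counts.items() if is_numbered_chromosome(c)}
    if not numbered:
        raise EstimationError(
            "no numbered chromosome (chr1-chr22 or 1-22) found among contigs; "
            "refusing a silent zero baseline"
        )
    return sum(numbered.values())


def compute_18s_ratio(region_reads: int, contig_counts: Mapping[str, int] | int) -> float:
    """18S Ratio: region reads over the numbered-chromosome baseline."""
    if region_reads < 0:
        raise ValidationError("negative region read count")
    baseline = (
        contig_counts
        if isinstance(contig_counts, (int, np.integer))
        else numbered_chromosome_sum(contig_counts)
    )
    if baseline <= 0:
        raise EstimationError("numbered-chromosome baseline is zero")
    return region_reads / baseline


def ratio_to_cn_equivalent(
    ratio: float, constants: ConversionConstants = ConversionConstants()
) -> float:
    """Convert an 18S Ratio to a diploid copy-number equivalent: ratio x G / L."""
    if ratio < 0:
        raise ValidationError("negative ratio")
    return ratio * constants.genome_bases / constants.subunit_bases


def tailored_cn_estimate(depths: DepthPair) -> float:
    """Prior-published estimator: twice the 18S/exome mean-depth quotient."""
    if depths.depth_exome <= 0:
        raise EstimationError("zero exome depth")
    return 2.0 * depths.depth_18s / depths.depth_exome


def estimate_sample(
    sample_id: str,
    alignment: str | Path,
    regions: AnalogueRegionSet,
    center: str = "",
    policy: CountingPolicy = CountingPolicy(),
    constants: ConversionConstants = ConversionConstants(),
    reference: str | Path | None = None,
) -> RatioEstimate:
    """Full per-sample proxy estimate from an indexed alignment.

    Baseline failures flag the sample (machine-readable ``flag``) instead of
    raising, so batch runs keep going.
    """
    with _open_alignment(alignment, reference) as af:
        region_reads = count_region_reads(af, regions, policy)
        contig_counts = count_numbered_chromosome_reads(af)
    try:
        baseline = numbered_chromosome_sum(contig_counts)
        ratio = compute_18s_ratio(region_reads, baseline)
    except EstimationError as exc:
        return RatioEstimate(sample_id, region_reads, 0, math.nan, math.nan,
                             center=center, flag=str(exc))
    return RatioEstimate(
        sample_id,
        region_reads,
        baseline,
        ratio,
        ratio_to_cn_equivalent(ratio, constants),
        center=center,
    )


def center_adjust(
    estimates: Sequence[RatioEstimate], reference_center: str
) -> list[RatioEstimate]:
    """Remove sequencing-center batch shifts by one-factor regression.

    Fits ratio ~ center with ``reference_center`` as the reference level and
    subtracts each non-reference center's coefficient from its samples' ratios
    (for a single categorical predictor the coefficient is exactly the
    difference of center means). After adjustment all center means coincide.
    Single-center input is returned unchanged with a warning.
    """
    import warnings

    centers = {e.center for e in estimates}
    if reference_center not in centers:
        raise ValidationError(f"reference center {reference_center!r} not present in input")
    if len(centers) < 2:
        warnings.warn("single-center input: center adjustment is the identity", stacklevel=2)
        return [replace(e, adjusted_ratio=e.ratio) for e in estimates]
    ref_mean = np.mean([e.ratio for e in estimates if e.center == reference_center])
    offsets = {
        c: float(np.mean([e.ratio for e in estimates if e.center == c]) - ref_mean)
        for c in centers
    }
    offsets[reference_center] = 0.0
    return [replace(e, adjusted_ratio=e.ratio - offsets[e.center]) for e in estimates]


def familial_correlation(
    estimates: Mapping[str, float] | Sequence[RatioEstimate],
    pairs: Iterable[tuple[str, str]],
    use_adjusted: bool = False,
) -> tuple[float, float, int]:
    """Pearson correlation of proxy estimates across relative pairs.

    ``pairs`` fixes the member ordering; returns (r, p, n_pairs). Requires at
    least 3 pairs with both members estimated.
    """
    if not isinstance(estimates, Mapping):
        key = "adjusted_ratio" if use_adjusted else "ratio"
        estimates = {e.sample_id: getattr(e, key) for e in estimates}
    x, y = [], []
    for id1, id2 in pairs:
        if id1 in estimates and id2 in estimates:
            v1, v2 = estimates[id1], estimates[id2]
            if v1 is not None and v2 is not None and math.isfinite(v1) and math.isfinite(v2):
                x.append(v1)
                y.append(v2)
    if len(x) < 3:
        raise InsufficientDataError(
            f"need >= 3 estimated pairs for a familial correlation, got {len(x)}"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)
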