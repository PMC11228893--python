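"""rDNA reference preparation: 18S query extraction, looped references, analogue discovery.

The 47S rDNA unit is a circular-ish tandem repeat in practice: reads from the
promoter-proximal ends of a unit map poorly when the linear reference starts at
the transcription start site (TSS). The "looped" reference rotates the unit so
that the breakpoint sits 2,120 bp upstream of the TSS (the midpoint of the
repetitive element nearest the 3' end), moving the sequence ends away from the
promoter. The 18S subunit itself occupies positions 3,658-5,526 of the unit
(GenBank KY962518.1 coordinates); its analogues in a standard assembly are found
by local similarity search and stored as a BED file for read counting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from ribocn.errors import CoordinateError, ParseError, ValidationError

_IUPAC = set("ACGTUWSMKRYBDHVNacgtuwsmkrybdhvn")

_COMPLEMENT = str.maketrans("ACGTUacgtuNnRYKMrykmWSwsBDHVbdhv",
                            "TGCAAtgcaaNnYRMKyrmkWSwsVHDBvhdb")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RdnaUnitSequence:
    """One rDNA repeat unit with its TSS position (1-based)."""

    id: str
    residues: str
    tss_offset: int = 1

    def __post_init__(self):
        if not self.residues:
            raise ValidationError("empty rDNA unit sequence")
        bad = set(self.residues) - _IUPAC
        if bad:
            raise ValidationError(f"non-IUPAC residues in unit {self.id!r}: {sorted(bad)}")
        if not 1 <= self.tss_offset <= len(self.residues):
            raise CoordinateError(
                f"tss_offset {self.tss_offset} outside unit of length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    source_coords: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.contig:
            raise ValidationError("empty contig name")
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"invalid interval {self.contig}:{self.start}-{self.end} (need end > start >= 0)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based_inclusive(cls, contig: str, start: int, end: int) -> "GenomicInterval":
        return cls(contig, start - 1, end, source_coords=(start, end))

    def to_1based_inclusive(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass
class AnalogueRegionSet:
    """Non-overlapping, sorted set of 18S-analogue intervals plus provenance."""

    intervals: list[GenomicInterval]
    query_length: int = 0
    provenance: str = ""

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other):
        if not isinstance(other, AnalogueRegionSet):
            return NotImplemented
        return [(i.contig, i.start, i.end) for i in self.intervals] == [
            (i.contig, i.start, i.end) for i in other.intervals
        ]

    def contigs(self) -> list[str]:
        return sorted({iv.contig for iv in self.intervals})

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per contig; return sorted by (contig, start)."""
    by_key = sorted(intervals, key=lambda iv: (iv.contig, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return merged


def extract_18s_query(unit: RdnaUnitSequence, start_1based: int, end_1based: int) -> str:
    """Extract an inclusive 1-based subsequence (default use: the 18S subunit, 3658-5526)."""
    if start_1based < 1:
        raise CoordinateError(f"start {start_1based} < 1")
    if end_1based > len(unit):
        raise CoordinateError(f"end {end_1based} beyond unit length {len(unit)}")
    if start_1based > end_1based:
        raise CoordinateError(f"start {start_1based} > end {end_1based}")
    return unit.residues[start_1based - 1 : end_1based]


def loop_rdna_reference(
    unit: RdnaUnitSequence, breakpoint_upstream_of_tss: int = 2120
) -> str:
    """Rotate the unit so the sequence ends fall at the breakpoint upstream of the TSS.

    For a TSS-initial unit the breakpoint lies ``breakpoint_upstream_of_tss`` bases
    before the sequence end; the tail from the breakpoint onward is prepended to
    the head. The result is a pure rotation: length and residue content preserved.
    """
    n = len(unit)
    if not 0 <= breakpoint_upstream_of_tss <= n:
        raise CoordinateError(
            f"breakpoint {breakpoint_upstream_of_tss} outside unit of length {n}"
        )
    # position of the breakpoint in 0-based coordinates, relative to the TSS
    bp = (unit.tss_offset - 1 - breakpoint_upstream_of_tss) % n
    s = unit.residues
    if unit.tss_offset != 1:
        # rotate to TSS-initial first so the contract matches the TSS-relative geometry
        s = s[unit.tss_offset - 1 :] + s[: unit.tss_offset - 1]
        bp = (n - breakpoint_upstream_of_tss) % n
    return s[bp:] + s[:bp]


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    upper = seq.upper()
    for i in range(len(upper) - k + 1):
        kmer = upper[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend_ungapped(
    query: str, subject: str, qpos: int, spos: int, k: int
) -> tuple[int, int, int, int]:
    """Extend an exact k-mer seed in both directions without gaps.

    Returns (q_start, s_start, length, matches) of the maximal extension that
    never lets the running identity drop below what trimming mismatched ends
    would give: we extend to the sequence bounds and then trim terminal
    mismatches (alignment ends on a match).
    """
    q, s = query.upper(), subject.upper()
    left = 0
    while qpos - left - 1 >= 0 and spos - left - 1 >= 0:
        left += 1
    right = 0
    while qpos + k + right < len(q) and spos + k + right < len(s):
        right += 1
    q0, s0 = qpos - left, spos - left
    length = left + k + right
    # trim mismatched termini
    while length > 0 and q[q0] != s[s0]:
        q0 += 1
        s0 += 1
        length -= 1
    while length > 0 and q[q0 + length - 1] != s[s0 + length - 1]:
        length -= 1
    matches = sum(1 for i in range(length) if q[q0 + i] == s[s0 + i])
    return q0, s0, length, matches


def find_analogue_regions(
    query: str,
    subjects: Mapping[str, str],
    min_identity: float = 0.90,
    min_length: int = 100,
    seed_k: int = 16,
) -> AnalogueRegionSet:
    """Locate ungapped local matches of ``query`` (either strand) in each subject.

    A self-contained seed-and-extend similarity search: exact ``seed_k``-mer hits
    are extended without gaps, and extensions with identity >= ``min_identity``
    over >= ``min_length`` aligned bases are reported as merged forward-strand
    intervals in subject coordinates, sorted by (contig, start). Designed for
    high-identity analogues such as the 18S pseudo-copies in a standard assembly.
    """
    if not query:
        raise ValidationError("empty query")
    if set(query.upper()) <= {"N"}:
        raise ValidationError("degenerate all-N query")
    if not 0 < min_identity <= 1:
        raise ValidationError(f"min_identity {min_identity} outside (0, 1]")
    if min_length < 1:
        raise ValidationError(f"min_length {min_length} < 1")
    if not subjects:
        warnings.warn("empty subject set: returning no analogue regions", stacklevel=2)
        return AnalogueRegionSet([], query_length=len(query), provenance="empty subject set")

    hits: list[GenomicInterval] = []
    for strand_query in (query, _revcomp(query)):
        qindex = _seed_index(strand_query, seed_k)
        for contig, subject in subjects.items():
            seen_diagonals: set[tuple[int, int, int]] = set()
            supper = subject.upper()
            for spos in range(len(supper) - seed_k + 1):
                kmer = supper[spos : spos + seed_k]
                qposs = qindex.get(kmer)
                if not qposs:
                    continue
                for qpos in qposs:
                    q0, s0, length, matches = _extend_ungapped(
                        strand_query, subject, qpos, spos, seed_k
                    )
                    diag_key = (spos - qpos, s0, length)
                    if diag_key in seen_diagonals:
                        continue
                    seen_diagonals.add(diag_key)
                    if length >= min_length and matches / length >= min_identity:
                        hits.append(GenomicInterval(contig, s0, s0 + length))
    return AnalogueRegionSet(
        hits,
        query_length=len(query),
        provenance=f"seed-and-extend k={seed_k}, min_identity={min_identity}, "
        f"min_length={min_length}",
    )


_BED_LINE = re.compile(r"^\S+\t\d+\t\d+")


def write_region_bed(regions: AnalogueRegionSet, destination: str | Path | TextIO) -> None:
    """Write regions as 3-column BED (0-based half-open, tab-separated, no header)."""
    lines = [f"{iv.contig}\t{iv.start}\t{iv.end}\n" for iv in regions]
    if hasattr(destination, "write"):
        destination.writelines(lines)
    else:
        Path(destination).write_text("".join(lines))


def read_region_bed(source: str | Path | TextIO) -> AnalogueRegionSet:
    """Parse a 3+-column BED into an AnalogueRegionSet; raises ParseError with line numbers."""
    if hasattr(source, "read"):
        text = source.read()
        name = "<stream>"
    else:
        text = Path(source).read_text()
        name = str(source)
    intervals = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"expected >= 3 tab-separated BED columns, got {len(fields)}", lineno)
        contig, start_s, end_s = fields[0], fields[1], fields[2]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno) from exc
        if end <= start or start < 0:
            raise ParseError(f"invalid BED interval {contig}:{start}-{end}", lineno)
        intervals.append(GenomicInterval(contig, start, end))
    return AnalogueRegionSet(intervals, provenance=f"read from {name}")
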