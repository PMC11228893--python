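"""Relative-pair classification, family clustering, and unrelated-subset selection.

KING kinship coefficients fall into fixed bands by relationship degree:
monozygotic twins above 0.4, first degree 0.177-0.354, second degree down to
2^-3.5 (~0.0884), third degree down to 0.0442. First-degree pairs split into
parental vs fraternal by IBS0 (parent-offspring pairs share at least one allele
at essentially every marker, so IBS0 ~ 0), guarded by a 10-year minimum
birth-year gap. Families are the connected components of the pair graph; the
unrelated subset keeps everyone without a pair record plus the oldest member of
each family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ribocn.errors import ValidationError


class RelationshipCategory(str, Enum):
    MZ = "MZ"
    FIRST = "FIRST"
    SECOND = "SECOND"
    THIRD = "THIRD"
    UNRELATED = "UNRELATED"


class FirstDegreeSubtype(str, Enum):
    PARENTAL = "PARENTAL"
    FRATERNAL = "FRATERNAL"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class KinshipThresholds:
    """Band edges for degree classification.

    Lower bounds are inclusive and upper bounds exclusive, except the MZ cut
    which is strictly greater-than. ``boundary_23`` separates second from third
    degree; the canonical KING value is 2^-3.5 ~ 0.0884.
    """

    mz: float = 0.4
    first_low: float = 0.177
    first_high: float = 0.354
    boundary_23: float = 0.0884
    third_low: float = 0.0442


@dataclass(frozen=True)
class KinshipPair:
    id1: str
    id2: str
    kinship: float
    ibs0: float = math.nan
    birth_year1: int | None = None
    birth_year2: int | None = None

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValidationError(f"self-pair {self.id1!r}")
        if not math.isfinite(self.kinship):
            raise ValidationError(f"non-finite kinship for pair {self.id1}/{self.id2}")


@dataclass
class FamilyAssignment:
    """Partition of individuals into families (connected components of the pair graph)."""

    member_to_family: dict[str, int]
    families: dict[int, list[str]]

    def __len__(self) -> int:
        return len(self.families)


def classify_relationship(
    pair: KinshipPair, thresholds: KinshipThresholds = KinshipThresholds()
) -> RelationshipCategory:
    """Map a kinship coefficient to its relationship degree band."""
    k = pair.kinship
    t = thresholds
    if k > t.mz:
        return RelationshipCategory.MZ
    if t.first_low <= k <= t.first_high:
        return RelationshipCategory.FIRST
    if t.boundary_23 <= k < t.first_low:
        return RelationshipCategory.SECOND
    if t.third_low <= k < t.boundary_23:
        return RelationshipCategory.THIRD
    return RelationshipCategory.UNRELATED


def classify_first_degree(
    pair: KinshipPair,
    ibs0_threshold: float = 0.0012,
    min_gap_years: int = 10,
) -> FirstDegreeSubtype:
    """Split a first-degree pair into parental vs fraternal via IBS0.

    IBS0 below threshold indicates parent-offspring, but a birth gap under
    ``min_gap_years`` is biologically implausible for that label, so such pairs
    are discarded; so are putatively parental pairs whose birth years are
    unknown (unverifiable gap).
    """
    if math.isnan(pair.ibs0):
        raise ValidationError(f"pair {pair.id1}/{pair.id2} has no IBS0 value")
    if pair.ibs0 >= ibs0_threshold:
        return FirstDegreeSubtype.FRATERNAL
    if pair.birth_year1 is None or pair.birth_year2 is None:
        return FirstDegreeSubtype.DISCARDED
    if abs(pair.birth_year1 - pair.birth_year2) < min_gap_years:
        return FirstDegreeSubtype.DISCARDED
    return FirstDegreeSubtype.PARENTAL


def build_families(pairs: Iterable[KinshipPair | tuple[str, str]]) -> FamilyAssignment:
    """Cluster individuals into families as connected components of the pair graph.

    Family ids are assigned in order of the smallest member id of each
    component, making labels deterministic across runs.
    """
    g = nx.Graph()
    for pair in pairs:
        if isinstance(pair, KinshipPair):
            g.add_edge(pair.id1, pair.id2)
        else:
            g.add_edge(pair[0], pair[1])
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    member_to_family: dict[str, int] = {}
    families: dict[int, list[str]] = {}
    for fid, comp in enumerate(components, start=1):
        members = sorted(comp)
        families[fid] = members
        for m in members:
            member_to_family[m] = fid
    return FamilyAssignment(member_to_family, families)


def select_unrelated(
    birth_years: Mapping[str, int | None],
    assignment: FamilyAssignment,
) -> set[str]:
    """Unrelated subset: all singletons plus the oldest member of each family.

    ``birth_years`` lists every candidate individual (value None if unknown).
    Oldest = smallest birth year; ties and all-missing families resolve to the
    lexicographically smallest id (all-missing choices are reported via warning).
    """
    selected = {i for i in birth_years if i not in assignment.member_to_family}
    for fid, members in assignment.families.items():
        known = [(birth_years.get(m), m) for m in members if birth_years.get(m) is not None]
        if known:
            _, chosen = min(known)
        else:
            chosen = min(members)
            warnings.warn(
                f"family {fid}: all birth years missing; kept {chosen!r} by id order",
                stacklevel=2,
            )
        selected.add(chosen)
    return selected


def read_kinship_tsv(path) -> list[KinshipPair]:
    """Read a KING-style kinship TSV (columns ID1, ID2, Kinship, IBS0[, BirthYear1, BirthYear2])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"ID1": str, "ID2": str}, comment="#")
    required = {"ID1", "ID2", "Kinship"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"kinship table missing column(s): {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            KinshipPair(
                id1=row.ID1,
                id2=row.ID2,
                kinship=float(row.Kinship),
                ibs0=float(getattr(row, "IBS0", math.nan)),
                birth_year1=_opt_int(getattr(row, "BirthYear1", None)),
                birth_year2=_opt_int(getattr(row, "BirthYear2", None)),
            )
        )
    return pairs


def _opt_int(v) -> int | None:
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else int(f)
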