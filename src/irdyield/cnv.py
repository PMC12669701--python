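"""Read-count-ratio filtering of exome CNV candidates.

Downstream of a read-depth CNV caller, each candidate deletion or
duplication carries a read-count ratio (RR = observed / expected reads over
the region).  Deletions with RR between 0.3 and 0.7 (inclusive) are called
heterozygous and those with RR below 0.1 homozygous/hemizygous;
duplications are retained only when RR exceeds 1.3.  Deletions falling in
the unclaimed RR windows [0.1, 0.3) and (0.7, inf) are surfaced as
*ambiguous* for manual plot review rather than silently dropped.

Coordinates are 1-based inclusive; gene overlap is any-base overlap and is
taken as given on the call record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import InvalidInputError

__all__ = ["CnvKind", "CnvClass", "CnvCall", "CnvThresholds", "classify_cnv",
           "filter_to_panel"]


class CnvKind(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class CnvClass(str, Enum):
    HET_DELETION = "het_deletion"
    HOM_OR_HEMI_DELETION = "hom_or_hemi_deletion"
    RETAINED_DUPLICATION = "retained_duplication"
    REJECTED = "rejected"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CnvCall:
    proband_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: CnvKind
    read_ratio: float
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        try:
            kind = CnvKind(self.kind)
        except ValueError as exc:
            raise InvalidInputError(f"unknown CNV kind {self.kind!r}") from exc
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.read_ratio < 0:
            raise InvalidInputError("read_ratio must be non-negative")
        if self.start > self.end:
            raise InvalidInputError("start must not exceed end")


@dataclass(frozen=True)
class CnvThresholds:
    """RR boundaries; endpoint conventions follow the filtering rules
    (het window closed on both sides, hom strictly below ``hom_max``,
    duplications strictly above ``dup_min``)."""

    hom_max: float = 0.1
    het_low: float = 0.3
    het_high: float = 0.7
    dup_min: float = 1.3


_DEFAULT = CnvThresholds()


def classify_cnv(call: CnvCall, thresholds: CnvThresholds = _DEFAULT) -> CnvClass:
    """Dosage classification of one CNV candidate from its read ratio."""
    rr = call.read_ratio
    if call.kind == CnvKind.DUPLICATION:
        return (CnvClass.RETAINED_DUPLICATION if rr > thresholds.dup_min
                else CnvClass.REJECTED)
    if rr < thresholds.hom_max:
        return CnvClass.HOM_OR_HEMI_DELETION
    if thresholds.het_low <= rr <= thresholds.het_high:
        return CnvClass.HET_DELETION
    return CnvClass.AMBIGUOUS


def filter_to_panel(
    calls: Iterable[CnvCall], panel: Sequence[str] | frozenset[str]
) -> list[CnvCall]:
    """Retain calls overlapping at least one panel gene, order preserved."""
    panel = frozenset(panel)
    return [c for c in calls if c.genes & panel]
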