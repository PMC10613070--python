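"""Core in-memory model of rearranged TRB repertoires.

A *rearrangement record* is one unique rearranged TRB nucleotide sequence
observed in a sample, together with the number of copies (templates/reads)
sequenced, the V/D/J gene calls, the reading-frame status of the CDR3, and
optional 0-based indices of the CDR3 and of the non-templated N2 region.
A *repertoire* is the collection of records from one sample plus the donor
metadata (age in years, sex, cell compartment, CD4/CD8 blood ratio) used by
the downstream models.

Copy counts, not unique sequences, are the unit of observation throughout:
every diversity denominator N is a copy total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

UNRESOLVED = "unresolved"


class FrameStatus(str, enum.Enum):
    """Reading-frame status of the CDR3 junction."""

    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    STOP_CODON = "stop_codon"
    UNKNOWN = "unknown"


class Compartment(str, enum.Enum):
    WHOLE_BLOOD = "whole_blood"
    CD4 = "CD4"
    CD8 = "CD8"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class RearrangementRecord:
    """One unique rearranged TRB nucleotide sequence in a sample.

    ``copy_count`` is the number of sequenced copies (>= 1).  ``v_call`` and
    ``j_call`` may hold the sentinel :data:`UNRESOLVED`; ``d_call`` may be
    empty.  ``cdr3_start`` and ``n2_start`` are 0-based indices into
    ``nucleotide`` or ``None`` when the annotation is absent.
    """

    nucleotide: str
    copy_count: int
    v_call: str = UNRESOLVED
    d_call: str = ""
    j_call: str = UNRESOLVED
    frame_status: FrameStatus = FrameStatus.UNKNOWN
    cdr3_start: Optional[int] = None
    n2_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError(f"copy_count must be >= 1, got {self.copy_count}")
        for name in ("cdr3_start", "n2_start"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx <= len(self.nucleotide)):
                raise ValueError(
                    f"{name}={idx} outside sequence of length {len(self.nucleotide)}"
                )

    @property
    def is_productive(self) -> bool:
        return self.frame_status is FrameStatus.IN_FRAME


@dataclass
class Repertoire:
    """One sample's rearrangement records plus donor metadata."""

    sample_id: str
    records: list[RearrangementRecord] = field(default_factory=list)
    donor_id: str = ""
    age: Optional[int] = None
    sex: Optional[Sex] = None
    compartment: Compartment = Compartment.WHOLE_BLOOD
    timepoint: Optional[int] = None
    cd4_cd8_ratio: Optional[float] = None

    @property
    def total_copies(self) -> int:
        return sum(r.copy_count for r in self.records)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def copy_counts(self) -> np.ndarray:
        return np.fromiter(
            (r.copy_count for r in self.records), dtype=np.int64, count=len(self.records)
        )

    def with_records(self, records: Iterable[RearrangementRecord]) -> "Repertoire":
        """Metadata-preserving copy holding ``records``."""
        new = replace_metadata(self)
        new.records = list(records)
        return new

    def has_metadata(self) -> bool:
        """True when both age and sex are known (the sample-level filter)."""
        return self.age is not None and self.sex is not None


def replace_metadata(rep: Repertoire) -> Repertoire:
    return Repertoire(
        sample_id=rep.sample_id,
        records=[],
        donor_id=rep.donor_id,
        age=rep.age,
        sex=rep.sex,
        compartment=rep.compartment,
        timepoint=rep.timepoint,
        cd4_cd8_ratio=rep.cd4_cd8_ratio,
    )


def collapse_clones(rep: Repertoire) -> Repertoire:
    """Merge records sharing an identical nucleotide sequence, summing copies.

    A clone is a set of sequence copies with the same rearranged TRB
    nucleotide sequence; collapsing is performed after curation so that the
    copy totals feeding the diversity estimators count clones once each.
    Annotations are taken from the first record of each clone (identical
    nucleotide sequences carry identical annotations in practice).
    """
    merged: dict[str, RearrangementRecord] = {}
    order: list[str] = []
    for rec in rep.records:
        prev = merged.get(rec.nucleotide)
        if prev is None:
            merged[rec.nucleotide] = rec
            order.append(rec.nucleotide)
        else:
            merged[rec.nucleotide] = replace(
                prev, copy_count=prev.copy_count + rec.copy_count
            )
    return rep.with_records(merged[nt] for nt in order)
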