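"""Sample- and sequence-level curation of TRB repertoires.

Curation proceeds in two tiers.  Sample level: repertoires lacking donor
age or sex are dropped, and samples whose total copy count is extreme for
the cohort are screened out (see :mod:`trbdyn.outliers`).  Sequence level:
each record is tested, in a fixed order, against six removal rules —

1. orphon V gene call,
2. unresolved V call,
3. unresolved J call,
4. indexing error (annotated N2 region starting before the CDR3 start),
5. V or J gene outside the functional reference set (non-functional/ORF),
6. V gene on the exclusion list (TRBV03-01).

A record is attributed to the first rule it violates, so the per-rule
removal counts in the :class:`CurationReport` sum, together with the
retained total, exactly to the input copy count.  After curation, records
with identical nucleotide sequences are collapsed into clones, and each
record is classified as productive (open CDR3 reading frame) or
non-productive (frameshifted or containing a stop codon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .genes import GeneReference, default_reference
from .outliers import DEFAULT_ALPHA, detect_outlier_samples
from .repertoire import (
    FrameStatus,
    RearrangementRecord,
    Repertoire,
    UNRESOLVED,
    collapse_clones,
)

#: sequence-level filter categories, in attribution order
SEQUENCE_FILTERS = (
    "orphon_v",
    "unresolved_v",
    "unresolved_j",
    "indexing_error",
    "nonfunctional_or_orf_gene",
    "excluded_gene",
)

SAMPLE_FILTERS = ("missing_metadata", "outlier_sample")


@dataclass
class CurationReport:
    """Per-filter accounting of removed copies and unique sequences.

    Invariant: ``input_copies == retained_copies + sum(removed_copies)``.
    """

    input_copies: int = 0
    input_sequences: int = 0
    removed_copies: dict[str, int] = field(default_factory=dict)
    removed_sequences: dict[str, int] = field(default_factory=dict)
    retained_copies: int = 0
    retained_sequences: int = 0
    empty_after_curation: bool = False

    def __post_init__(self) -> None:
        for cat in SAMPLE_FILTERS + SEQUENCE_FILTERS:
            self.removed_copies.setdefault(cat, 0)
            self.removed_sequences.setdefault(cat, 0)

    @property
    def conserved(self) -> bool:
        return self.input_copies == self.retained_copies + sum(
            self.removed_copies.values()
        )

    def merge(self, other: "CurationReport") -> None:
        self.input_copies += other.input_copies
        self.input_sequences += other.input_sequences
        self.retained_copies += other.retained_copies
        self.retained_sequences += other.retained_sequences
        for cat in self.removed_copies:
            self.removed_copies[cat] += other.removed_copies.get(cat, 0)
            self.removed_sequences[cat] += other.removed_sequences.get(cat, 0)

    def to_dict(self) -> dict:
        return {
            "input": {"copies": self.input_copies, "sequences": self.input_sequences},
            "removed_copies": dict(self.removed_copies),
            "removed_sequences": dict(self.removed_sequences),
            "retained": {
                "copies": self.retained_copies,
                "sequences": self.retained_sequences,
            },
            "empty_after_curation": self.empty_after_curation,
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self):
        """Table-shaped view: one row per filter with copy/sequence counts."""
        import pandas as pd

        rows = [
            {
                "filter": cat,
                "removed_copies": self.removed_copies[cat],
                "removed_sequences": self.removed_sequences[cat],
                "fraction_of_input": (
                    self.removed_copies[cat] / self.input_copies
                    if self.input_copies
                    else 0.0
                ),
            }
            for cat in SAMPLE_FILTERS + SEQUENCE_FILTERS
        ]
        rows.append(
            {
                "filter": "retained",
                "removed_copies": self.retained_copies,
                "removed_sequences": self.retained_sequences,
                "fraction_of_input": (
                    self.retained_copies / self.input_copies if self.input_copies else 0.0
                ),
            }
        )
        return pd.DataFrame(rows)


def filter_metadata(cohort: list[Repertoire]) -> tuple[list[Repertoire], list[Repertoire]]:
    """Split a cohort into samples with and without age+sex metadata."""
    if not cohort:
        raise ValueError("cohort is empty")
    kept = [rep for rep in cohort if rep.has_metadata()]
    dropped = [rep for rep in cohort if not rep.has_metadata()]
    return kept, dropped


def classify_functionality(rec: RearrangementRecord) -> str:
    """``productive`` for an open CDR3 reading frame, else ``nonproductive``.

    Out-of-frame junctions and in-frame junctions interrupted by a stop
    codon both close the reading frame and are non-productive.
    """
    if rec.frame_status is FrameStatus.UNKNOWN:
        raise ValueError(
            "frame_status is unknown; record should have been annotated or filtered upstream"
        )
    return "productive" if rec.frame_status is FrameStatus.IN_FRAME else "nonproductive"


def _violation(rec: RearrangementRecord, ref: GeneReference) -> Optional[str]:
    """First curation rule violated by ``rec``, or None."""
    if ref.is_orphon_v(rec.v_call):
        return "orphon_v"
    if rec.v_call == UNRESOLVED:
        return "unresolved_v"
    if rec.j_call == UNRESOLVED:
        return "unresolved_j"
    if (
        rec.n2_start is not None
        and rec.cdr3_start is not None
        and rec.n2_start < rec.cdr3_start
    ):
        return "indexing_error"
    if not ref.is_functional_v(rec.v_call) or not ref.is_functional_j(rec.j_call):
        return "nonfunctional_or_orf_gene"
    if ref.is_excluded(rec.v_call):
        return "excluded_gene"
    return None


def curate_records(
    rep: Repertoire, ref: Optional[GeneReference] = None
) -> tuple[Repertoire, CurationReport]:
    """Apply the six sequence-level filters to one repertoire.

    Idempotent: curating an already-curated repertoire removes nothing.
    An empty post-curation repertoire is flagged in the report rather than
    raised, so cohort-level runs can continue and report it.
    """
    if ref is None:
        ref = default_reference()
    report = CurationReport(
        input_copies=rep.total_copies, input_sequences=rep.n_records
    )
    kept: list[RearrangementRecord] = []
    for rec in rep.records:
        rule = _violation(rec, ref)
        if rule is None:
            kept.append(rec)
        else:
            report.removed_copies[rule] += rec.copy_count
            report.removed_sequences[rule] += 1
    report.retained_copies = sum(r.copy_count for r in kept)
    report.retained_sequences = len(kept)
    report.empty_after_curation = not kept
    return rep.with_records(kept), report


def curate_cohort(
    cohort: list[Repertoire],
    ref: Optional[GeneReference] = None,
    outlier_alpha: Optional[float] = DEFAULT_ALPHA,
    collapse: bool = True,
) -> tuple[list[Repertoire], CurationReport]:
    """Full curation of a cohort: metadata filter, outlier screen, sequence
    filters, clone collapsing.  Returns curated repertoires and a pooled
    report.  ``outlier_alpha=None`` (or a cohort smaller than the fence
    minimum) skips the outlier screen.
    """
    report = CurationReport()
    kept, dropped = filter_metadata(cohort)
    for rep in dropped:
        report.removed_copies["missing_metadata"] += rep.total_copies
        report.removed_sequences["missing_metadata"] += rep.n_records
    report.input_copies = sum(r.total_copies for r in cohort)
    report.input_sequences = sum(r.n_records for r in cohort)

    if outlier_alpha is not None and len(kept) >= 8:
        totals = [rep.total_copies for rep in kept]
        flags = detect_outlier_samples(totals, alpha=outlier_alpha)
        screened = []
        for rep, flag in zip(kept, flags):
            if flag:
                report.removed_copies["outlier_sample"] += rep.total_copies
                report.removed_sequences["outlier_sample"] += rep.n_records
            else:
                screened.append(rep)
        kept = screened

    curated: list[Repertoire] = []
    for rep in kept:
        cur, sample_report = curate_records(rep, ref)
        for cat in SEQUENCE_FILTERS:
            report.removed_copies[cat] += sample_report.removed_copies[cat]
            report.removed_sequences[cat] += sample_report.removed_sequences[cat]
        if collapse:
            cur = collapse_clones(cur)
        curated.append(cur)
    report.retained_copies = sum(r.total_copies for r in curated)
    report.retained_sequences = sum(r.n_records for r in curated)
    return curated, report
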