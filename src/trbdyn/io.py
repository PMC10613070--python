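"""Reading and writing rearrangement tables and cohort manifests.

Two tab-separated dialects are supported:

``immunoseq``
    The vendor export style: columns like ``nucleotide``,
    ``count (templates/reads)``, ``vGeneName``, ``sequenceStatus``
    (``In``/``Out``/``Stop``), ``cdr3Index``, ``n2Index``.  Index columns
    are taken as 0-based.

``airr``
    The AIRR Rearrangement standard: ``sequence``, ``duplicate_count``,
    ``v_call``/``d_call``/``j_call``, boolean ``productive`` and
    ``stop_codon``, with 1-based ``cdr3_start`` converted to the package's
    0-based convention on read.

Column names vary across export versions, so every role can be remapped
through ``column_map``.  Rows are read one record per row; collapsing of
identical nucleotide sequences is deliberately left to curation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .genes import normalize_gene_name
from .repertoire import (
    Compartment,
    FrameStatus,
    RearrangementRecord,
    Repertoire,
    Sex,
)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class RowError(ValueError):
    """A row could not be parsed; the message carries the line number."""


#: mapping from schema roles to column names, per dialect
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "immunoseq": {
        "nucleotide": "nucleotide",
        "copy_count": "count (templates/reads)",
        "v_call": "vGeneName",
        "d_call": "dGeneName",
        "j_call": "jGeneName",
        "frame": "sequenceStatus",
        "cdr3_start": "cdr3Index",
        "n2_start": "n2Index",
    },
    "airr": {
        "nucleotide": "sequence",
        "copy_count": "duplicate_count",
        "v_call": "v_call",
        "d_call": "d_call",
        "j_call": "j_call",
        "productive": "productive",
        "stop_codon": "stop_codon",
        "cdr3_start": "cdr3_start",
        "n2_start": "n2_start",
    },
}

_IMMUNOSEQ_FRAME = {
    "in": FrameStatus.IN_FRAME,
    "out": FrameStatus.OUT_OF_FRAME,
    "stop": FrameStatus.STOP_CODON,
}

_REQUIRED_ROLES = ("nucleotide", "copy_count")


def _parse_bool(value: object) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text in {"t", "true", "1", "yes"}:
        return True
    if text in {"f", "false", "0", "no"}:
        return False
    return None


def _frame_from_airr(productive: object, stop: object) -> FrameStatus:
    prod = _parse_bool(productive)
    stop_b = _parse_bool(stop)
    if stop_b:
        return FrameStatus.STOP_CODON
    if prod is True:
        return FrameStatus.IN_FRAME
    if prod is False:
        return FrameStatus.OUT_OF_FRAME
    return FrameStatus.UNKNOWN


def _frame_from_immunoseq(value: object) -> FrameStatus:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return FrameStatus.UNKNOWN
    return _IMMUNOSEQ_FRAME.get(str(value).strip().lower(), FrameStatus.UNKNOWN)


def _optional_index(value: object) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    idx = int(float(value))
    return None if idx < 0 else idx


def read_repertoire(
    path: Path | str,
    dialect: str = "immunoseq",
    column_map: Optional[dict[str, str]] = None,
    sample_id: Optional[str] = None,
    index_base: Optional[int] = None,
    **metadata,
) -> Repertoire:
    """Read a tab-separated rearrangement table into a :class:`Repertoire`.

    Parameters
    ----------
    dialect
        ``"immunoseq"`` or ``"airr"``.
    column_map
        Overrides for individual roles of :data:`DEFAULT_COLUMN_MAPS`.
    index_base
        Base of the CDR3/N2 index columns in the file (default: 0 for
        immunoSEQ, 1 for AIRR).  The in-memory convention is always 0-based.
    metadata
        Donor metadata forwarded to the :class:`Repertoire` constructor
        (``donor_id``, ``age``, ``sex``, ``compartment``, ...).
    """
    if dialect not in DEFAULT_COLUMN_MAPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cmap = dict(DEFAULT_COLUMN_MAPS[dialect])
    if column_map:
        cmap.update(column_map)
    if index_base is None:
        index_base = 1 if dialect == "airr" else 0

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for role in _REQUIRED_ROLES:
        if cmap[role] not in table.columns:
            raise SchemaError(
                f"missing mapped column {cmap[role]!r} for role {role!r} in {path}"
            )
    if len(table) == 0:
        raise SchemaError(f"empty repertoire: {path} has a header but no rows")

    def col(role: str) -> Optional[pd.Series]:
        name = cmap.get(role)
        return table[name] if name is not None and name in table.columns else None

    nts = table[cmap["nucleotide"]]
    counts_raw = table[cmap["copy_count"]]
    v = col("v_call")
    d = col("d_call")
    j = col("j_call")
    cdr3 = col("cdr3_start")
    n2 = col("n2_start")
    frame = col("frame")
    productive = col("productive")
    stop = col("stop_codon")

    records: list[RearrangementRecord] = []
    for i in range(len(table)):
        line_no = i + 2  # header is line 1
        try:
            count = int(float(counts_raw.iloc[i]))
        except (TypeError, ValueError):
            raise RowError(
                f"non-numeric copy count {counts_raw.iloc[i]!r} at line {line_no} of {path}"
            ) from None
        if dialect == "airr":
            status = _frame_from_airr(
                productive.iloc[i] if productive is not None else None,
                stop.iloc[i] if stop is not None else None,
            )
        else:
            status = _frame_from_immunoseq(frame.iloc[i] if frame is not None else None)

        def idx(series: Optional[pd.Series]) -> Optional[int]:
            if series is None:
                return None
            raw = _optional_index(series.iloc[i])
            return None if raw is None else raw - index_base

        records.append(
            RearrangementRecord(
                nucleotide=str(nts.iloc[i]).strip().upper(),
                copy_count=count,
                v_call=normalize_gene_name(v.iloc[i] if v is not None else None),
                d_call=(
                    ""
                    if d is None or str(d.iloc[i]).strip() == ""
                    else normalize_gene_name(d.iloc[i])
                ),
                j_call=normalize_gene_name(j.iloc[i] if j is not None else None),
                frame_status=status,
                cdr3_start=idx(cdr3),
                n2_start=idx(n2),
            )
        )

    sid = sample_id if sample_id is not None else Path(path).stem
    return Repertoire(sample_id=sid, records=records, **metadata)


def write_repertoire(
    rep: Repertoire,
    path: Path | str,
    dialect: str = "immunoseq",
    sidecar: bool = False,
) -> None:
    """Write a repertoire as a tab-separated table in the given dialect.

    Round-trip stable: ``read_repertoire(write_repertoire(rep))`` reproduces
    records, counts and (via the JSON sidecar) metadata exactly.
    """
    if dialect not in DEFAULT_COLUMN_MAPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not rep.records:
        raise ValueError(f"refusing to write empty repertoire {rep.sample_id!r}")
    cmap = DEFAULT_COLUMN_MAPS[dialect]
    rows = []
    for rec in rep.records:
        if dialect == "airr":
            row = {
                cmap["nucleotide"]: rec.nucleotide,
                cmap["copy_count"]: rec.copy_count,
                cmap["v_call"]: rec.v_call,
                cmap["d_call"]: rec.d_call,
                cmap["j_call"]: rec.j_call,
                cmap["productive"]: "T" if rec.frame_status is FrameStatus.IN_FRAME else "F",
                cmap["stop_codon"]: "T" if rec.frame_status is FrameStatus.STOP_CODON else "F",
                cmap["cdr3_start"]: "" if rec.cdr3_start is None else rec.cdr3_start + 1,
                cmap["n2_start"]: "" if rec.n2_start is None else rec.n2_start + 1,
            }
        else:
            frame_txt = {
                FrameStatus.IN_FRAME: "In",
                FrameStatus.OUT_OF_FRAME: "Out",
                FrameStatus.STOP_CODON: "Stop",
                FrameStatus.UNKNOWN: "",
            }[rec.frame_status]
            row = {
                cmap["nucleotide"]: rec.nucleotide,
                cmap["copy_count"]: rec.copy_count,
                cmap["v_call"]: rec.v_call,
                cmap["d_call"]: rec.d_call,
                cmap["j_call"]: rec.j_call,
                cmap["frame"]: frame_txt,
                cmap["cdr3_start"]: "" if rec.cdr3_start is None else rec.cdr3_start,
                cmap["n2_start"]: "" if rec.n2_start is None else rec.n2_start,
            }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "sample_id": rep.sample_id,
            "donor_id": rep.donor_id,
            "age": rep.age,
            "sex": rep.sex.value if rep.sex else None,
            "compartment": rep.compartment.value,
            "timepoint": rep.timepoint,
            "cd4_cd8_ratio": rep.cd4_cd8_ratio,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


@dataclass
class ManifestRow:
    sample_id: str
    path: str
    donor_id: str = ""
    age: Optional[int] = None
    sex: Optional[Sex] = None
    compartment: Compartment = Compartment.WHOLE_BLOOD
    cd4_cd8_ratio: Optional[float] = None
    timepoint: Optional[int] = None
    dialect: str = "immunoseq"


@dataclass
class CohortManifest:
    """One row per sample: file location plus donor covariates."""

    rows: list[ManifestRow] = field(default_factory=list)
    root: Path = Path(".")

    def __len__(self) -> int:
        return len(self.rows)

    def load_repertoires(self) -> list[Repertoire]:
        reps = []
        for row in self.rows:
            rep = read_repertoire(
                self.root / row.path,
                dialect=row.dialect,
                sample_id=row.sample_id,
                donor_id=row.donor_id,
                age=row.age,
                sex=row.sex,
                compartment=row.compartment,
                timepoint=row.timepoint,
                cd4_cd8_ratio=row.cd4_cd8_ratio,
            )
            reps.append(rep)
        return reps


_SEX_ALIASES = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "man": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "woman": Sex.FEMALE,
}

_COMPARTMENT_ALIASES = {
    "whole_blood": Compartment.WHOLE_BLOOD,
    "wholeblood": Compartment.WHOLE_BLOOD,
    "wb": Compartment.WHOLE_BLOOD,
    "blood": Compartment.WHOLE_BLOOD,
    "cd4": Compartment.CD4,
    "cd8": Compartment.CD8,
}


def read_manifest(path: Path | str, check_paths: bool = True) -> CohortManifest:
    """Read a cohort manifest TSV.

    Required columns: ``sample_id``, ``path``.  Optional: ``donor_id``,
    ``age``, ``sex``, ``compartment``, ``cd4_cd8_ratio``, ``timepoint``,
    ``dialect``.  Missing age/sex are stored as absent (never imputed) so
    that the metadata filter can drop those samples explicitly.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("sample_id", "path"):
        if required not in table.columns:
            raise SchemaError(f"manifest {path} lacks required column {required!r}")
    if table["sample_id"].duplicated().any():
        dupes = sorted(table.loc[table["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id in manifest: {dupes}")

    root = Path(path).parent
    rows: list[ManifestRow] = []
    for _, rec in table.iterrows():
        def get(name: str) -> str:
            return str(rec[name]).strip() if name in table.columns else ""

        age_txt = get("age")
        sex_txt = get("sex").lower()
        ratio_txt = get("cd4_cd8_ratio")
        tp_txt = get("timepoint")
        comp_txt = get("compartment").lower()
        rows.append(
            ManifestRow(
                sample_id=get("sample_id"),
                path=get("path"),
                donor_id=get("donor_id"),
                age=int(float(age_txt)) if age_txt else None,
                sex=_SEX_ALIASES.get(sex_txt),
                compartment=_COMPARTMENT_ALIASES.get(comp_txt, Compartment.WHOLE_BLOOD),
                cd4_cd8_ratio=float(ratio_txt) if ratio_txt else None,
                timepoint=int(float(tp_txt)) if tp_txt else None,
                dialect=get("dialect") or "immunoseq",
            )
        )
    manifest = CohortManifest(rows=rows, root=root)
    if check_paths:
        missing = [r.path for r in rows if not (root / r.path).exists()]
        if missing:
            raise FileNotFoundError(
                f"manifest {path} references missing files: {missing[:5]}"
            )
    return manifest


def write_manifest(manifest: CohortManifest, path: Path | str) -> None:
    rows = []
    for r in manifest.rows:
        rows.append(
            {
                "sample_id": r.sample_id,
                "path": r.path,
                "donor_id": r.donor_id,
                "age": "" if r.age is None else r.age,
                "sex": "" if r.sex is None else r.sex.value,
                "compartment": r.compartment.value,
                "cd4_cd8_ratio": "" if r.cd4_cd8_ratio is None else r.cd4_cd8_ratio,
                "timepoint": "" if r.timepoint is None else r.timepoint,
                "dialect": r.dialect,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
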