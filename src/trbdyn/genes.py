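"""TRB gene-name normalization and the functional-gene reference.

Gene calls arrive in several vendor spellings (``TCRBV03-01*01``,
``TRBV3-1``, ``TRBV07.3`` ...).  Matching against the reference set is done
on a canonical form: locus prefix ``TRB``, two-digit family and gene
numbers, allele suffix stripped for matching but preserved on the record.

The bundled reference (``data/trb_gene_reference_synthetic.json``) is a
constructed, IMGT-style functionality snapshot — see its docstring field —
sized to the curated study set: 42 functional V genes once the excluded
TRBV03-01 is removed, 13 functional J genes and 2 D genes.  Users may load
their own snapshot with :meth:`GeneReference.from_json`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .repertoire import UNRESOLVED

_GENE_RE = re.compile(
    r"^(?:TCR|TR)B(?P<seg>[VDJ])(?P<family>\d+)(?:[-.](?P<gene>\d+))?(?P<orphon>/OR[\w.-]*)?$"
)

_UNRESOLVED_TOKENS = {"", "unresolved", "na", "nan", "none", "unknown", "(undefined)"}


def normalize_gene_name(name: object) -> str:
    """Canonicalize a TRB gene call; unknown/empty calls map to ``unresolved``.

    The allele suffix (``*01``) is stripped; family and gene numbers are
    zero-padded to two digits; single-gene families gain an explicit ``-01``;
    orphon suffixes (``/OR9-2``) are preserved.  Strings that do not look
    like a TRB gene at all are returned trimmed/upper-cased so that they can
    still be counted (they will fail the functional-set membership test).
    """
    if name is None:
        return UNRESOLVED
    text = str(name).strip()
    if text.lower() in _UNRESOLVED_TOKENS:
        return UNRESOLVED
    text = text.upper()
    # drop allele suffix for matching
    text = text.split("*", 1)[0]
    m = _GENE_RE.match(text)
    if m is None:
        return text
    family = int(m.group("family"))
    gene = int(m.group("gene")) if m.group("gene") else 1
    orphon = m.group("orphon") or ""
    return f"TRB{m.group('seg')}{family:02d}-{gene:02d}{orphon}"


def is_orphon(name: str) -> bool:
    """Orphon V segments carry an ``/OR`` locus suffix."""
    return "/OR" in name


@dataclass
class GeneReference:
    """Functionality reference for TRB V/D/J gene segments.

    ``excluded`` lists genes removed from analysis regardless of their
    functionality class (the study excluded TRBV03-01 for extreme rarity);
    exclusion wins over functional-set membership.
    """

    functional_v: frozenset[str]
    functional_j: frozenset[str]
    functional_d: frozenset[str]
    orphon_v: frozenset[str] = frozenset()
    excluded: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.functional_v or not self.functional_j:
            raise ValueError("functional V and J sets must be non-empty")

    def is_functional_v(self, name: str) -> bool:
        return name in self.functional_v

    def is_functional_j(self, name: str) -> bool:
        return name in self.functional_j

    def is_orphon_v(self, name: str) -> bool:
        return name in self.orphon_v or is_orphon(name)

    def is_excluded(self, name: str) -> bool:
        return name in self.excluded

    @property
    def final_v_count(self) -> int:
        """Number of functional V genes after exclusions."""
        return len(self.functional_v - self.excluded)

    @classmethod
    def from_json(cls, path: Path | str) -> "GeneReference":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload, name=str(path))

    @classmethod
    def _from_payload(cls, payload: dict, name: str = "") -> "GeneReference":
        def norm(names: list[str]) -> frozenset[str]:
            return frozenset(normalize_gene_name(n) for n in names)

        return cls(
            functional_v=norm(payload["functional_v"]),
            functional_j=norm(payload["functional_j"]),
            functional_d=norm(payload["functional_d"]),
            orphon_v=norm(payload.get("orphon_v", [])),
            excluded=norm(payload.get("excluded", [])),
            name=payload.get("name", name),
        )


_default_reference: Optional[GeneReference] = None


def default_reference() -> GeneReference:
    """The bundled synthetic IMGT-style snapshot (cached)."""
    global _default_reference
    if _default_reference is None:
        text = (
            resources.files("trbdyn.data")
            .joinpath("trb_gene_reference_synthetic.json")
            .read_text()
        )
        _default_reference = GeneReference._from_payload(json.loads(text))
    return _default_reference
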