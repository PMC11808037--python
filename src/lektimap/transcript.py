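"""HGVS c.-notation parsing and coordinate arithmetic on a coding transcript.

Netherton syndrome is caused by biallelic loss-of-function variants in
*SPINK5*. Published case reports describe these variants in HGVS cDNA
notation on transcript NM_006846.4, whose coding sequence (CDS) is 3195 nt:
1064 amino acids plus the stop codon. This module parses the c.-notation
subset that occurs in such reports (single positions, intronic offsets such
as ``c.1431-12`` or ``c.1887+1``, ranges like ``c.1032_1036``, and
del/dup/ins/delins/substitution edits) and resolves each variant to

* a CDS *anchor* base — for intronic positions, the coding base named in
  the HGVS string; for multi-base edits, the 5'-most affected coding base;
* the affected codon, ``ceil(anchor / 3)``;
* a transcript *half*: positions 1–1598 are the 5' half (code 1) and
  1599–3195 the 3' half (code 2), with the boundary inclusive on the 5'
  side;
* a mutation-type class (nonsense, missense, splicing, deletion,
  duplication, insertion, deletion/insertion).

Variant strings in the literature are frequently typeset with stray spaces
(``c. 995delT``, ``c. 1887 + 1G>A``); all whitespace is stripped before
parsing and the normalized form is whitespace-free.

The module never translates sequence: discriminating nonsense from missense
substitutions requires the caller to supply the reported protein
consequence (e.g. ``p.(Arg371*)``). A coding substitution without one is
classified as ``"unclassified-substitution"`` — an explicit state, not an
error and not a silent default.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import Optional, Union

from .errors import HgvsParseError, ValidationError

__all__ = [
    "TranscriptModel",
    "CdnaVariant",
    "EditKind",
    "MutationType",
    "UNCLASSIFIED",
    "spink5_transcript",
    "parse_hgvs",
    "format_hgvs",
    "anchor_codon",
    "assign_half",
    "classify_type",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Coordinate system of one coding transcript.

    ``half_boundary`` is the last CDS base belonging to the 5' half.
    The CDS includes the stop codon: ``cds_length == 3 * (protein_length + 1)``.
    """

    accession: str
    cds_length: int
    protein_length: int
    half_boundary: int

    def __post_init__(self) -> None:
        if self.cds_length != 3 * (self.protein_length + 1):
            raise ValidationError(
                f"{self.accession}: cds_length {self.cds_length} != "
                f"3 * (protein_length {self.protein_length} + 1)"
            )
        if not 1 <= self.half_boundary < self.cds_length:
            raise ValidationError(
                f"{self.accession}: half_boundary {self.half_boundary} "
                f"outside 1..{self.cds_length - 1}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            accession=str(d["accession"]),
            cds_length=int(d["cds_length"]),
            protein_length=int(d["protein_length"]),
            half_boundary=int(d["half_boundary"]),
        )

    @classmethod
    def from_json(cls, path) -> "TranscriptModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def spink5_transcript() -> TranscriptModel:
    """The packaged SPINK5 NM_006846.4 transcript model (default everywhere)."""
    text = (
        _importlib_resources.files("lektimap.resources")
        .joinpath("spink5_nm_006846.4.json")
        .read_text(encoding="utf-8")
    )
    return TranscriptModel.from_dict(json.loads(text))


class EditKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class MutationType(str, enum.Enum):
    """The seven mutation-type classes tallied in the cohort."""

    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SPLICING = "splicing"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELETION_INSERTION = "deletion/insertion"


#: Explicit state for a coding substitution whose protein consequence is
#: unknown: it cannot be split into nonsense vs missense, but it is not an
#: error either.
UNCLASSIFIED = "unclassified-substitution"


@dataclass(frozen=True)
class CdnaVariant:
    """One parsed HGVS c. edit.

    ``anchor`` is the 5'-most coding base named in the string (intronic
    offsets hang off it in ``intron_offset``). ``end_anchor`` /
    ``end_intron_offset`` are present only for range edits.
    """

    raw: str
    anchor: int
    edit_kind: EditKind
    intron_offset: Optional[int] = None
    end_anchor: Optional[int] = None
    end_intron_offset: Optional[int] = None
    ref_bases: Optional[str] = None
    alt_bases: Optional[str] = None

    @property
    def is_intronic(self) -> bool:
        """True if any named position carries a nonzero intronic offset."""
        return bool(self.intron_offset) or bool(self.end_intron_offset)

    @property
    def normalized(self) -> str:
        return format_hgvs(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


_POSITION = r"(?P<anchor>\d+)(?P<off>[+-]\d+)?"
_END = r"(?P<end>\d+)(?P<endoff>[+-]\d+)?"
_EDIT = (
    r"(?:(?P<ref>[ACGT])>(?P<alt>[ACGT])"
    r"|delins(?P<delins>[ACGT]*)"
    r"|del(?P<del>[ACGT]*)"
    r"|dup(?P<dup>[ACGT]*)"
    r"|ins(?P<ins>[ACGT]+))"
)
_HGVS_RE = re.compile(rf"^c\.{_POSITION}(?:_{_END})?{_EDIT}$")


def parse_hgvs(s: str, transcript: Optional[TranscriptModel] = None) -> CdnaVariant:
    """Parse an HGVS c. string into a :class:`CdnaVariant`.

    All whitespace (including internal, as printed in some reports) is
    stripped first. Anchors are validated against the transcript CDS
    (SPINK5 by default).

    Raises
    ------
    HgvsParseError
        If the string does not match the supported c. grammar or an anchor
        falls outside ``1..cds_length``.
    """
    t = transcript if transcript is not None else spink5_transcript()
    normalized = "".join(str(s).split())
    if normalized.startswith("C."):
        normalized = "c." + normalized[2:]
    if not normalized.startswith("c."):
        raise HgvsParseError(f"not a c. variant: {s!r}")
    m = _HGVS_RE.match(normalized)
    if m is None:
        raise HgvsParseError(f"unparseable HGVS token: {s!r} (normalized {normalized!r})")

    anchor = int(m.group("anchor"))
    end = m.group("end")
    end_anchor = int(end) if end is not None else None
    for label, pos in (("anchor", anchor), ("end anchor", end_anchor)):
        if pos is not None and not 1 <= pos <= t.cds_length:
            raise HgvsParseError(
                f"{label} {pos} outside CDS 1..{t.cds_length} in {s!r}"
            )
    if end_anchor is not None and end_anchor < anchor:
        raise HgvsParseError(f"range end {end_anchor} precedes start {anchor} in {s!r}")

    off = m.group("off")
    endoff = m.group("endoff")

    if m.group("ref") is not None:
        kind, ref, alt = EditKind.SUBSTITUTION, m.group("ref"), m.group("alt")
    elif m.group("delins") is not None:
        kind, ref, alt = EditKind.DELINS, None, m.group("delins") or None
    elif m.group("del") is not None:
        kind, ref, alt = EditKind.DELETION, m.group("del") or None, None
    elif m.group("dup") is not None:
        kind, ref, alt = EditKind.DUPLICATION, m.group("dup") or None, None
    else:
        kind, ref, alt = EditKind.INSERTION, None, m.group("ins")

    return CdnaVariant(
        raw=str(s),
        anchor=anchor,
        intron_offset=int(off) if off is not None else None,
        end_anchor=end_anchor,
        end_intron_offset=int(endoff) if endoff is not None else None,
        edit_kind=kind,
        ref_bases=ref,
        alt_bases=alt,
    )


def format_hgvs(v: CdnaVariant) -> str:
    """Render the canonical whitespace-free form of a parsed variant."""

    def fmt_off(off: Optional[int]) -> str:
        return "" if not off else f"{off:+d}"

    pos = f"{v.anchor}{fmt_off(v.intron_offset)}"
    if v.end_anchor is not None:
        pos += f"_{v.end_anchor}{fmt_off(v.end_intron_offset)}"
    if v.edit_kind is EditKind.SUBSTITUTION:
        edit = f"{v.ref_bases}>{v.alt_bases}"
    elif v.edit_kind is EditKind.DELETION:
        edit = f"del{v.ref_bases or ''}"
    elif v.edit_kind is EditKind.DUPLICATION:
        edit = f"dup{v.ref_bases or ''}"
    elif v.edit_kind is EditKind.INSERTION:
        edit = f"ins{v.alt_bases}"
    else:
        edit = f"delins{v.alt_bases or ''}"
    return f"c.{pos}{edit}"


def anchor_codon(v: CdnaVariant, transcript: Optional[TranscriptModel] = None) -> int:
    """Codon index of the anchor base: ``ceil(anchor / 3)``.

    The stop codon (index ``protein_length + 1``) is representable; domain
    lookup for it yields no domain.
    """
    t = transcript if transcript is not None else spink5_transcript()
    codon = math.ceil(v.anchor / 3)
    if not 1 <= codon <= t.protein_length + 1:
        raise ValidationError(f"codon {codon} outside 1..{t.protein_length + 1}")
    return codon


def assign_half(v: CdnaVariant, transcript: Optional[TranscriptModel] = None) -> int:
    """Transcript half of the anchor base: 1 (5') or 2 (3').

    Intronic offsets are ignored — the variant is anchored to the coding
    base named in the HGVS string.
    """
    t = transcript if transcript is not None else spink5_transcript()
    return 1 if v.anchor <= t.half_boundary else 2


_PROTEIN_RE = re.compile(
    r"^p\.?\(?(?P<ref>[A-Z][a-z]{2}|\*)(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|\*|=)\)?$"
)


def classify_type(
    v: CdnaVariant, protein_consequence: Optional[str] = None
) -> Union[MutationType, str]:
    """Classify a parsed variant into one of the seven mutation types.

    Rules, in order:

    * any nonzero intronic offset (on either end of a range) → splicing;
      supplying a protein consequence for such a variant is contradictory
      and raises :class:`ValidationError`;
    * coding del/dup/ins/delins → the corresponding class;
    * coding substitution with a protein consequence → nonsense for a stop
      gain (``*``/``Ter``), missense for a single-residue substitution;
    * coding substitution without one → :data:`UNCLASSIFIED`.
    """
    if v.is_intronic:
        if protein_consequence:
            raise ValidationError(
                f"protein consequence {protein_consequence!r} supplied for "
                f"intronic variant {v.normalized}"
            )
        return MutationType.SPLICING
    if v.edit_kind is EditKind.DELETION:
        return MutationType.DELETION
    if v.edit_kind is EditKind.DUPLICATION:
        return MutationType.DUPLICATION
    if v.edit_kind is EditKind.INSERTION:
        return MutationType.INSERTION
    if v.edit_kind is EditKind.DELINS:
        return MutationType.DELETION_INSERTION

    if protein_consequence is None or str(protein_consequence).strip() == "":
        return UNCLASSIFIED
    p = "".join(str(protein_consequence).split())
    p = p.replace("Ter", "*")
    m = _PROTEIN_RE.match(p)
    if m is None:
        raise ValidationError(f"unparseable protein consequence: {protein_consequence!r}")
    alt = m.group("alt")
    if alt == "*":
        return MutationType.NONSENSE
    if alt == "=" or alt == m.group("ref"):
        return UNCLASSIFIED  # synonymous at the protein level
    return MutationType.MISSENSE
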