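"""LEKTI domain and domain-region tables, and per-variant annotation.

LEKTI, the *SPINK5* product, is a 1064-residue serine protease inhibitor
built from fifteen Kazal-type domains separated by linkers; proteolytic
processing releases multidomain fragments with distinct bio-reactivity.
The fifteen domains are grouped here into five such fragment regions:
D1–D5, D6, D7, D8–D9 and D10–D15. Residues outside every domain (signal
peptide 1–27, inter-domain linkers, the C-terminal tail past residue 1048)
are "non-domain".

Both tables ship as a JSON resource and users may supply an alternative
table with the same schema for other multidomain proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import Optional, Sequence, Union

from .errors import ValidationError
from .transcript import (
    CdnaVariant,
    MutationType,
    TranscriptModel,
    anchor_codon,
    assign_half,
    classify_type,
    spink5_transcript,
)

__all__ = [
    "DomainDef",
    "DomainRegionDef",
    "DomainTable",
    "VariantAnnotation",
    "lekti_domain_table",
    "domain_of_aa",
    "region_of_domain",
    "annotate_variant",
]


@dataclass(frozen=True)
class DomainDef:
    index: int
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValidationError(
                f"domain {self.index}: aa_start {self.aa_start} > aa_end {self.aa_end}"
            )

    def __contains__(self, aa: int) -> bool:
        return self.aa_start <= aa <= self.aa_end


@dataclass(frozen=True)
class DomainRegionDef:
    index: int
    member_domains: frozenset


class DomainTable:
    """Validated set of domains plus a partition of them into regions."""

    def __init__(
        self, domains: Sequence[DomainDef], regions: Sequence[DomainRegionDef]
    ) -> None:
        domains = sorted(domains, key=lambda d: d.index)
        if [d.index for d in domains] != list(range(1, len(domains) + 1)):
            raise ValidationError("domain indices must be 1..n without gaps")
        for prev, cur in zip(domains, domains[1:]):
            if cur.aa_start <= prev.aa_end:
                raise ValidationError(
                    f"domains {prev.index} and {cur.index} overlap or are unordered"
                )
        covered = sorted(i for r in regions for i in r.member_domains)
        if covered != [d.index for d in domains]:
            raise ValidationError("regions must partition the domain indices")
        self.domains = tuple(domains)
        self.regions = tuple(sorted(regions, key=lambda r: r.index))
        self._region_of = {
            i: r.index for r in self.regions for i in r.member_domains
        }

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def domain_of_aa(self, aa: int, protein_length: int = 1064) -> Optional[int]:
        """Domain index whose inclusive range contains ``aa``, else None.

        ``aa`` may be any codon index, including the stop codon
        ``protein_length + 1``, which maps to no domain.
        """
        if not 1 <= aa <= protein_length + 1:
            raise ValidationError(f"amino-acid position {aa} outside 1..{protein_length + 1}")
        for d in self.domains:
            if aa in d:
                return d.index
        return None

    def region_of_domain(self, domain: int) -> int:
        if domain not in self._region_of:
            raise ValidationError(
                f"domain index {domain} outside 1..{self.n_domains}"
            )
        return self._region_of[domain]

    def location_label(self, aa: int, protein_length: int = 1064) -> str:
        """Bar-chart bin for a residue: ``D7`` in-domain, flanking-pair
        labels (``D1-2``) for linkers, ``pre-D1`` / ``post-D15`` for the
        termini."""
        d = self.domain_of_aa(aa, protein_length)
        if d is not None:
            return f"D{d}"
        if aa < self.domains[0].aa_start:
            return "pre-D1"
        if aa > self.domains[-1].aa_end:
            return f"post-D{self.domains[-1].index}"
        for prev, cur in zip(self.domains, self.domains[1:]):
            if prev.aa_end < aa < cur.aa_start:
                return f"D{prev.index}-{cur.index}"
        raise AssertionError("unreachable")  # pragma: no cover

    @classmethod
    def from_dict(cls, d: dict) -> "DomainTable":
        return cls(
            domains=[
                DomainDef(int(x["index"]), int(x["aa_start"]), int(x["aa_end"]))
                for x in d["domains"]
            ],
            regions=[
                DomainRegionDef(int(x["index"]), frozenset(int(i) for i in x["member_domains"]))
                for x in d["regions"]
            ],
        )

    @classmethod
    def from_json(cls, path) -> "DomainTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def lekti_domain_table() -> DomainTable:
    """The packaged 15-domain / 5-region LEKTI table (default everywhere)."""
    text = (
        _importlib_resources.files("lektimap.resources")
        .joinpath("lekti_domains.json")
        .read_text(encoding="utf-8")
    )
    return DomainTable.from_dict(json.loads(text))


def domain_of_aa(aa: int, table: Optional[DomainTable] = None) -> Optional[int]:
    return (table or lekti_domain_table()).domain_of_aa(aa)


def region_of_domain(domain: int, table: Optional[DomainTable] = None) -> int:
    return (table or lekti_domain_table()).region_of_domain(domain)


@dataclass(frozen=True)
class VariantAnnotation:
    """Everything the association analysis needs about one allele."""

    variant: CdnaVariant
    half: int
    codon: int
    domain: Optional[int]
    region: Optional[int]
    in_domain: bool
    mutation_type: Union[MutationType, str]

    def __post_init__(self) -> None:
        if self.in_domain != (self.domain is not None) or self.in_domain != (
            self.region is not None
        ):
            raise ValidationError("in_domain must match presence of domain and region")


def annotate_variant(
    v: CdnaVariant,
    transcript: Optional[TranscriptModel] = None,
    protein_consequence: Optional[str] = None,
    table: Optional[DomainTable] = None,
) -> VariantAnnotation:
    """Resolve one parsed variant to half, codon, domain, region and type."""
    t = transcript if transcript is not None else spink5_transcript()
    tab = table if table is not None else lekti_domain_table()
    codon = anchor_codon(v, t)
    domain = tab.domain_of_aa(codon, t.protein_length)
    return VariantAnnotation(
        variant=v,
        half=assign_half(v, t),
        codon=codon,
        domain=domain,
        region=tab.region_of_domain(domain) if domain is not None else None,
        in_domain=domain is not None,
        mutation_type=classify_type(v, protein_consequence),
    )
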