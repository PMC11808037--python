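"""Cohort table ingest, validation, curation filters and summaries.

A cohort file is a UTF-8 TSV/CSV with one row per patient. Mandatory
columns: ``patient_id``, ``source``, ``age_years``, ``allele1_cdna``,
``allele2_cdna``, ``large_event_flag``, ``died_in_infancy`` and one column
per recorded phenotype (tokens ``+`` / ``-`` / ``NA``). Optional columns:
``allele1_protein``, ``allele2_protein``, ``exclude_reason``.

Phenotypes are tri-state: ``NA`` (no clear clinical record) is distinct
from ``-`` (phenotype recorded absent), and downstream association models
are complete-case. ``died_in_infancy`` uses the same tokens, with infancy
taken as age at death below one year.

Curation filters mirror the study's exclusion criteria: curator-flagged
rows (via ``exclude_reason``), large deletions/duplications that cannot be
assigned to a domain (``large_event_flag``), and duplicate reports of the
same patient across publications (first occurrence kept). Single-variant
patients are rejected at ingest — both alleles are an inclusion
requirement.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .domains import DomainTable, VariantAnnotation, annotate_variant, lekti_domain_table
from .errors import LektimapError, ValidationError
from .transcript import TranscriptModel, parse_hgvs, spink5_transcript

__all__ = [
    "PHENOTYPES",
    "PhenotypeStatus",
    "PatientRecord",
    "ExclusionReport",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "apply_exclusions",
    "phenotype_summary",
]

#: The nine commonly recorded Netherton syndrome phenotypes analysed here.
PHENOTYPES: Tuple[str, ...] = (
    "ilc",
    "erythroderma",
    "hair_shaft_anomalies",
    "failure_to_thrive",
    "recurrent_infection",
    "hypernatremia",
    "angioedema",
    "urticaria",
    "asthma",
)

_MANDATORY = (
    "patient_id",
    "source",
    "age_years",
    "allele1_cdna",
    "allele2_cdna",
    "large_event_flag",
    "died_in_infancy",
) + PHENOTYPES

_OPTIONAL = ("allele1_protein", "allele2_protein", "exclude_reason")


class PhenotypeStatus(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @classmethod
    def from_token(cls, token: str) -> "PhenotypeStatus":
        t = str(token).strip()
        if t == "+":
            return cls.PRESENT
        if t == "-":
            return cls.ABSENT
        if t.upper() == "NA" or t == "":
            return cls.UNKNOWN
        raise ValidationError(
            f"phenotype token {token!r} not allowed; use one of {{+, -, NA}}"
        )

    @property
    def token(self) -> str:
        return {"present": "+", "absent": "-", "unknown": "NA"}[self.value]


@dataclass
class PatientRecord:
    patient_id: str
    source: str
    age: Optional[float]
    allele1: VariantAnnotation
    allele2: VariantAnnotation
    phenotypes: Dict[str, PhenotypeStatus]
    died_in_infancy: PhenotypeStatus
    large_event: bool = False
    exclude_reason: Optional[str] = None
    allele1_protein: Optional[str] = None
    allele2_protein: Optional[str] = None

    @property
    def zygosity(self) -> str:
        """Derived: equal normalized allele strings mean homozygous."""
        if self.allele1.variant.normalized == self.allele2.variant.normalized:
            return "homozygous"
        return "compound-heterozygous"

    @property
    def is_homozygous(self) -> bool:
        return self.zygosity == "homozygous"


def _parse_age(token, row_id: str) -> Optional[float]:
    s = str(token).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE"}:
        return None
    try:
        age = float(s)
    except ValueError as exc:
        raise ValidationError(f"row {row_id}: bad age_years {token!r}") from exc
    if age < 0:
        raise ValidationError(f"row {row_id}: negative age {age}")
    return age


def _parse_flag(token, row_id: str) -> bool:
    s = str(token).strip().lower()
    if s in {"", "0", "false", "no", "nan"}:
        return False
    if s in {"1", "true", "yes"}:
        return True
    raise ValidationError(f"row {row_id}: bad large_event_flag {token!r}")


def _row_to_record(
    row: pd.Series,
    row_id: str,
    transcript: TranscriptModel,
    table: DomainTable,
) -> PatientRecord:
    def opt(col: str) -> Optional[str]:
        if col not in row.index:
            return None
        v = row[col]
        s = "" if pd.isna(v) else str(v).strip()
        return s or None

    alleles = []
    for i in (1, 2):
        hgvs = opt(f"allele{i}_cdna")
        if hgvs is None:
            raise ValidationError(
                f"row {row_id}: allele{i}_cdna is empty — single-variant "
                "patients are excluded (both alleles required)"
            )
        protein = opt(f"allele{i}_protein")
        try:
            alleles.append(
                annotate_variant(
                    parse_hgvs(hgvs, transcript),
                    transcript,
                    protein_consequence=protein,
                    table=table,
                )
            )
        except LektimapError as exc:
            raise ValidationError(f"row {row_id}, allele{i}: {exc}") from exc

    try:
        phenotypes = {p: PhenotypeStatus.from_token(row[p]) for p in PHENOTYPES}
        died = PhenotypeStatus.from_token(row["died_in_infancy"])
    except ValidationError as exc:
        raise ValidationError(f"row {row_id}: {exc}") from exc

    return PatientRecord(
        patient_id=str(row["patient_id"]).strip(),
        source=opt("source") or "",
        age=_parse_age(row["age_years"], row_id),
        allele1=alleles[0],
        allele2=alleles[1],
        phenotypes=phenotypes,
        died_in_infancy=died,
        large_event=_parse_flag(row["large_event_flag"], row_id),
        exclude_reason=opt("exclude_reason"),
        allele1_protein=opt("allele1_protein"),
        allele2_protein=opt("allele2_protein"),
    )


def read_cohort(
    path,
    transcript: Optional[TranscriptModel] = None,
    table: Optional[DomainTable] = None,
) -> List[PatientRecord]:
    """Read and fully annotate a cohort file (TSV by default, CSV by suffix).

    Every row must parse; errors carry the offending row's patient_id (or
    file line) so curation problems are traceable.
    """
    t = transcript if transcript is not None else spink5_transcript()
    tab = table if table is not None else lekti_domain_table()
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        row_id = str(row["patient_id"]).strip() or f"<line {i + 2}>"
        records.append(_row_to_record(row, row_id, t, tab))
    return records


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialize records back to the cohort-table dialect (as a DataFrame)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "source": r.source,
            "age_years": "" if r.age is None else f"{r.age:g}",
            "allele1_cdna": r.allele1.variant.normalized,
            "allele2_cdna": r.allele2.variant.normalized,
            "allele1_protein": r.allele1_protein or "",
            "allele2_protein": r.allele2_protein or "",
            "large_event_flag": "1" if r.large_event else "0",
            "exclude_reason": r.exclude_reason or "",
            "died_in_infancy": r.died_in_infancy.token,
        }
        row.update({p: r.phenotypes[p].token for p in PHENOTYPES})
        rows.append(row)
    cols = [
        "patient_id", "source", "age_years", "allele1_cdna", "allele2_cdna",
        "allele1_protein", "allele2_protein", "large_event_flag",
        "exclude_reason", "died_in_infancy", *PHENOTYPES,
    ]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    records_to_frame(records).to_csv(path, sep=sep, index=False)


@dataclass
class ExclusionReport:
    curator_flagged: int = 0
    large_event: int = 0
    duplicate_id: int = 0
    excluded_ids: List[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.curator_flagged + self.large_event + self.duplicate_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["curator_flagged", "large_event", "duplicate_id"],
                "n_excluded": [self.curator_flagged, self.large_event, self.duplicate_id],
            }
        )


def apply_exclusions(
    records: Sequence[PatientRecord],
) -> Tuple[List[PatientRecord], ExclusionReport]:
    """Apply the curation filters; filtering is idempotent, never an error."""
    report = ExclusionReport()
    kept: List[PatientRecord] = []
    seen_ids = set()
    for r in records:
        if r.exclude_reason:
            report.curator_flagged += 1
            report.excluded_ids.append(r.patient_id)
        elif r.large_event:
            report.large_event += 1
            report.excluded_ids.append(r.patient_id)
        elif r.patient_id in seen_ids:
            report.duplicate_id += 1
            report.excluded_ids.append(r.patient_id)
        else:
            seen_ids.add(r.patient_id)
            kept.append(r)
    return kept, report


@dataclass
class CohortSummary:
    n_patients: int
    n_alleles: int
    n_distinct_variants: int
    n_homozygous: int
    n_heterozygous: int
    phenotype_counts: pd.DataFrame  # index phenotype; present/absent/unknown + pct_*
    allele_type_counts: "Counter[str]"
    allele_region_counts: "Counter[str]"

    def complete_case_n(self, phenotype: str) -> int:
        row = self.phenotype_counts.loc[phenotype]
        return int(row["present"] + row["absent"])


def phenotype_summary(records: Sequence[PatientRecord]) -> CohortSummary:
    """Tri-state phenotype tallies plus allele tallies by type and region.

    Percentages are of cohort size, rounded to two decimals. Every patient
    contributes exactly two alleles to the type and region tallies.
    """
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(records)
    rows = []
    for p in list(PHENOTYPES) + ["died_in_infancy"]:
        statuses = [
            (r.phenotypes[p] if p != "died_in_infancy" else r.died_in_infancy)
            for r in records
        ]
        c = Counter(statuses)
        pres, absent, unk = (
            c[PhenotypeStatus.PRESENT],
            c[PhenotypeStatus.ABSENT],
            c[PhenotypeStatus.UNKNOWN],
        )
        rows.append(
            {
                "phenotype": p,
                "present": pres,
                "absent": absent,
                "unknown": unk,
                "pct_present": round(pres / n * 100, 2),
                "pct_absent": round(absent / n * 100, 2),
                "pct_unknown": round(unk / n * 100, 2),
            }
        )
    pheno = pd.DataFrame(rows).set_index("phenotype")

    type_counts: Counter = Counter()
    region_counts: Counter = Counter()
    variants = set()
    for r in records:
        for a in (r.allele1, r.allele2):
            mt = a.mutation_type
            type_counts[mt.value if hasattr(mt, "value") else str(mt)] += 1
            region_counts[
                f"DomainR-{a.region}" if a.region is not None else "non-domain"
            ] += 1
            variants.add(a.variant.normalized)

    n_hom = sum(1 for r in records if r.is_homozygous)
    return CohortSummary(
        n_patients=n,
        n_alleles=2 * n,
        n_distinct_variants=len(variants),
        n_homozygous=n_hom,
        n_heterozygous=n - n_hom,
        phenotype_counts=pheno,
        allele_type_counts=type_counts,
        allele_region_counts=region_counts,
    )
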