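"""Numeric coding of biallelic genotypes into regression covariates.

Per-allele codes: transcript half (1 = 5', 2 = 3'); domain number (1..15,
missing outside domains); DomainR-5 indicator (1 inside D10-D15, else 0);
in-domain indicator (1 inside any domain, else 0). The overall effect of
the two alleles is the product of the per-allele values: ``halfx``
(1/2/4), ``domnum_x``, ``d5x`` and ``indom_x`` (0/1). A product with an
undefined factor (a non-domain allele has no domain number) is missing and
the patient drops out of that analysis. For homozygous-only analyses the
single-allele value is used, since both alleles are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import pandas as pd

from .cohort import PHENOTYPES, PatientRecord, PhenotypeStatus
from .domains import VariantAnnotation
from .errors import StatsError, ValidationError

__all__ = [
    "CodedGenotype",
    "DropReport",
    "PRODUCT_VARIABLES",
    "SINGLE_VARIABLES",
    "code_alleles",
    "coded_frame",
    "build_dataset",
]

#: Two-allele product covariates (available for all patients).
PRODUCT_VARIABLES: Tuple[str, ...] = ("halfx", "domnum_x", "d5x", "indom_x")
#: Single-allele covariates, valid only for the homozygous-only analysis.
SINGLE_VARIABLES: Tuple[str, ...] = ("half", "domnum", "in_d5", "in_dom")

_D5_REGION = 5


@dataclass(frozen=True)
class CodedGenotype:
    half1: int
    half2: int
    halfx: int
    dom1: Optional[int]
    dom2: Optional[int]
    domnum_x: Optional[int]
    in_d5_1: int
    in_d5_2: int
    d5x: int
    in_dom1: int
    in_dom2: int
    indom_x: int

    def value(self, variable: str) -> Optional[float]:
        mapping = {
            "halfx": self.halfx,
            "domnum_x": self.domnum_x,
            "d5x": self.d5x,
            "indom_x": self.indom_x,
            "half": self.half1,
            "domnum": self.dom1,
            "in_d5": self.in_d5_1,
            "in_dom": self.in_dom1,
        }
        if variable not in mapping:
            raise ValidationError(
                f"unknown covariate {variable!r}; choose from "
                f"{PRODUCT_VARIABLES + SINGLE_VARIABLES}"
            )
        v = mapping[variable]
        return None if v is None else float(v)


def code_alleles(a1: VariantAnnotation, a2: VariantAnnotation) -> CodedGenotype:
    """Code a biallelic genotype. Symmetric: alleles are canonically ordered
    by (anchor, normalized string) so swapping the arguments changes nothing.
    """
    first, second = sorted(
        (a1, a2), key=lambda a: (a.variant.anchor, a.variant.normalized)
    )
    in_d5 = tuple(int(a.region == _D5_REGION) for a in (first, second))
    in_dom = tuple(int(a.in_domain) for a in (first, second))
    domnum_x = (
        first.domain * second.domain
        if first.domain is not None and second.domain is not None
        else None
    )
    return CodedGenotype(
        half1=first.half,
        half2=second.half,
        halfx=first.half * second.half,
        dom1=first.domain,
        dom2=second.domain,
        domnum_x=domnum_x,
        in_d5_1=in_d5[0],
        in_d5_2=in_d5[1],
        d5x=in_d5[0] * in_d5[1],
        in_dom1=in_dom[0],
        in_dom2=in_dom[1],
        indom_x=in_dom[0] * in_dom[1],
    )


def coded_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Audit table: one row per patient with every coded field (TSV-ready)."""
    rows = []
    for r in records:
        g = code_alleles(r.allele1, r.allele2)
        rows.append(
            {
                "patient_id": r.patient_id,
                "zygosity": r.zygosity,
                "age_years": r.age,
                **{f: getattr(g, f) for f in CodedGenotype.__dataclass_fields__},
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DropReport:
    phenotype_unknown: int = 0
    covariate_missing: int = 0
    age_missing: int = 0
    non_homozygous: int = 0

    @property
    def total(self) -> int:
        return (
            self.phenotype_unknown
            + self.covariate_missing
            + self.age_missing
            + self.non_homozygous
        )


def build_dataset(
    records: Sequence[PatientRecord],
    variable: str,
    phenotype: str,
    homozygous_only: bool = False,
) -> Tuple[pd.DataFrame, DropReport]:
    """Assemble the complete-case model table (outcome, covariate, age).

    Rows with an unknown phenotype, a missing covariate (non-domain allele
    in a domain-number analysis) or a missing age are dropped and counted.
    Single-allele covariates require ``homozygous_only=True``.
    """
    if phenotype not in PHENOTYPES and phenotype != "died_in_infancy":
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    if variable in SINGLE_VARIABLES and not homozygous_only:
        raise ValidationError(
            f"single-allele covariate {variable!r} is only defined for the "
            "homozygous-only analysis"
        )
    if variable not in PRODUCT_VARIABLES + SINGLE_VARIABLES:
        raise ValidationError(f"unknown covariate {variable!r}")

    report = DropReport()
    rows = []
    for r in records:
        if homozygous_only and not r.is_homozygous:
            report.non_homozygous += 1
            continue
        status = (
            r.died_in_infancy if phenotype == "died_in_infancy" else r.phenotypes[phenotype]
        )
        if status is PhenotypeStatus.UNKNOWN:
            report.phenotype_unknown += 1
            continue
        cov = code_alleles(r.allele1, r.allele2).value(variable)
        if cov is None:
            report.covariate_missing += 1
            continue
        if r.age is None:
            report.age_missing += 1
            continue
        rows.append(
            {
                "patient_id": r.patient_id,
                "outcome": int(status is PhenotypeStatus.PRESENT),
                "covariate": cov,
                "age": r.age,
            }
        )
    if not rows:
        raise StatsError(
            f"no complete cases for phenotype={phenotype!r}, variable={variable!r} "
            f"(dropped: {report.phenotype_unknown} unknown outcome, "
            f"{report.covariate_missing} missing covariate, "
            f"{report.age_missing} missing age, "
            f"{report.non_homozygous} non-homozygous)"
        )
    return pd.DataFrame(rows).set_index("patient_id"), report
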