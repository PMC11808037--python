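"""Built-in demonstration cohort.

:func:`fatal_variant_demo_cohort` reconstructs, patient by patient, the
published carrier counts of the five recurrent fatal *SPINK5* variants
(c.153delT, c.1431-12G>A, c.1111C>T, c.1887+1G>A, c.995delT): 18 patients
homozygous for a fatal variant of whom 14 died during infancy, and 12
compound heterozygotes pairing a fatal allele with a non-fatal partner
allele, none of whom died. Genotypes, zygosity and death counts follow the
published tallies; ages and the non-death phenotype fields are synthetic
fill (the sources report only aggregates), so only the fatal-variant
analysis on this cohort is meaningful.
"""

from __future__ import annotations

from typing import List, Optional

from .cohort import PHENOTYPES, PatientRecord, PhenotypeStatus
from .domains import annotate_variant, lekti_domain_table
from .transcript import parse_hgvs, spink5_transcript

__all__ = ["FATAL_VARIANTS", "fatal_variant_demo_cohort"]

#: The five recurrent homozygous-lethal variants, normalized.
FATAL_VARIANTS = (
    "c.153delT",
    "c.1431-12G>A",
    "c.1111C>T",
    "c.1887+1G>A",
    "c.995delT",
)

# (fatal variant, protein consequence, homozygous total, homozygous deaths,
#  [(partner allele, partner protein, n het patients), ...])
_ROWS = [
    ("c.153delT", None, 11, 8, [("c.81+2T>A", None, 2), ("c.891C>T", None, 3)]),
    (
        "c.1431-12G>A",
        None,
        3,
        3,
        [
            ("c.1816_1820+21delinsCT", None, 1),
            ("c.891C>T", None, 1),
            ("c.2472_2473delAG", None, 1),
        ],
    ),
    (
        "c.1111C>T",
        "p.(Arg371*)",
        1,
        1,
        [
            ("c.2468delA", None, 1),
            ("c.1032_1036dupGAAAA", None, 1),
            ("c.81+2T>A", None, 1),
            ("c.2041_2042delAG", None, 1),
        ],
    ),
    ("c.1887+1G>A", None, 2, 1, []),
    ("c.995delT", None, 1, 1, []),
]


def _record(
    pid: str,
    hgvs1: str,
    hgvs2: str,
    died: bool,
    age: float,
    protein1: Optional[str] = None,
    protein2: Optional[str] = None,
) -> PatientRecord:
    t = spink5_transcript()
    tab = lekti_domain_table()
    a1 = annotate_variant(parse_hgvs(hgvs1, t), t, protein_consequence=protein1, table=tab)
    a2 = annotate_variant(parse_hgvs(hgvs2, t), t, protein_consequence=protein2, table=tab)
    phenos = {p: PhenotypeStatus.UNKNOWN for p in PHENOTYPES}
    phenos["erythroderma"] = PhenotypeStatus.PRESENT  # synthetic fill
    return PatientRecord(
        patient_id=pid,
        source="literature-aggregate",
        age=age,
        allele1=a1,
        allele2=a2,
        phenotypes=phenos,
        died_in_infancy=PhenotypeStatus.PRESENT if died else PhenotypeStatus.ABSENT,
        allele1_protein=protein1,
        allele2_protein=protein2,
    )


def fatal_variant_demo_cohort() -> List[PatientRecord]:
    """The 30-patient fatal-variant carrier cohort (see module docstring)."""
    records: List[PatientRecord] = []
    n = 0
    for hgvs, protein, hom_total, hom_deaths, het_partners in _ROWS:
        for i in range(hom_total):
            n += 1
            died = i < hom_deaths
            # one live homozygote in the sources was under a year old
            age = 0.5 if died else (0.8 if (hgvs == "c.153delT" and i == hom_deaths) else 2.0 + i)
            records.append(
                _record(f"FV{n:03d}", hgvs, hgvs, died, age, protein, protein)
            )
        for partner, partner_protein, count in het_partners:
            for i in range(count):
                n += 1
                records.append(
                    _record(
                        f"FV{n:03d}", hgvs, partner, False, 3.0 + i, protein, partner_protein
                    )
                )
    return records
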