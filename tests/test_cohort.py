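"""Cohort ingest, validation, curation filters and tri-state summaries."""

import random

import pytest

from lektimap import (
    PHENOTYPES,
    PatientRecord,
    PhenotypeStatus,
    ValidationError,
    annotate_variant,
    apply_exclusions,
    parse_hgvs,
    phenotype_summary,
    read_cohort,
    write_cohort,
)
from lektimap.cohort import records_to_frame

HEADER = (
    "patient_id\tsource\tage_years\tallele1_cdna\tallele2_cdna\t"
    "allele1_protein\tallele2_protein\tlarge_event_flag\texclude_reason\t"
    "died_in_infancy\t" + "\t".join(PHENOTYPES)
)


def make_row(pid, allele1="c.153delT", allele2="c.153delT", age="3.5",
             flag="0", reason="", died="-", pheno=None):
    pheno = pheno or ["+"] + ["NA"] * 8
    return "\t".join(
        [pid, "unit-test", age, allele1, allele2, "", "", flag, reason, died, *pheno]
    )


def write_tsv(path, rows):
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


def make_record(pid, hgvs1, hgvs2, age=3.0, died=PhenotypeStatus.ABSENT,
                phenotypes=None, large_event=False, exclude_reason=None):
    a1 = annotate_variant(parse_hgvs(hgvs1))
    a2 = annotate_variant(parse_hgvs(hgvs2))
    return PatientRecord(
        patient_id=pid,
        source="unit-test",
        age=age,
        allele1=a1,
        allele2=a2,
        phenotypes=phenotypes or {p: PhenotypeStatus.UNKNOWN for p in PHENOTYPES},
        died_in_infancy=died,
        large_event=large_event,
        exclude_reason=exclude_reason,
    )


class TestReadCohort:
    def test_homozygous_row(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", [make_row("P1")])
        (rec,) = read_cohort(p)
        assert rec.zygosity == "homozygous"
        assert rec.allele1.domain == rec.allele2.domain == 1
        assert rec.phenotypes["ilc"] is PhenotypeStatus.PRESENT
        assert rec.age == 3.5

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("patient_id\tage_years\nP1\t3\n")
        with pytest.raises(ValidationError, match="mandatory column"):
            read_cohort(p)

    def test_single_variant_patient_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", [make_row("P1", allele2="")])
        with pytest.raises(ValidationError, match="P1"):
            read_cohort(p)

    def test_bad_phenotype_token_lists_allowed(self, tmp_path):
        row = make_row("P7", pheno=["?"] + ["NA"] * 8)
        p = write_tsv(tmp_path / "c.tsv", [row])
        with pytest.raises(ValidationError, match=r"P7.*\+, -, NA"):
            read_cohort(p)

    def test_unparseable_hgvs_names_row(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", [make_row("P9", allele1="c.abc>T")])
        with pytest.raises(ValidationError, match="P9"):
            read_cohort(p)

    def test_round_trip_preserves_records(self, tmp_path, demo_cohort):
        p = tmp_path / "c.tsv"
        write_cohort(demo_cohort, p)
        back = read_cohort(p)
        assert len(back) == len(demo_cohort)
        for a, b in zip(demo_cohort, back):
            assert a.patient_id == b.patient_id
            assert a.allele1.variant.normalized == b.allele1.variant.normalized
            assert a.zygosity == b.zygosity
            assert a.died_in_infancy is b.died_in_infancy

    def test_csv_dialect_by_suffix(self, tmp_path, demo_cohort):
        p = tmp_path / "c.csv"
        write_cohort(demo_cohort[:3], p)
        assert len(read_cohort(p)) == 3


class TestExclusions:
    def test_duplicate_ids_collapse(self):
        r1 = make_record("P1", "c.153delT", "c.153delT")
        r2 = make_record("P1", "c.153delT", "c.153delT")
        kept, report = apply_exclusions([r1, r2])
        assert len(kept) == 1 and report.duplicate_id == 1

    def test_large_event_excluded(self):
        r = make_record("P1", "c.153delT", "c.153delT", large_event=True)
        kept, report = apply_exclusions([r])
        assert kept == [] and report.large_event == 1

    def test_curator_flag_honored(self):
        r = make_record("P1", "c.153delT", "c.153delT",
                        exclude_reason="pathogenicity undeterminable")
        kept, report = apply_exclusions([r])
        assert kept == [] and report.curator_flagged == 1

    def test_clean_cohort_is_noop_and_idempotent(self, demo_cohort):
        kept, report = apply_exclusions(demo_cohort)
        assert len(kept) == len(demo_cohort) and report.total == 0
        kept2, report2 = apply_exclusions(kept)
        assert [r.patient_id for r in kept2] == [r.patient_id for r in kept]
        assert report2.total == 0


# tri-state counts (present, absent, unknown) of a published 162-patient
# cohort, used to build a synthetic cohort with the same marginals
_PUBLISHED_COUNTS = {
    "ilc": (73, 27, 62),
    "erythroderma": (124, 18, 20),
    "hair_shaft_anomalies": (120, 14, 28),
    "failure_to_thrive": (56, 17, 89),
    "recurrent_infection": (79, 16, 67),
    "hypernatremia": (31, 25, 106),
    "angioedema": (12, 23, 127),
    "urticaria": (12, 32, 118),
    "asthma": (16, 34, 112),
}


def _marginal_cohort():
    n = 162
    records = []
    for i in range(n):
        phenos = {}
        for name, (pres, absent, _unk) in _PUBLISHED_COUNTS.items():
            if i < pres:
                phenos[name] = PhenotypeStatus.PRESENT
            elif i < pres + absent:
                phenos[name] = PhenotypeStatus.ABSENT
            else:
                phenos[name] = PhenotypeStatus.UNKNOWN
        records.append(make_record(f"M{i:03d}", "c.153delT", "c.995delT",
                                   phenotypes=phenos))
    return records


class TestPhenotypeSummary:
    def test_tri_state_counts(self):
        recs = []
        for i, status in enumerate("+-N"):
            phenos = {p: PhenotypeStatus.UNKNOWN for p in PHENOTYPES}
            phenos["ilc"] = {"+": PhenotypeStatus.PRESENT,
                             "-": PhenotypeStatus.ABSENT,
                             "N": PhenotypeStatus.UNKNOWN}[status]
            recs.append(make_record(f"P{i}", "c.153delT", "c.153delT",
                                    phenotypes=phenos))
        s = phenotype_summary(recs)
        row = s.phenotype_counts.loc["ilc"]
        assert (row["present"], row["absent"], row["unknown"]) == (1, 1, 1)

    def test_percentages_of_cohort_size(self):
        recs = _marginal_cohort()
        s = phenotype_summary(recs)
        assert s.phenotype_counts.loc["ilc", "pct_present"] == 45.06
        assert s.phenotype_counts.loc["ilc", "pct_unknown"] == 38.27

    def test_complete_case_ns_match_marginals(self):
        s = phenotype_summary(_marginal_cohort())
        expected = [100, 142, 134, 73, 95, 56, 35, 44, 50]
        got = [s.complete_case_n(p) for p in PHENOTYPES]
        assert got == expected

    def test_allele_conservation(self, demo_cohort):
        s = phenotype_summary(demo_cohort)
        assert sum(s.allele_type_counts.values()) == 2 * s.n_patients
        assert sum(s.allele_region_counts.values()) == 2 * s.n_patients

    def test_invariant_under_reordering(self, demo_cohort):
        shuffled = list(demo_cohort)
        random.Random(11).shuffle(shuffled)
        a = phenotype_summary(demo_cohort)
        b = phenotype_summary(shuffled)
        assert a.allele_type_counts == b.allele_type_counts
        assert a.allele_region_counts == b.allele_region_counts

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValidationError):
            phenotype_summary([])
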