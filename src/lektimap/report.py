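"""End-to-end pipeline orchestration and report writing.

``run_pipeline`` takes a cohort (file path, in-memory records, or a
simulation config), applies the curation filters, summarizes phenotypes and
allele distributions, fits the full grid of genotype-phenotype logistic
models (all phenotypes x product covariates, plus the homozygous-only
single-allele analysis), and runs the fatal-variant contingency analysis.
``write_report`` emits deterministic TSV/JSON artifacts (and optional bar
charts on a non-interactive backend), so rerunning on the same inputs
reproduces the same bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import __version__
from .coding import PRODUCT_VARIABLES, SINGLE_VARIABLES, build_dataset, coded_frame
from .cohort import (
    PHENOTYPES,
    CohortSummary,
    ExclusionReport,
    PatientRecord,
    apply_exclusions,
    phenotype_summary,
    read_cohort,
)
from .domains import lekti_domain_table
from .errors import StatsError, ValidationError
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    AssociationResult,
    ContingencyResult,
    FatalVariantSet,
    fatal_contingency,
    fit_logistic,
    identify_fatal_variants,
)
from .transcript import spink5_transcript

__all__ = ["PipelineOptions", "PipelineReport", "run_pipeline", "write_report"]


@dataclass
class PipelineOptions:
    phenotypes: Tuple[str, ...] = PHENOTYPES
    variables: Tuple[str, ...] = PRODUCT_VARIABLES
    homozygous_variables: Tuple[str, ...] = SINGLE_VARIABLES
    include_homozygous_analysis: bool = True
    yates: bool = False


# Anchoring/coding conventions in effect, echoed into report provenance.
_DECISIONS = {
    "half_split": "CDS coordinates; 5' half = bases 1-1598 inclusive, coded 1",
    "anchor_rule": "intronic offsets and range ends ignored; 5'-most coding base anchors",
    "domain_ranges": "inclusive amino-acid ranges; stop codon and linkers are non-domain",
    "domain_product": "domnum_x = product of domain numbers, missing if either allele "
    "is non-domain; indom_x = product of in-domain indicators",
    "complete_case": "rows with unknown outcome, missing covariate or missing age dropped",
    "ci": "Wald 95% CI, z = 1.96",
    "infancy": "death during infancy = age at death < 1 year",
}


@dataclass
class PipelineReport:
    n_input: int
    exclusions: ExclusionReport
    summary: CohortSummary
    associations: List[AssociationResult]
    association_errors: List[Dict[str, str]]
    fatal_set: FatalVariantSet
    fatal_result: Optional[ContingencyResult]
    fatal_error: Optional[str]
    coded: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_analyzed": self.summary.n_patients,
            "exclusions": {
                "curator_flagged": self.exclusions.curator_flagged,
                "large_event": self.exclusions.large_event,
                "duplicate_id": self.exclusions.duplicate_id,
            },
            "cohort": {
                "n_patients": self.summary.n_patients,
                "n_alleles": self.summary.n_alleles,
                "n_distinct_variants": self.summary.n_distinct_variants,
                "n_homozygous": self.summary.n_homozygous,
                "n_heterozygous": self.summary.n_heterozygous,
                "phenotypes": self.summary.phenotype_counts.reset_index().to_dict(
                    orient="records"
                ),
                "allele_types": dict(sorted(self.summary.allele_type_counts.items())),
                "allele_regions": dict(sorted(self.summary.allele_region_counts.items())),
            },
            "associations": [a.to_dict() for a in self.associations],
            "association_errors": self.association_errors,
            "fatal": {
                "variants": {
                    name: dataclasses.asdict(st)
                    for name, st in sorted(self.fatal_set.variants.items())
                },
                "contingency": self.fatal_result.to_dict() if self.fatal_result else None,
                "error": self.fatal_error,
            },
            "provenance": self.provenance,
        }


def _input_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    source: Union[str, Path, Sequence[PatientRecord], SimulationConfig],
    options: Optional[PipelineOptions] = None,
) -> PipelineReport:
    """Run read/exclude → annotate → code → associate → fatal analysis."""
    opts = options or PipelineOptions()
    provenance: Dict[str, object] = {
        "package_version": __version__,
        "transcript": spink5_transcript().accession,
        "n_domains": lekti_domain_table().n_domains,
        "options": dataclasses.asdict(opts),
        "decisions": dict(_DECISIONS),
    }

    if isinstance(source, SimulationConfig):
        records, _truth = simulate_cohort(source)
        provenance["input"] = {"kind": "simulation", "seed": source.seed,
                               "n_patients": source.n_patients}
    elif isinstance(source, (str, Path)):
        records = read_cohort(source)
        provenance["input"] = {"kind": "file", "path": str(source),
                               "sha256": _input_hash(source)}
    else:
        records = list(source)
        provenance["input"] = {"kind": "records", "n": len(records)}
    if not records:
        raise ValidationError("input stage: cohort is empty")

    n_input = len(records)
    kept, excl = apply_exclusions(records)
    if not kept:
        raise ValidationError("exclusion stage: no records survive the filters")
    summary = phenotype_summary(kept)

    associations: List[AssociationResult] = []
    errors: List[Dict[str, str]] = []
    grid = [(v, False) for v in opts.variables]
    if opts.include_homozygous_analysis:
        grid += [(v, True) for v in opts.homozygous_variables]
    for phenotype in opts.phenotypes:
        for variable, hom_only in grid:
            label = f"{variable}{'|homozygous' if hom_only else ''}"
            try:
                table, _drops = build_dataset(
                    kept, variable, phenotype, homozygous_only=hom_only
                )
                res = fit_logistic(table, phenotype, label)
                associations.append(res)
            except StatsError as exc:
                errors.append(
                    {"phenotype": phenotype, "variable": label, "error": str(exc)}
                )

    fatal_set = identify_fatal_variants(kept)
    fatal_result: Optional[ContingencyResult] = None
    fatal_error: Optional[str] = None
    if len(fatal_set):
        try:
            fatal_result = fatal_contingency(kept, fatal_set, yates=opts.yates)
        except StatsError as exc:
            fatal_error = str(exc)
    else:
        fatal_error = "no fatal variants identified"

    return PipelineReport(
        n_input=n_input,
        exclusions=excl,
        summary=summary,
        associations=associations,
        association_errors=errors,
        fatal_set=fatal_set,
        fatal_result=fatal_result,
        fatal_error=fatal_error,
        coded=coded_frame(kept),
        provenance=provenance,
    )


def write_report(
    report: PipelineReport,
    out_dir,
    formats: Sequence[str] = ("tsv", "json"),
    charts: bool = False,
) -> List[Path]:
    """Write report artifacts; returns the list of files created."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if "tsv" in formats:
        p = out / "summary_phenotypes.tsv"
        report.summary.phenotype_counts.reset_index().to_csv(p, sep="\t", index=False)
        written.append(p)

        dist_rows = [
            {"category": "mutation_type", "key": k, "n_alleles": v}
            for k, v in sorted(report.summary.allele_type_counts.items())
        ] + [
            {"category": "domain_region", "key": k, "n_alleles": v}
            for k, v in sorted(report.summary.allele_region_counts.items())
        ]
        dist = pd.DataFrame(dist_rows)
        dist["pct"] = (dist["n_alleles"] / report.summary.n_alleles * 100).round(2)
        p = out / "allele_distribution.tsv"
        dist.to_csv(p, sep="\t", index=False)
        written.append(p)

        p = out / "associations.tsv"
        pd.DataFrame([a.to_dict() for a in report.associations]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)

        p = out / "fatal_variants.tsv"
        pd.DataFrame(
            [dataclasses.asdict(st) for _, st in sorted(report.fatal_set.variants.items())]
        ).to_csv(p, sep="\t", index=False)
        written.append(p)

        p = out / "coded_genotypes.tsv"
        report.coded.to_csv(p, sep="\t", index=False)
        written.append(p)

        p = out / "exclusions.tsv"
        report.exclusions.to_frame().to_csv(p, sep="\t", index=False)
        written.append(p)

    if "json" in formats:
        p = out / "report.json"
        p.write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        written.append(p)

    if charts:
        written.extend(_write_charts(report, out))
    return written


def _write_charts(report: PipelineReport, out: Path) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    regions = sorted(report.summary.allele_region_counts.items())
    axes[0].bar([k for k, _ in regions], [v for _, v in regions], color="#4878d0")
    axes[0].set_ylabel("alleles")
    axes[0].set_title("Allele variants by domain region")
    axes[0].tick_params(axis="x", rotation=45)
    types = sorted(report.summary.allele_type_counts.items())
    axes[1].bar([k for k, _ in types], [v for _, v in types], color="#ee854a")
    axes[1].set_title("Allele variants by mutation type")
    axes[1].tick_params(axis="x", rotation=45)
    fig.tight_layout()
    p = out / "allele_distribution.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
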