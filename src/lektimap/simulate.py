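"""Synthetic Netherton-syndrome cohorts with a known generative model.

No individual-level dataset ships with this package, so every pipeline
stage is exercised against simulated cohorts whose generative model mirrors
the statistical structure the analysis assumes:

* each patient carries two *SPINK5* alleles; with probability
  ``homozygous_fraction`` (default 89/162, the published homozygote share)
  the two alleles are identical;
* each allele draws a domain region (or the non-domain class) from
  ``region_weights`` — defaults are the published 324-allele region counts
  126:12:14:23:107:42 — then a codon uniformly within that region's span,
  then a mutation type from ``type_weights`` (published counts
  99:93:85:33:7:6:1 for nonsense, splicing, deletion, duplication,
  insertion, missense, deletion/insertion);
* age is uniform on ``age_range`` (default 0-18 years, a synthetic
  convention for a pediatric-skewed cohort);
* each phenotype is Bernoulli with logit equal to
  ``intercept + sum(beta_v * covariate_v) + beta_age * age`` computed on
  the patient's coded genotype, then masked to NA
  missing-completely-at-random with probability ``missingness[phenotype]``
  (defaults are the published NA rates);
* optional ``fatal_variant_rules`` make named variants lethal in the
  homozygous state with a given probability.

Default phenotype intercepts are the logits of the published complete-case
prevalences with all genotype effects at zero, so the generator's defaults
describe the study conditions and effect sizes are opt-in.

Everything is driven by one ``numpy.random.default_rng(seed)`` stream, so
a config plus seed fully determines the cohort on any platform.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .coding import build_dataset, code_alleles
from .cohort import PHENOTYPES, PatientRecord, PhenotypeStatus
from .domains import DomainTable, annotate_variant, lekti_domain_table
from .errors import ConfigError, StatsError
from .stats import fit_logistic
from .transcript import MutationType, TranscriptModel, parse_hgvs, spink5_transcript

__all__ = [
    "PhenotypeModel",
    "SimulationConfig",
    "RecoveryResult",
    "REGION_LABELS",
    "DEFAULT_REGION_WEIGHTS",
    "DEFAULT_TYPE_WEIGHTS",
    "DEFAULT_HOMOZYGOUS_FRACTION",
    "default_phenotype_models",
    "default_missingness",
    "simulate_cohort",
    "recovery_study",
]

REGION_LABELS = (
    "DomainR-1",
    "DomainR-2",
    "DomainR-3",
    "DomainR-4",
    "DomainR-5",
    "non-domain",
)

# Published allele tallies over 324 alleles (regions, then mutation types).
_REGION_COUNTS = (126, 12, 14, 23, 107, 42)
_TYPE_COUNTS = {
    MutationType.NONSENSE: 99,
    MutationType.SPLICING: 93,
    MutationType.DELETION: 85,
    MutationType.DUPLICATION: 33,
    MutationType.INSERTION: 7,
    MutationType.MISSENSE: 6,
    MutationType.DELETION_INSERTION: 1,
}

DEFAULT_REGION_WEIGHTS: Dict[str, float] = {
    label: c / 324 for label, c in zip(REGION_LABELS, _REGION_COUNTS)
}
DEFAULT_TYPE_WEIGHTS: Dict[MutationType, float] = {
    t: c / 324 for t, c in _TYPE_COUNTS.items()
}
DEFAULT_HOMOZYGOUS_FRACTION = 89 / 162

# Published complete-case prevalences (present / (present + absent)) and
# NA rates (unknown / 162) per phenotype.
_PREVALENCE = {
    "ilc": 73 / 100,
    "erythroderma": 124 / 142,
    "hair_shaft_anomalies": 120 / 134,
    "failure_to_thrive": 56 / 73,
    "recurrent_infection": 79 / 95,
    "hypernatremia": 31 / 56,
    "angioedema": 12 / 35,
    "urticaria": 12 / 44,
    "asthma": 16 / 50,
}
_NA_RATE = {
    "ilc": 62 / 162,
    "erythroderma": 20 / 162,
    "hair_shaft_anomalies": 28 / 162,
    "failure_to_thrive": 89 / 162,
    "recurrent_infection": 67 / 162,
    "hypernatremia": 106 / 162,
    "angioedema": 127 / 162,
    "urticaria": 118 / 162,
    "asthma": 112 / 162,
}


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass
class PhenotypeModel:
    """Logistic link for one phenotype: logit p = intercept + betas . x + beta_age * age."""

    intercept: float
    betas: Dict[str, float] = field(default_factory=dict)
    beta_age: float = 0.0


def default_phenotype_models() -> Dict[str, PhenotypeModel]:
    return {p: PhenotypeModel(intercept=_logit(_PREVALENCE[p])) for p in PHENOTYPES}


def default_missingness() -> Dict[str, float]:
    return dict(_NA_RATE)


@dataclass
class SimulationConfig:
    seed: int
    n_patients: int = 162
    homozygous_fraction: float = DEFAULT_HOMOZYGOUS_FRACTION
    region_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    type_weights: Dict[MutationType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    phenotype_models: Dict[str, PhenotypeModel] = field(
        default_factory=default_phenotype_models
    )
    missingness: Dict[str, float] = field(default_factory=default_missingness)
    age_range: Tuple[float, float] = (0.0, 18.0)
    fatal_variant_rules: List[Tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        for name, weights, keys in (
            ("region_weights", self.region_weights, set(REGION_LABELS)),
            ("type_weights", self.type_weights, set(MutationType)),
        ):
            if set(weights) != keys:
                raise ConfigError(f"{name} keys must be exactly {sorted(map(str, keys))}")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name} contains a negative weight")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(weights.values())!r})")
        probs = [self.homozygous_fraction, *self.missingness.values()]
        probs += [p for _, p in self.fatal_variant_rules]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if not self.age_range[0] <= self.age_range[1]:
            raise ConfigError(f"invalid age_range {self.age_range}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "type_weights" in raw:
            raw["type_weights"] = {
                MutationType(k): float(v) for k, v in raw["type_weights"].items()
            }
        if "phenotype_models" in raw:
            raw["phenotype_models"] = {
                k: PhenotypeModel(**v) for k, v in raw["phenotype_models"].items()
            }
        if "fatal_variant_rules" in raw:
            raw["fatal_variant_rules"] = [
                (str(v), float(p)) for v, p in raw["fatal_variant_rules"]
            ]
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


def _region_codon_pools(table: DomainTable, protein_length: int) -> Dict[str, np.ndarray]:
    """Codon pools per region label; non-domain = all codons in no domain."""
    pools: Dict[str, List[int]] = {label: [] for label in REGION_LABELS}
    in_domain = set()
    for d in table.domains:
        label = f"DomainR-{table.region_of_domain(d.index)}"
        pools[label].extend(range(d.aa_start, d.aa_end + 1))
        in_domain.update(range(d.aa_start, d.aa_end + 1))
    pools["non-domain"] = [
        aa for aa in range(1, protein_length + 1) if aa not in in_domain
    ]
    return {k: np.asarray(v, dtype=int) for k, v in pools.items()}


def _draw_hgvs(
    rng: np.random.Generator, codon: int, mtype: MutationType
) -> Tuple[str, Optional[str]]:
    """Synthesize one HGVS c. string (and protein consequence if needed)
    anchored inside the given codon, realizing the requested mutation type."""
    base = 3 * codon - int(rng.integers(0, 3))
    if mtype is MutationType.SPLICING:
        off = int(rng.integers(1, 21)) * (1 if rng.random() < 0.5 else -1)
        return f"c.{base}{off:+d}G>A", None
    if mtype is MutationType.NONSENSE:
        return f"c.{base}C>T", f"p.(Gln{codon}*)"
    if mtype is MutationType.MISSENSE:
        return f"c.{base}G>A", f"p.(Gly{codon}Asp)"
    if mtype is MutationType.DELETION:
        return f"c.{base}delT", None
    if mtype is MutationType.DUPLICATION:
        return f"c.{base}dupA", None
    if mtype is MutationType.INSERTION:
        return f"c.{base}_{base + 1}insA", None
    return f"c.{base}_{base + 1}delinsTT", None


def simulate_cohort(
    config: SimulationConfig,
    transcript: Optional[TranscriptModel] = None,
    table: Optional[DomainTable] = None,
) -> Tuple[List[PatientRecord], dict]:
    """Draw one cohort; returns (records, ground-truth latent parameters)."""
    t = transcript if transcript is not None else spink5_transcript()
    tab = table if table is not None else lekti_domain_table()
    rng = np.random.default_rng(config.seed)
    pools = _region_codon_pools(tab, t.protein_length)

    region_labels = list(REGION_LABELS)
    region_p = np.asarray([config.region_weights[r] for r in region_labels])
    type_list = list(config.type_weights)
    type_p = np.asarray([config.type_weights[k] for k in type_list])
    fatal_rules = {parse_hgvs(v, t).normalized: p for v, p in config.fatal_variant_rules}

    def draw_allele():
        region = region_labels[rng.choice(len(region_labels), p=region_p)]
        codon = int(rng.choice(pools[region]))
        mtype = type_list[rng.choice(len(type_list), p=type_p)]
        hgvs, protein = _draw_hgvs(rng, codon, mtype)
        ann = annotate_variant(
            parse_hgvs(hgvs, t), t, protein_consequence=protein, table=tab
        )
        return ann, protein

    records: List[PatientRecord] = []
    for i in range(config.n_patients):
        a1, p1 = draw_allele()
        if rng.random() < config.homozygous_fraction:
            a2, p2 = a1, p1
        else:
            a2, p2 = draw_allele()
        age = round(float(rng.uniform(*config.age_range)), 2)
        coded = code_alleles(a1, a2)

        phenotypes: Dict[str, PhenotypeStatus] = {}
        for name in PHENOTYPES:
            model = config.phenotype_models[name]
            lp = model.intercept + model.beta_age * age
            for var, beta in model.betas.items():
                value = coded.value(var)
                if value is not None:  # missing covariate contributes nothing
                    lp += beta * value
            present = rng.random() < 1.0 / (1.0 + math.exp(-lp))
            status = PhenotypeStatus.PRESENT if present else PhenotypeStatus.ABSENT
            if rng.random() < config.missingness.get(name, 0.0):
                status = PhenotypeStatus.UNKNOWN
            phenotypes[name] = status

        died = PhenotypeStatus.ABSENT
        hom_variant = a1.variant.normalized if a1 is a2 else None
        if hom_variant is not None and hom_variant in fatal_rules:
            if rng.random() < fatal_rules[hom_variant]:
                died = PhenotypeStatus.PRESENT
                age = round(float(rng.uniform(0.0, 1.0)), 2)

        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:05d}",
                source="simulated",
                age=age,
                allele1=a1,
                allele2=a2,
                phenotypes=phenotypes,
                died_in_infancy=died,
                allele1_protein=p1,
                allele2_protein=p2,
            )
        )

    ground_truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "homozygous_fraction": config.homozygous_fraction,
        "phenotype_models": {
            name: dataclasses.asdict(m) for name, m in config.phenotype_models.items()
        },
        "fatal_variant_rules": dict(fatal_rules),
    }
    return records, ground_truth


@dataclass
class RecoveryResult:
    """Monte-Carlo summary for one coefficient of the phenotype model."""

    phenotype: str
    variable: str
    true_beta: float
    n_replicates: int
    n_converged: int
    mean_beta: float
    bias: float
    sd_beta: float
    ci_coverage: float
    rejection_rate: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def recovery_study(
    config: SimulationConfig,
    n_replicates: int,
    phenotype: str = "failure_to_thrive",
    variable: str = "halfx",
    alpha: float = 0.05,
) -> RecoveryResult:
    """Repeated simulate → code → fit cycles for one phenotype/covariate.

    Reports mean estimate, bias against the generating coefficient, 95%
    Wald CI coverage of the truth and the Wald rejection rate at ``alpha``
    (the type-I error under a null configuration). Replicates that fail to
    converge are counted and dropped, not fatal.
    """
    true_beta = config.phenotype_models[phenotype].betas.get(variable, 0.0)
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_replicates)

    betas, ses, pvals = [], [], []
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        records, _ = simulate_cohort(cfg)
        try:
            model_table, _ = build_dataset(records, variable, phenotype)
            res = fit_logistic(model_table, phenotype, variable)
        except StatsError:
            continue
        if not (res.converged and np.isfinite(res.beta) and np.isfinite(res.se)):
            continue
        betas.append(res.beta)
        ses.append(res.se)
        pvals.append(res.p_value)

    betas_a = np.asarray(betas)
    ses_a = np.asarray(ses)
    pvals_a = np.asarray(pvals)
    n_ok = len(betas_a)
    if n_ok == 0:
        raise StatsError("no replicate converged; cannot summarize recovery")
    covered = (betas_a - 1.96 * ses_a <= true_beta) & (
        true_beta <= betas_a + 1.96 * ses_a
    )
    return RecoveryResult(
        phenotype=phenotype,
        variable=variable,
        true_beta=true_beta,
        n_replicates=n_replicates,
        n_converged=n_ok,
        mean_beta=float(betas_a.mean()),
        bias=float(betas_a.mean() - true_beta),
        sd_beta=float(betas_a.std(ddof=1)) if n_ok > 1 else 0.0,
        ci_coverage=float(covered.mean()),
        rejection_rate=float((pvals_a < alpha).mean()),
    )
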