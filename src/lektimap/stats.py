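"""Association statistics: logistic fits, odds ratios, fatal-variant 2x2.

The genotype-phenotype model is a binary logistic regression of one coded
genotype covariate plus age (all covariates entered simultaneously, no
selection), reported as the odds ratio per covariate unit with a Wald 95%
confidence interval exp(beta +/- 1.96 se) and a Wald z-test p-value.

A "fatal variant" is defined operationally: a variant with at least one
homozygous carrier who died during infancy. Carriers of fatal variants are
cross-tabulated (homozygous vs heterozygous carriage x died in infancy vs
survived) and tested with a Pearson chi-square on 1 df; the Yates
continuity correction is available behind a flag but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import PatientRecord, PhenotypeStatus
from .errors import StatsError

__all__ = [
    "AssociationResult",
    "ContingencyResult",
    "FatalVariantStats",
    "FatalVariantSet",
    "fit_logistic",
    "odds_ratio_ci",
    "chi_square_2x2",
    "identify_fatal_variants",
    "fatal_contingency",
]

_Z95 = 1.96  # Wald normal quantile used for 95% CIs
_SEPARATION_BETA = 15.0  # |beta| beyond this is treated as divergence


@dataclass
class AssociationResult:
    phenotype: str
    variable: str
    n_used: int
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    age_in_model: bool = True

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "variable": self.variable,
            "n_used": self.n_used,
            "beta": self.beta,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "converged": self.converged,
            "age_in_model": self.age_in_model,
        }


def odds_ratio_ci(beta: float, se: float) -> Tuple[float, float, float]:
    """OR and 95% Wald bounds: exp(beta), exp(beta -/+ 1.96 se)."""
    if se < 0:
        raise StatsError(f"negative standard error {se}")
    with np.errstate(over="ignore"):  # diverged fits may overflow to inf
        return (
            float(np.exp(beta)),
            float(np.exp(beta - _Z95 * se)),
            float(np.exp(beta + _Z95 * se)),
        )


def fit_logistic(
    table: pd.DataFrame,
    phenotype: str = "",
    variable: str = "covariate",
) -> AssociationResult:
    """Maximum-likelihood logit fit of outcome ~ covariate + age.

    ``table`` must hold 0/1 ``outcome``, numeric ``covariate`` and ``age``
    columns (the shape produced by :func:`lektimap.coding.build_dataset`).
    A constant age column is collinear with the intercept and is dropped
    (recorded via ``age_in_model``). Non-convergence and separation are
    reported through ``converged=False``, never silently.
    """
    y = table["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise StatsError("outcome is constant; logistic model is undefined")
    if table["covariate"].nunique() < 2:
        raise StatsError("covariate is constant; its effect is not estimable")

    age_in_model = table["age"].nunique() > 1
    cols = ["covariate", "age"] if age_in_model else ["covariate"]
    X = sm.add_constant(table[cols].astype(float), has_constant="add")

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                disp=0, maxiter=100, tol=1e-8, warn_convergence=False
            )
        beta = float(res.params["covariate"])
        se = float(res.bse["covariate"])
        p = float(res.pvalues["covariate"])
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, PerfectSeparationError):
        beta, se, p, converged = float("nan"), float("nan"), float("nan"), False

    if converged and (not np.isfinite(beta) or abs(beta) > _SEPARATION_BETA):
        converged = False  # quasi-separation: estimate diverging
    if np.isfinite(beta) and np.isfinite(se):
        or_, lo, hi = odds_ratio_ci(beta, se)
    else:
        or_, lo, hi = float("nan"), float("nan"), float("nan")
    return AssociationResult(
        phenotype=phenotype,
        variable=variable,
        n_used=len(table),
        beta=beta,
        se=se,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        converged=converged,
        age_in_model=age_in_model,
    )


@dataclass
class ContingencyResult:
    table: np.ndarray  # rows: homozygous / heterozygous carriers; cols: died / survived
    chi2: float
    df: int
    p_value: float
    yates: bool

    def to_dict(self) -> dict:
        return {
            "table": [[int(x) for x in row] for row in self.table],
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "yates": self.yates,
        }


def chi_square_2x2(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table (optional continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("table entries must be non-negative integers")
    t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError(
            "a table margin is zero; the chi-square approximation is undefined "
            "— use an exact test"
        )
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=yates)
    return ContingencyResult(
        table=t, chi2=float(chi2), df=int(dof), p_value=float(p), yates=yates
    )


@dataclass
class FatalVariantStats:
    hgvs: str
    homozygous_carriers: int = 0
    homozygous_deaths: int = 0
    heterozygous_carriers: int = 0
    heterozygous_deaths: int = 0


@dataclass
class FatalVariantSet:
    """Variants with >= 1 homozygous carrier who died during infancy."""

    variants: Dict[str, FatalVariantStats] = field(default_factory=dict)

    @property
    def names(self) -> List[str]:
        return sorted(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, hgvs: str) -> bool:
        return hgvs in self.variants


def _carriage(record: PatientRecord, hgvs: str) -> int:
    """Number of alleles (0/1/2) of ``hgvs`` carried by the patient."""
    return sum(
        a.variant.normalized == hgvs for a in (record.allele1, record.allele2)
    )


def identify_fatal_variants(records: Sequence[PatientRecord]) -> FatalVariantSet:
    """Scan the cohort for variants homozygous in at least one infant death.

    Carrier and death tallies are attached per variant. An empty set (no
    infant deaths among homozygotes) is a valid outcome, not an error.
    """
    # candidate pass: which variants are homozygous-lethal at least once
    fatal: Dict[str, FatalVariantStats] = {}
    for r in records:
        if (
            r.is_homozygous
            and r.died_in_infancy is PhenotypeStatus.PRESENT
        ):
            hgvs = r.allele1.variant.normalized
            fatal.setdefault(hgvs, FatalVariantStats(hgvs))
    # tally pass
    for r in records:
        for hgvs, st in fatal.items():
            n = _carriage(r, hgvs)
            if n == 2:
                st.homozygous_carriers += 1
                if r.died_in_infancy is PhenotypeStatus.PRESENT:
                    st.homozygous_deaths += 1
            elif n == 1:
                st.heterozygous_carriers += 1
                if r.died_in_infancy is PhenotypeStatus.PRESENT:
                    st.heterozygous_deaths += 1
    return FatalVariantSet(variants=fatal)


def fatal_contingency(
    records: Sequence[PatientRecord],
    fatal_set: FatalVariantSet,
    yates: bool = False,
) -> ContingencyResult:
    """2x2 of fatal-variant carriage (homozygous vs heterozygous) x infant death.

    Row 1: patients homozygous for a fatal variant. Row 2: patients carrying
    fatal-variant alleles without being homozygous for one (including the
    synthetic edge case of two different fatal variants in trans). Patients
    with unknown death status are dropped; non-carriers do not enter.
    """
    if not fatal_set.variants:
        raise StatsError("fatal-variant set is empty; nothing to cross-tabulate")
    table = np.zeros((2, 2), dtype=int)
    for r in records:
        hom = r.is_homozygous and r.allele1.variant.normalized in fatal_set
        het = (not hom) and any(
            _carriage(r, hgvs) >= 1 for hgvs in fatal_set.variants
        )
        if not (hom or het):
            continue
        if r.died_in_infancy is PhenotypeStatus.UNKNOWN:
            continue
        row = 0 if hom else 1
        col = 0 if r.died_in_infancy is PhenotypeStatus.PRESENT else 1
        table[row, col] += 1
    return chi_square_2x2(table, yates=yates)
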