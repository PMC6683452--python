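"""Case-control association statistics for candidate regulatory SNPs.

Implements the battery applied to each genotyped candidate: Hardy–Weinberg
equilibrium in controls, the 2×3 genotype χ² test, collapsed allele /
dominant / recessive 2×2 tables with cross-product odds ratios and Wald 95%
confidence intervals, covariate-adjusted logistic regression, and power of
the genetic χ² test.

Conventions (chosen to reproduce published two-decimal tables from their
printed counts): Pearson χ² without Yates continuity correction throughout;
Wald log-scale CI with z = 1.96; no Haldane–Anscombe zero-cell correction —
a zero case-exposed cell reports OR = 0 with CI (0, ∞), a zero denominator
cell OR = ∞.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GeneticModel",
    "GenotypeCounts",
    "Contingency2x2",
    "AssociationResult",
    "PowerSpec",
    "hwe_test",
    "genotype_chisq",
    "build_model_tables",
    "odds_ratio",
    "adjusted_logistic",
    "power_genetic",
    "genotype_counts_from_subjects",
]

_Z95 = 1.96


class GeneticModel(Enum):
    GENOTYPE = "genotype"
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


@dataclass
class GenotypeCounts:
    """2×3 genotype counts, genotypes ordered (AA, Aa, aa), a = minor/risk allele.

    Row sums may be below the cohort sizes (missing genotypes are allowed and
    excluded from all statistics).
    """

    snp_id: str
    control: tuple[int, int, int]
    case: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in (*self.control, *self.case)):
            raise ValueError("genotype counts must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array([self.control, self.case], dtype=float)


@dataclass(frozen=True)
class Contingency2x2:
    """(case-exposed, case-unexposed; control-exposed, control-unexposed)."""

    a: int  # case, exposed
    b: int  # case, unexposed
    c: int  # control, exposed
    d: int  # control, unexposed

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass
class AssociationResult:
    snp_id: str
    model: GeneticModel
    or_estimate: float
    ci95: tuple[float, float]
    p_value: float
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    separation: bool = False


def hwe_test(control_genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Pearson χ² (1 df) goodness-of-fit to Hardy–Weinberg proportions.

    Expected counts derive from the observed allele frequency:
    (n·p̂², 2·n·p̂·q̂, n·q̂²).  Tested in controls by convention.
    """
    obs = np.asarray(control_genotype_counts, dtype=float)
    if obs.shape != (3,) or obs.min() < 0:
        raise ValueError("expected a 3-vector of non-negative genotype counts")
    n = obs.sum()
    if n == 0:
        raise ValueError("zero total genotype count")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1 - p
    exp = n * np.array([p * p, 2 * p * q, q * q])
    if p in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: trivially in equilibrium
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_chisq(counts: GenotypeCounts) -> float:
    """Pearson χ² p-value for the 2×3 genotype table (df = 2, no correction).

    Genotype columns that are empty in both groups are dropped, reducing the
    degrees of freedom, with a warning.
    """
    t = counts.table
    nonzero = t.sum(axis=0) > 0
    if not nonzero.all():
        warnings.warn(
            f"{counts.snp_id}: empty genotype column(s); df reduced to "
            f"{nonzero.sum() - 1}",
            stacklevel=2,
        )
        t = t[:, nonzero]
    _, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


def build_model_tables(counts: GenotypeCounts) -> dict[GeneticModel, Contingency2x2]:
    """Collapse a 2×3 genotype table into allele / dominant / recessive 2×2s.

    Allele: 2·AA+Aa major alleles vs Aa+2·aa minor alleles per group.
    Dominant: carriers (Aa+aa) vs AA.  Recessive: aa vs (AA+Aa).
    "Exposed" is the risk category of each dichotomy (minor allele, carrier,
    minor homozygote respectively).
    """
    cAA, cAa, caa = counts.control
    kAA, kAa, kaa = counts.case
    return {
        GeneticModel.ALLELE: Contingency2x2(
            a=2 * kaa + kAa, b=2 * kAA + kAa, c=2 * caa + cAa, d=2 * cAA + cAa
        ),
        GeneticModel.DOMINANT: Contingency2x2(
            a=kAa + kaa, b=kAA, c=cAa + caa, d=cAA
        ),
        GeneticModel.RECESSIVE: Contingency2x2(
            a=kaa, b=kAA + kAa, c=caa, d=cAA + cAa
        ),
    }


def odds_ratio(t: Contingency2x2, snp_id: str = "", model: GeneticModel | None = None) -> AssociationResult:
    """Cross-product odds ratio with Wald 95% CI and Pearson χ² p-value.

    OR = ad/bc; CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  Zero-cell policy:
    a = 0 → OR 0 with CI (0, ∞); b or c = 0 → OR ∞; no 0.5 correction.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    num_zero = a == 0 or d == 0
    den_zero = b == 0 or c == 0
    if num_zero and den_zero:
        orr, ci = math.nan, (0.0, math.inf)
    elif num_zero:
        orr, ci = 0.0, (0.0, math.inf)
    elif den_zero:
        orr, ci = math.inf, (0.0, math.inf)
    else:
        orr = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (
            math.exp(math.log(orr) - _Z95 * se),
            math.exp(math.log(orr) + _Z95 * se),
        )
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        p = 1.0
    return AssociationResult(
        snp_id=snp_id,
        model=model or GeneticModel.GENOTYPE,
        or_estimate=orr,
        ci95=ci,
        p_value=float(p),
    )


def _code_genotype(g: pd.Series, model: GeneticModel) -> pd.DataFrame:
    """Numeric design columns for a genotype count of minor alleles (0/1/2)."""
    if model is GeneticModel.DOMINANT:
        return pd.DataFrame({"carrier": (g >= 1).astype(float)})
    if model is GeneticModel.RECESSIVE:
        return pd.DataFrame({"homozygote": (g == 2).astype(float)})
    if model is GeneticModel.ALLELE:
        return pd.DataFrame({"additive": g.astype(float)})
    return pd.DataFrame(
        {"het": (g == 1).astype(float), "hom": (g == 2).astype(float)}
    )


def adjusted_logistic(
    subjects: pd.DataFrame,
    snp_col: str,
    model: GeneticModel = GeneticModel.RECESSIVE,
    covariates: Sequence[str] = ("sex", "age", "bmi", "htn", "dm"),
    group_col: str = "group",
) -> AssociationResult:
    """Covariate-adjusted logistic regression odds ratio for a genetic term.

    ``subjects[snp_col]`` holds minor-allele dosage 0/1/2 (NaN = missing,
    dropped).  ``group_col`` is 1 for cases, 0 for controls.  Returns
    exp(coefficient) for the (first) genetic term with Wald 95% CI and p.
    Perfect separation is flagged rather than raised.
    """
    df = subjects.dropna(subset=[snp_col, group_col, *covariates]).copy()
    y = df[group_col].astype(float)
    if y.nunique() < 2:
        raise ValueError("need at least one case and one control")
    X = _code_genotype(df[snp_col], model)
    term = X.columns[0]
    for cov in covariates:
        X[cov] = df[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
            beta = fit.params[term]
            se = fit.bse[term]
            if not np.isfinite(se) or abs(beta) > 30:
                separation = True
        except Exception:
            separation, beta, se = True, math.inf, math.inf
    if separation:
        return AssociationResult(
            snp_id=snp_col, model=model, or_estimate=math.inf,
            ci95=(0.0, math.inf), p_value=1.0, adjusted=bool(covariates),
            covariates=tuple(covariates), separation=True,
        )
    z = beta / se
    return AssociationResult(
        snp_id=snp_col,
        model=model,
        or_estimate=math.exp(beta),
        ci95=(math.exp(beta - _Z95 * se), math.exp(beta + _Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        adjusted=bool(covariates),
        covariates=tuple(covariates),
    )


@dataclass
class PowerSpec:
    """Design for a genetic-model χ² power computation."""

    n_case: int
    n_control: int
    target_or: float
    alpha: float = 0.05
    model: GeneticModel = GeneticModel.RECESSIVE

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.target_or <= 0:
            raise ValueError("target_or must be positive")


def _exposure_probs(control_genotype_freqs: Sequence[float], model: GeneticModel,
                    target_or: float) -> tuple[float, float]:
    """(case, control) exposure probabilities under the model and OR."""
    p0 = np.asarray(control_genotype_freqs, dtype=float)
    if p0.shape != (3,) or abs(p0.sum() - 1) > 1e-6 or p0.min() < 0:
        raise ValueError("control genotype frequencies must be a 3-simplex vector")
    if model is GeneticModel.RECESSIVE:
        exp_ctrl = p0[2]
    elif model is GeneticModel.DOMINANT:
        exp_ctrl = p0[1] + p0[2]
    elif model is GeneticModel.ALLELE:
        exp_ctrl = p0[2] + p0[1] / 2  # minor-allele frequency
    else:
        raise ValueError("power computation needs a dichotomous model")
    if exp_ctrl in (0.0, 1.0):
        raise ValueError("degenerate control exposure frequency")
    odds = target_or * exp_ctrl / (1 - exp_ctrl)
    exp_case = odds / (1 + odds)
    return exp_case, exp_ctrl


def power_genetic(spec: PowerSpec, control_genotype_freqs: Sequence[float]) -> float:
    """Power of the 2×2 Pearson χ² test at ``spec.alpha``.

    Uses the noncentral-χ² approximation: the noncentrality is N times the
    discrepancy between the alternative's cell probabilities and the nearest
    independence table (the one sharing its margins).
    """
    p_case, p_ctrl = _exposure_probs(control_genotype_freqs, spec.model, spec.target_or)
    n1, n0 = spec.n_case, spec.n_control
    N = n1 + n0
    f1, f0 = n1 / N, n0 / N
    # joint cell probabilities under the alternative
    alt = np.array(
        [[f1 * p_case, f1 * (1 - p_case)], [f0 * p_ctrl, f0 * (1 - p_ctrl)]]
    )
    row = alt.sum(axis=1, keepdims=True)
    col = alt.sum(axis=0, keepdims=True)
    null = row @ col
    lam = N * float(((alt - null) ** 2 / null).sum())
    crit = stats.chi2.isf(spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def genotype_counts_from_subjects(
    subjects: pd.DataFrame, snp_col: str, snp_id: str | None = None,
    group_col: str = "group",
) -> GenotypeCounts:
    """Tabulate minor-allele dosage (0/1/2) into a 2×3 count structure.

    Missing genotypes (NaN) are excluded, so totals can fall short of the
    cohort sizes.
    """
    df = subjects.dropna(subset=[snp_col])
    if (df[group_col] == 1).sum() == 0:
        raise ValueError("empty case group")
    if (df[group_col] == 0).sum() == 0:
        raise ValueError("empty control group")

    def _row(mask: pd.Series) -> tuple[int, int, int]:
        g = df.loc[mask, snp_col].astype(int)
        return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))

    return GenotypeCounts(
        snp_id=snp_id or snp_col,
        control=_row(df[group_col] == 0),
        case=_row(df[group_col] == 1),
    )
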