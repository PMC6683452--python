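"""ChIP-qPCR percent-input quantification and per-genotype comparison.

Percent input normalises the immunoprecipitated (IP) qPCR signal to the
fraction of chromatin reserved as input: the input Ct is first shifted by
log2(1/input_fraction) to what a 100% input would have given, then

    percent_input = 100 × 2^(adjusted_input_ct − ct_ip).

Group summaries report mean ± SEM per genotype and a one-way fixed-effects
ANOVA across genotype groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "GroupSummary",
    "percent_input",
    "group_summary",
    "anova_oneway",
    "enrichment_ratio",
    "read_ct_table",
    "quantify",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired IP/input Ct values for one sample."""

    sample: str
    genotype: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.input_fraction <= 1):
            raise ValueError(f"input_fraction must be in (0, 1], got {self.input_fraction}")
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_input)):
            raise ValueError("Ct values must be finite")
        if self.ct_ip <= 0 or self.ct_input <= 0:
            raise ValueError("Ct values must be positive")


@dataclass
class GroupSummary:
    genotype: str
    n: int
    mean: float
    sem: float  # NaN when n == 1 (undefined)


def percent_input(m: QpcrMeasurement) -> float:
    """Percent of input chromatin recovered in the IP, from the ΔCt.

    Strictly decreasing in ``ct_ip`` and increasing in ``input_fraction``.
    """
    adjusted_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - m.ct_ip)


def group_summary(measurements: Sequence[QpcrMeasurement]) -> dict[str, GroupSummary]:
    """Per-genotype mean and SEM (= sd/√n, ddof=1) of percent input.

    A singleton group gets SEM = NaN (flagged undefined rather than zero).
    """
    values: dict[str, list[float]] = {}
    for m in measurements:
        values.setdefault(m.genotype, []).append(percent_input(m))
    out = {}
    for g, xs in values.items():
        arr = np.asarray(xs)
        n = arr.size
        sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        out[g] = GroupSummary(genotype=g, n=n, mean=float(arr.mean()), sem=sem)
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p) with (k−1, N−k) df.

    With two groups F equals the squared equal-variance t statistic.
    All-identical groups give F = 0, p = 1.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


def enrichment_ratio(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Fold enrichment of group a over group b.

    Returns (ratio, difference): published "x-fold enrichment" statements are
    sometimes the ratio of percent-input means and sometimes their difference,
    so both are reported and neither is silently preferred.
    """
    if mean_b == 0:
        raise ValueError("zero denominator mean")
    return mean_a / mean_b, mean_a - mean_b


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a Ct TSV (sample, genotype, ct_ip, ct_input, input_fraction)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "genotype", "ct_ip", "ct_input"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "input_fraction" not in df.columns:
        df["input_fraction"] = 0.01
    return [
        QpcrMeasurement(
            sample=str(r["sample"]),
            genotype=str(r["genotype"]),
            ct_ip=float(r["ct_ip"]),
            ct_input=float(r["ct_input"]),
            input_fraction=float(r["input_fraction"]),
        )
        for _, r in df.iterrows()
    ]


def quantify(measurements: Sequence[QpcrMeasurement]) -> pd.DataFrame:
    """Full quantification: per-sample percent input with group labels.

    Returns a tidy frame (sample, genotype, percent_input); use
    :func:`group_summary` / :func:`anova_oneway` for the comparisons.
    """
    return pd.DataFrame(
        {
            "sample": [m.sample for m in measurements],
            "genotype": [m.genotype for m in measurements],
            "percent_input": [percent_input(m) for m in measurements],
        }
    )
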