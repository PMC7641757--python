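"""Population-level statistics over per-individual metric values.

The workflow mirrors a standard stratified comparison: a one-way ANOVA per
(gene, codon, metric) asks whether any population differs; Bonferroni
thresholds are derived from the number of tests actually run; pairwise
t-tests localise significant ANOVAs to population pairs; Cohen's d sizes the
significant differences; Tukey's HSD gives range-corrected pairwise
comparisons for small test families such as per-variant minor-allele
frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PopulationAssignment:
    """sample → (subpopulation, superpopulation) mapping."""

    subpopulation: Mapping[str, str]
    superpopulation: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.subpopulation) != set(self.superpopulation):
            raise ValueError("sub- and superpopulation maps must cover the same samples")
        # a subpopulation may not straddle two superpopulations
        seen: dict[str, str] = {}
        for sample, sub in self.subpopulation.items():
            sup = self.superpopulation[sample]
            if seen.setdefault(sub, sup) != sup:
                raise ValueError(
                    f"subpopulation {sub} maps to multiple superpopulations"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationAssignment":
        """Build from a DataFrame with columns sample, subpopulation, superpopulation."""
        return cls(
            subpopulation=dict(zip(frame["sample"], frame["subpopulation"])),
            superpopulation=dict(zip(frame["sample"], frame["superpopulation"])),
        )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.subpopulation)

    def group_of(self, sample: str, level: str = "superpopulation") -> str:
        mapping = (
            self.superpopulation if level == "superpopulation" else self.subpopulation
        )
        return mapping[sample]

    def groups(self, level: str = "superpopulation") -> tuple[str, ...]:
        mapping = (
            self.superpopulation if level == "superpopulation" else self.subpopulation
        )
        return tuple(sorted(set(mapping.values())))


@dataclass(frozen=True)
class GroupedValues:
    """Per-group value lists for one (metric, gene, codon) cell."""

    values: Mapping[str, np.ndarray]
    metric: str = ""
    gene: str = ""
    codon: str = ""

    @classmethod
    def from_lists(cls, values: Mapping[str, Sequence[float]], **meta) -> "GroupedValues":
        return cls(
            values={g: np.asarray(v, dtype=float) for g, v in values.items()}, **meta
        )

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.values))

    def _context(self) -> str:
        parts = [p for p in (self.metric, self.gene, self.codon) if p]
        return "/".join(parts) or "grouped values"

    def require(self, min_groups: int = 2, min_size: int = 2) -> None:
        if len(self.values) < min_groups:
            raise ValueError(
                f"{self._context()}: need at least {min_groups} groups, "
                f"got {len(self.values)}"
            )
        for name, arr in self.values.items():
            if arr.size < min_size:
                raise ValueError(
                    f"{self._context()}: group {name} has {arr.size} value(s), "
                    f"needs at least {min_size}"
                )


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, p-value, optional effect size."""

    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    effect_size: float | None = None
    threshold: float | None = None
    significant: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        sig = self.threshold is not None and self.p_value < self.threshold
        object.__setattr__(self, "significant", bool(sig))


def one_way_anova(groups: GroupedValues, threshold: float | None = None) -> TestResult:
    """Standard one-way ANOVA across the groups."""
    groups.require()
    f, p = stats.f_oneway(*(groups.values[g] for g in groups.group_names))
    return TestResult(
        statistic=float(f), p_value=float(p), groups=groups.group_names,
        threshold=threshold,
    )


def cohens_d(a, b) -> float:
    """Pooled-standard-deviation effect size ``(mean_a - mean_b) / s_pooled``.

    Returns ``nan`` when the pooled variance is zero (undefined, reported as
    missing rather than infinite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Cohen's d needs at least two values per group")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def pairwise_t_tests(
    groups: GroupedValues,
    threshold: float,
    equal_var: bool = True,
) -> list[TestResult]:
    """t-test for every unordered group pair; Cohen's d for significant ones.

    Student's pooled-variance test by default (consistent with the pooled-sd
    effect size); set ``equal_var=False`` for Welch's test.
    """
    groups.require()
    results = []
    for ga, gb in itertools.combinations(groups.group_names, 2):
        a, b = groups.values[ga], groups.values[gb]
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        effect = cohens_d(a, b) if p < threshold else None
        results.append(
            TestResult(
                statistic=float(t), p_value=float(p), groups=(ga, gb),
                effect_size=effect, threshold=threshold,
            )
        )
    return results


def count_pairwise_tests(n_genes: int, n_codons: int, n_groups: int) -> int:
    """Total pairwise tests over genes × codons × group pairs."""
    if min(n_genes, n_codons, n_groups) <= 0:
        raise ValueError("all counts must be positive")
    return n_genes * n_codons * math.comb(n_groups, 2)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def tukey_hsd(groups: GroupedValues, threshold: float = 0.05) -> list[TestResult]:
    """Tukey's honestly-significant-difference test for all group pairs.

    P-values come from the studentized range distribution, which controls
    the family-wise error across the pairwise comparisons.
    """
    groups.require()
    names = groups.group_names
    res = stats.tukey_hsd(*(groups.values[g] for g in names))
    results = []
    for i, j in itertools.combinations(range(len(names)), 2):
        results.append(
            TestResult(
                statistic=float(res.statistic[i, j]),
                p_value=float(res.pvalue[i, j]),
                groups=(names[i], names[j]),
                threshold=threshold,
            )
        )
    return results


def minor_allele_frequency(
    genotypes: Mapping[str, float],
    assignment: PopulationAssignment,
    level: str = "superpopulation",
) -> dict[str, float]:
    """Per-group frequency of the cohort-wide minor allele.

    ``genotypes`` maps sample → diploid alternate-allele count (0, 1 or 2;
    ``nan`` for missing, which shrinks that group's denominator).  The minor
    allele is defined on the pooled cohort, so an individual group's
    frequency may exceed 0.5.
    """
    alt: dict[str, float] = {}
    n_chrom: dict[str, int] = {}
    pooled_alt = 0.0
    pooled_chrom = 0
    for sample, count in genotypes.items():
        if count is None or (isinstance(count, float) and math.isnan(count)):
            continue
        if count not in (0, 1, 2):
            raise ValueError(f"{sample}: genotype {count!r} is not a diploid count")
        group = assignment.group_of(sample, level)
        alt[group] = alt.get(group, 0.0) + count
        n_chrom[group] = n_chrom.get(group, 0) + 2
        pooled_alt += count
        pooled_chrom += 2
    if pooled_chrom == 0:
        raise ValueError("no called genotypes")
    minor_is_alt = pooled_alt / pooled_chrom <= 0.5
    return {
        g: (alt[g] / n_chrom[g]) if minor_is_alt else 1.0 - alt[g] / n_chrom[g]
        for g in sorted(alt)
    }


def results_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Flatten test results into the output CSV shape."""
    rows = []
    for r in results:
        rows.append(
            {
                "group_a": r.groups[0] if len(r.groups) > 0 else "",
                "group_b": r.groups[1] if len(r.groups) > 1 else "",
                "statistic": r.statistic,
                "p_value": r.p_value,
                "effect_size": r.effect_size,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
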