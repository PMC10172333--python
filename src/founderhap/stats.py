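"""Carrier/allele frequencies, fold-enrichment between cohorts, and the
grandparental-ancestry summary.

Frequencies use exact Clopper–Pearson binomial intervals; fold enrichment
is the ratio of allele frequencies with a log-scale normal-approximation
interval and a two-sided Fisher exact test on the underlying 2x2 allele
table.  For a rare variant the carrier frequency is approximately twice
the allele frequency, since essentially all carriers are heterozygous.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panels import PanelError


@dataclass(frozen=True)
class CohortCount:
    """Risk-allele counts for one diploid cohort.

    ``n_alt_alleles`` defaults to ``n_carriers`` — i.e. every carrier is
    assumed heterozygous — unless given explicitly.
    """

    label: str
    n_individuals: int
    n_carriers: int
    n_alt_alleles: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_carriers <= self.n_individuals:
            raise PanelError(
                f"{self.label}: carriers ({self.n_carriers}) outside "
                f"[0, {self.n_individuals}]"
            )
        if self.n_alt_alleles is None:
            object.__setattr__(self, "n_alt_alleles", self.n_carriers)
        if not self.n_carriers <= self.n_alt_alleles <= 2 * self.n_carriers:
            raise PanelError(
                f"{self.label}: allele count {self.n_alt_alleles} incompatible "
                f"with {self.n_carriers} carriers"
            )

    @property
    def n_alleles(self) -> int:
        """Diploid chromosome count (the allele-frequency denominator)."""
        return 2 * self.n_individuals


@dataclass(frozen=True)
class FrequencyEstimate:
    point: float
    ci_low: float
    ci_high: float
    method: str
    denominator_type: str  # "alleles" | "individuals"
    k: int
    n: int
    level: float


@dataclass(frozen=True)
class EnrichmentResult:
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    focal_af: float
    reference_af: float


@dataclass(frozen=True)
class AncestrySummary:
    counts: dict[str, int]  # descending count, ties by name
    proportions: dict[str, float]
    n_carriers: int
    n_grandparents: int


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, summing the probabilities
    of all tables with the observed margins no more likely than the
    observed one."""
    _, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial interval via beta quantiles."""
    if n < 1:
        raise PanelError("Clopper–Pearson interval needs n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def allele_frequency(
    cohort: CohortCount,
    denominator_type: str = "alleles",
    level: float = 0.95,
) -> FrequencyEstimate:
    """Point frequency with an exact binomial interval.

    ``denominator_type`` "alleles" gives the allele frequency
    (alt alleles / 2N); "individuals" gives the carrier frequency
    (carriers / N).
    """
    if cohort.n_individuals < 1:
        raise PanelError(f"{cohort.label}: zero denominator")
    if denominator_type == "alleles":
        k, n = cohort.n_alt_alleles, cohort.n_alleles
    elif denominator_type == "individuals":
        k, n = cohort.n_carriers, cohort.n_individuals
    else:
        raise PanelError(f"unknown denominator_type {denominator_type!r}")
    lo, hi = clopper_pearson(k, n, level)
    return FrequencyEstimate(
        point=k / n, ci_low=lo, ci_high=hi, method="clopper-pearson",
        denominator_type=denominator_type, k=k, n=n, level=level,
    )


def fold_enrichment(
    focal_cohort: CohortCount,
    reference_cohort: CohortCount,
    level: float = 0.95,
) -> EnrichmentResult:
    """Fold-enrichment of the focal cohort's allele frequency over a reference.

    The ratio is AF_focal / AF_reference on allele denominators.  The
    interval is the standard log-ratio normal approximation with
    ``1/k - 1/n`` variance terms; when the reference has zero risk
    alleles the ratio is infinite and only a lower confidence bound
    (continuity-corrected) is reported.  The p-value is the two-sided
    Fisher exact test on the 2x2 table of risk vs non-risk allele counts,
    summing the probabilities of all tables no more likely than the one
    observed.
    """
    a1, n1 = focal_cohort.n_alt_alleles, focal_cohort.n_alleles
    a2, n2 = reference_cohort.n_alt_alleles, reference_cohort.n_alleles
    if a1 == 0 and a2 == 0:
        raise PanelError("zero risk alleles in both cohorts: enrichment undefined")
    table = ((a1, n1 - a1), (a2, n2 - a2))
    p = fisher_exact_two_sided(table)
    z = float(sps.norm.ppf(0.5 + level / 2))
    af1, af2 = a1 / n1, a2 / n2
    if a2 == 0:
        # continuity correction on the reference count for the bound only
        ratio_cc = af1 / ((a2 + 0.5) / n2)
        se = math.sqrt(1 / max(a1, 0.5) - 1 / n1 + 1 / (a2 + 0.5) - 1 / n2)
        return EnrichmentResult(
            ratio=math.inf, ci_low=ratio_cc * math.exp(-z * se), ci_high=math.inf,
            p_value=float(p), table=table, focal_af=af1, reference_af=af2,
        )
    ratio = af1 / af2
    if a1 == 0:
        ratio_cc = ((a1 + 0.5) / n1) / af2
        se = math.sqrt(1 / (a1 + 0.5) - 1 / n1 + 1 / a2 - 1 / n2)
        return EnrichmentResult(
            ratio=0.0, ci_low=0.0, ci_high=ratio_cc * math.exp(z * se),
            p_value=float(p), table=table, focal_af=af1, reference_af=af2,
        )
    se = math.sqrt(1 / a1 - 1 / n1 + 1 / a2 - 1 / n2)
    return EnrichmentResult(
        ratio=ratio,
        ci_low=ratio * math.exp(-z * se),
        ci_high=ratio * math.exp(z * se),
        p_value=float(p),
        table=table,
        focal_af=af1,
        reference_af=af2,
    )


def carrier_projection(
    freq: FrequencyEstimate, population_size: float
) -> tuple[float, float, float]:
    """Expected carrier count in a population of the given size.

    Scales the point estimate and its interval linearly; useful for
    service planning (how many carriers a screening programme would find).
    """
    if population_size < 0:
        raise PanelError("population_size must be >= 0")
    return (
        freq.point * population_size,
        freq.ci_low * population_size,
        freq.ci_high * population_size,
    )


def ancestry_summary(grandparents) -> AncestrySummary:
    """Summarize grandparental birthplaces over all carriers.

    ``grandparents`` is either a mapping carrier -> 4 birthplaces or a
    DataFrame with columns ``carrier_id, gp1..gp4``.  Unknown birthplaces
    should be recorded as "unknown".  Places are ordered by descending
    count, ties broken by name.
    """
    if isinstance(grandparents, pd.DataFrame):
        cols = ["gp1", "gp2", "gp3", "gp4"]
        if not set(cols) <= set(grandparents.columns):
            raise PanelError("ancestry table needs columns carrier_id, gp1..gp4")
        if grandparents[cols].isna().any().any():
            raise PanelError("every carrier needs exactly 4 grandparent entries")
        table = {
            str(row["carrier_id"]): [str(row[c]) for c in cols]
            for _, row in grandparents.iterrows()
        }
    else:
        table = {str(k): list(v) for k, v in dict(grandparents).items()}
    for cid, gps in table.items():
        if len(gps) != 4:
            raise PanelError(f"carrier {cid} has {len(gps)} grandparent entries, need 4")
    counts = Counter(place for gps in table.values() for place in gps)
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return AncestrySummary(
        counts=dict(ordered),
        proportions={place: c / total for place, c in ordered},
        n_carriers=len(table),
        n_grandparents=total,
    )
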