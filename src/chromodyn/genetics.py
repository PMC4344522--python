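"""Mendelian-ratio statistics for knockout viability cohorts.

A heterozygote intercross should yield offspring genotypes +/+ : +/- : -/-
at 1:2:1.  Published cohorts are often reported as a ratio plus a total
rather than raw counts, so this module provides:

* exact-total reconstruction of integer counts from a printed ratio
  (largest-remainder apportionment),
* a Pearson chi-square goodness-of-fit test against an expected ratio,
* the survival deficit of a genotype (the fraction of expected animals
  missing from the observed distribution),
* an exact two-sided binomial test for sex-ratio skew.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "counts_from_ratio",
    "mendelian_chi2",
    "survival_deficit",
    "sex_ratio_test",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts with the expected Mendelian ratio."""

    labels: tuple[str, ...] = ("+/+", "+/-", "-/-")
    observed: tuple[int, ...] = (0, 0, 0)
    expected_ratio: tuple[float, ...] = (1.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.observed) or len(self.labels) != len(self.expected_ratio):
            raise ValueError("labels, observed and expected_ratio must align")
        if any(c < 0 for c in self.observed):
            raise ValueError("counts must be non-negative")
        if any(r < 0 for r in self.expected_ratio) or all(r == 0 for r in self.expected_ratio):
            raise ValueError("expected_ratio must be non-negative and not all zero")

    @property
    def total(self) -> int:
        return int(sum(self.observed))

    @classmethod
    def from_ratio(cls, ratio: Sequence[float], total: int,
                   labels: Sequence[str] = ("+/+", "+/-", "-/-"),
                   expected_ratio: Sequence[float] = (1.0, 2.0, 1.0)) -> "GenotypeCounts":
        """Build counts from a printed ratio and total (largest remainder)."""
        return cls(labels=tuple(labels),
                   observed=tuple(counts_from_ratio(ratio, total)),
                   expected_ratio=tuple(expected_ratio))


def counts_from_ratio(ratio: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` across ratio shares by the largest-remainder rule.

    Deterministic, and the result always sums exactly to ``total``.  Ties
    on the fractional remainder are broken by lower index.
    """
    ratio = np.asarray(ratio, dtype=float)
    if total < 1:
        raise ValueError("total must be >=1")
    if np.any(ratio < 0) or ratio.sum() == 0:
        raise ValueError("ratio must be non-negative and not all zero")
    quota = total * ratio / ratio.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - int(counts.sum())
    # stable sort descending on remainder -> lower index wins ties
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return [int(c) for c in counts]


def mendelian_chi2(gc: GenotypeCounts) -> dict:
    """Pearson chi-square goodness of fit against the expected ratio.

    df = number of classes - 1.  Requires every expected count >= 1.
    """
    obs = np.asarray(gc.observed, dtype=float)
    ratio = np.asarray(gc.expected_ratio, dtype=float)
    expected = gc.total * ratio / ratio.sum()
    if np.any(expected < 1):
        raise ValueError("every expected class count must be >=1")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return {"chi2": float(chi2), "df": len(obs) - 1, "p": float(p)}


def survival_deficit(gc: GenotypeCounts, genotype_index: int) -> dict:
    """Percent of the expected animals of one genotype missing at census.

    deficit% = 100 * (1 - observed_share / expected_share), where the
    observed share is the genotype's fraction of the census total and the
    expected share comes from the Mendelian ratio.  A negative deficit
    (surplus) is clipped to 0 and flagged.  The rounded-to-nearest-ten
    presentation value is reported alongside the raw percentage.
    """
    ratio = np.asarray(gc.expected_ratio, dtype=float)
    expected_share = ratio[genotype_index] / ratio.sum()
    if expected_share == 0:
        raise ValueError("expected share of the genotype must be positive")
    if gc.total == 0:
        raise ValueError("zero total")
    observed_share = gc.observed[genotype_index] / gc.total
    raw = 100.0 * (1.0 - observed_share / expected_share)
    clipped = raw < 0
    deficit = max(raw, 0.0)
    return {
        "deficit_pct": float(deficit),
        "deficit_pct_rounded10": int(round(deficit / 10.0) * 10),
        "surplus_clipped": bool(clipped),
    }


def sex_ratio_test(n_male: int, n_female: int) -> dict:
    """Exact two-sided binomial test of the male fraction against 0.5.

    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed one (the standard exact-binomial convention).
    """
    if n_male < 0 or n_female < 0 or n_male + n_female < 1:
        raise ValueError("need at least one animal")
    res = stats.binomtest(n_male, n_male + n_female, p=0.5, alternative="two-sided")
    return {
        "n_male": int(n_male),
        "n_female": int(n_female),
        "male_fraction": n_male / (n_male + n_female),
        "p": float(res.pvalue),
    }
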