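"""Genome-wide allele-frequency differentiation testing between two populations.

Each variant carries per-population allele counts (AC), allele numbers (AN)
and allele frequencies (AF), in the style of gnomAD summary tables.  A
variant is called *population differentiated* when a two-sided pooled
two-proportion chi-square test (1 df, no continuity correction) rejects at
``p < 5e-8`` AND the absolute allele-frequency difference exceeds 0.05 —
both inequalities strict.  Variants lacking allele information in either
population are excluded from testing and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationRecord",
    "VariantFrequency",
    "DifferentiationCall",
    "DifferentiationSummary",
    "two_proportion_test",
    "classify_differentiated",
    "read_frequency_table",
    "write_calls",
]

P_THRESHOLD_DEFAULT = 5e-8
DIFF_THRESHOLD_DEFAULT = 0.05


@dataclass(frozen=True)
class PopulationRecord:
    """Allele counts for one variant in one population; fields may be absent."""

    ac: Optional[int] = None
    an: Optional[int] = None
    af: Optional[float] = None

    def __post_init__(self):
        if self.an is not None and self.an <= 0:
            raise ValueError("AN must be positive when present")
        if self.ac is not None:
            if self.ac < 0:
                raise ValueError("AC must be non-negative")
            if self.an is not None and self.ac > self.an:
                raise ValueError("AC exceeds AN")
        if self.af is not None and not 0 <= self.af <= 1:
            raise ValueError("AF must lie in [0, 1]")
        if None not in (self.ac, self.an, self.af):
            if abs(self.af - self.ac / self.an) > 1e-6:
                raise ValueError(
                    f"AF={self.af} inconsistent with AC/AN={self.ac}/{self.an}"
                )

    def counts(self) -> Optional[tuple[int, int]]:
        """(AC, AN) for testing; AC reconstructed from AF when only AF+AN exist."""
        if self.an is None:
            return None
        if self.ac is not None:
            return self.ac, self.an
        if self.af is not None:
            return int(round(self.af * self.an)), self.an
        return None


@dataclass(frozen=True)
class VariantFrequency:
    variant_id: str
    pop1: PopulationRecord
    pop2: PopulationRecord


@dataclass(frozen=True)
class DifferentiationCall:
    variant_id: str
    p_value: Optional[float]
    af_diff: Optional[float]  # AF_pop1 - AF_pop2
    chi_square: Optional[float]
    differentiated: bool
    excluded: bool
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class DifferentiationSummary:
    calls: list[DifferentiationCall]
    n_total: int
    n_excluded: int
    n_tested: int
    n_differentiated: int

    @property
    def fraction(self) -> float:
        """Differentiated fraction among tested variants."""
        return self.n_differentiated / self.n_tested if self.n_tested else math.nan


def two_proportion_test(ac1: int, an1: int, ac2: int, an2: int) -> tuple[float, float]:
    """Two-sided pooled two-proportion chi-square test (1 df).

    The statistic is the square of the pooled z-score,
    ``(p1 - p2)^2 / (p_pool (1 - p_pool) (1/an1 + 1/an2))``; no continuity
    correction.  A degenerate pooled proportion (0 or 1) yields statistic 0
    and p = 1.
    """
    if an1 <= 0 or an2 <= 0:
        raise ValueError("allele numbers must be positive")
    if not (0 <= ac1 <= an1 and 0 <= ac2 <= an2):
        raise ValueError("allele counts must satisfy 0 <= AC <= AN")
    p1, p2 = ac1 / an1, ac2 / an2
    pool = (ac1 + ac2) / (an1 + an2)
    if pool <= 0 or pool >= 1:
        return 0.0, 1.0
    chi2 = (p1 - p2) ** 2 / (pool * (1 - pool) * (1 / an1 + 1 / an2))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def classify_differentiated(
    table: Sequence[VariantFrequency],
    p_threshold: float = P_THRESHOLD_DEFAULT,
    diff_threshold: float = DIFF_THRESHOLD_DEFAULT,
) -> DifferentiationSummary:
    """Test every variant and flag the population-differentiated ones.

    A variant is flagged iff ``p < p_threshold`` and ``|AF1 - AF2| >
    diff_threshold`` (both strict).  Variants whose counts cannot be
    established in both populations are excluded (reason recorded), matching
    the retain-only-complete-records rule.
    """
    if not table:
        raise ValueError("empty frequency table")
    calls: list[DifferentiationCall] = []
    n_diff = n_excl = 0
    for vf in table:
        c1, c2 = vf.pop1.counts(), vf.pop2.counts()
        if c1 is None or c2 is None:
            side = "1" if c1 is None else "2"
            calls.append(
                DifferentiationCall(
                    vf.variant_id, None, None, None,
                    differentiated=False, excluded=True,
                    exclusion_reason=f"missing allele information in population {side}",
                )
            )
            n_excl += 1
            continue
        (ac1, an1), (ac2, an2) = c1, c2
        chi2, p = two_proportion_test(ac1, an1, ac2, an2)
        af_diff = ac1 / an1 - ac2 / an2
        flag = (p < p_threshold) and (abs(af_diff) > diff_threshold)
        calls.append(
            DifferentiationCall(vf.variant_id, p, af_diff, chi2, flag, False)
        )
        n_diff += flag
    return DifferentiationSummary(
        calls=calls,
        n_total=len(calls),
        n_excluded=n_excl,
        n_tested=len(calls) - n_excl,
        n_differentiated=n_diff,
    )


# ---------------------------------------------------------------------------
# TSV interface
# header: variant_id  AC_pop1  AN_pop1  AF_pop1  AC_pop2  AN_pop2  AF_pop2
# empty field = absent

_FREQ_COLUMNS = [
    "variant_id", "AC_pop1", "AN_pop1", "AF_pop1", "AC_pop2", "AN_pop2", "AF_pop2",
]


def read_frequency_table(path: str | Path) -> list[VariantFrequency]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if list(df.columns) != _FREQ_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_FREQ_COLUMNS}, got {list(df.columns)}"
        )

    def rec(row, pop):
        ac, an, af = row[f"AC_{pop}"], row[f"AN_{pop}"], row[f"AF_{pop}"]
        return PopulationRecord(
            ac=None if pd.isna(ac) else int(ac),
            an=None if pd.isna(an) else int(an),
            af=None if pd.isna(af) else float(af),
        )

    return [
        VariantFrequency(row["variant_id"], rec(row, "pop1"), rec(row, "pop2"))
        for _, row in df.iterrows()
    ]


def write_frequency_table(table: Sequence[VariantFrequency], path: str | Path) -> None:
    rows = []
    for vf in table:
        rows.append({
            "variant_id": vf.variant_id,
            "AC_pop1": vf.pop1.ac, "AN_pop1": vf.pop1.an, "AF_pop1": vf.pop1.af,
            "AC_pop2": vf.pop2.ac, "AN_pop2": vf.pop2.an, "AF_pop2": vf.pop2.af,
        })
    df = pd.DataFrame(rows, columns=_FREQ_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_calls(summary: DifferentiationSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "chi_square": c.chi_square,
                "p_value": c.p_value,
                "af_diff": c.af_diff,
                "differentiated": c.differentiated,
                "excluded": c.excluded,
                "exclusion_reason": c.exclusion_reason or "",
            }
            for c in summary.calls
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
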