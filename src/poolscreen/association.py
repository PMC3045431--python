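"""Case-control association for validated pool variants.

Pooled sequencing nominates variants; individual genotyping of the pool
members then yields per-group genotype counts, from which 2x2 contingency
tables are built on either of two bases:

* **allele**: minor vs major allele counts (2 per diploid individual);
* **carrier**: carriers of >= 1 minor allele vs non-carriers.

Association is tested with the 1-df Pearson chi-square (no continuity
correction) and effect sizes are odds ratios with Woolf (log-OR normal
approximation) confidence intervals.  Replication tables published as
frequencies only are converted back to nearest-integer allele counts; for
rare variants every carrier is assumed heterozygous, so carrier and allele
counts coincide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.96  # conventional two-sided 95% normal multiplier


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotyping outcome of one group for one biallelic variant."""

    label: str
    n: int  # individuals successfully genotyped
    hom_minor: int
    het: int

    def __post_init__(self) -> None:
        if min(self.n, self.hom_minor, self.het) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.hom_minor + self.het > self.n:
            raise ValueError(
                f"{self.label}: hom_minor + het = {self.hom_minor + self.het} exceeds n = {self.n}"
            )

    @property
    def minor_alleles(self) -> int:
        return 2 * self.hom_minor + self.het

    @property
    def carriers(self) -> int:
        return self.hom_minor + self.het

    @property
    def maf(self) -> float:
        return self.minor_alleles / (2 * self.n)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) = case minor/major, (c, d) = control minor/major."""

    a: int
    b: int
    c: int
    d: int
    basis: str = "allele"  # "allele" or "carrier"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.basis not in ("allele", "carrier"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def allele_table(case: GenotypeCounts, control: GenotypeCounts) -> ContingencyTable:
    """Allele-based 2x2 table; row totals are 2n per group."""
    return ContingencyTable(
        a=case.minor_alleles,
        b=2 * case.n - case.minor_alleles,
        c=control.minor_alleles,
        d=2 * control.n - control.minor_alleles,
        basis="allele",
    )


def carrier_table(case: GenotypeCounts, control: GenotypeCounts) -> ContingencyTable:
    """Carrier-based 2x2 table; row totals are n per group."""
    return ContingencyTable(
        a=case.carriers,
        b=case.n - case.carriers,
        c=control.carriers,
        d=control.n - control.carriers,
        basis="carrier",
    )


def allele_counts_from_frequency(freq: float, n_individuals: int) -> int:
    """Nearest-integer minor-allele count among 2n chromosomes (ties round
    half away from zero).  Under the all-heterozygote assumption appropriate
    for rare variants, the carrier count equals this allele count."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {freq}")
    return int(math.floor(freq * 2 * n_individuals + 0.5))


def carrier_table_from_frequencies(
    freq_case: float, n_case: int, freq_control: float, n_control: int
) -> ContingencyTable:
    """Reconstruct a carrier table from published minor-allele frequencies."""
    kc = allele_counts_from_frequency(freq_case, n_case)
    kt = allele_counts_from_frequency(freq_control, n_control)
    return ContingencyTable(kc, n_case - kc, kt, n_control - kt, basis="carrier")


def pearson_chi2(table: ContingencyTable) -> tuple[float, float, int]:
    """1-df Pearson chi-square without continuity correction.

    Returns (statistic, p, dof).  A zero margin leaves the statistic
    undefined; (nan, nan, 1) is returned with a warning.
    """
    a, b, c, d = (float(x) for x in table.cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        warnings.warn("chi-square undefined: zero margin in 2x2 table")
        return (float("nan"), float("nan"), 1)
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return (float(chi2), p, 1)


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """OR = ad / (bc).  With a zero cell the OR is undefined; pass
    ``haldane=True`` to add 0.5 to every cell (Haldane-Anscombe correction)."""
    a, b, c, d = _maybe_haldane(table, haldane)
    return (a * d) / (b * c)


def woolf_ci(
    table: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Woolf confidence interval: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).

    For the conventional 95% level the multiplier is exactly 1.96.
    """
    a, b, c, d = _maybe_haldane(table, haldane)
    z = Z_95 if level == 0.95 else float(stats.norm.ppf((1 + level) / 2))
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def _maybe_haldane(table: ContingencyTable, haldane: bool) -> tuple[float, ...]:
    cells = table.cells
    if any(x == 0 for x in cells):
        if not haldane:
            raise ValueError(
                f"zero cell in 2x2 table {cells}; enable haldane=True for the +0.5 fallback"
            )
        return tuple(x + 0.5 for x in cells)
    return tuple(float(x) for x in cells)


def validation_correlation(
    pool_freqs: Sequence[float],
    genotyped_freqs: Sequence[float],
    fr_scores: Optional[Sequence[float]] = None,
    score_cutoff: float = 1.0,
) -> float:
    """Pearson correlation between pool-sequencing and individual-genotyping
    allele frequencies.

    Variants whose strand-balance score exceeds ``score_cutoff`` in the pool
    under analysis are excluded (a missing/NaN score — e.g. the substitution
    was absent from the pool and its frequency entered as 0 — is kept).
    Requires >= 3 pairs after filtering; zero variance in either vector
    yields NaN.
    """
    x = np.asarray(pool_freqs, dtype=float)
    y = np.asarray(genotyped_freqs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must have equal length")
    if fr_scores is not None:
        s = np.asarray(fr_scores, dtype=float)
        keep = np.isnan(s) | (s <= score_cutoff)
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs after filtering, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def associate(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Association results for a long-format genotype table.

    Input columns: ``variant, group, n, hom_minor, het`` with ``group`` in
    {"case", "control"}.  For each variant both the allele- and carrier-based
    analyses are reported: OR, Woolf 95% CI, chi-square, p, per-group MAF,
    and a Bonferroni-adjusted p across the variants tested (reported for
    transparency; the primary p-values are unadjusted).
    """
    required = {"variant", "group", "n", "hom_minor", "het"}
    missing = required - set(genotypes.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    rows = []
    variants = list(dict.fromkeys(genotypes["variant"]))
    for variant in variants:
        sub = genotypes[genotypes["variant"] == variant]
        groups = {}
        for label in ("case", "control"):
            g = sub[sub["group"] == label]
            if len(g) != 1:
                raise ValueError(f"variant {variant!r}: need exactly one {label} row")
            r = g.iloc[0]
            groups[label] = GenotypeCounts(label, int(r["n"]), int(r["hom_minor"]), int(r["het"]))
        case, control = groups["case"], groups["control"]
        for basis, builder in (("allele", allele_table), ("carrier", carrier_table)):
            table = builder(case, control)
            chi2, p, _ = pearson_chi2(table)
            zero_cell = any(x == 0 for x in table.cells)
            if zero_cell:
                or_, lo, hi = (float("nan"),) * 3
            else:
                or_ = odds_ratio(table)
                lo, hi = woolf_ci(table)
            rows.append(
                {
                    "variant": variant,
                    "basis": basis,
                    "maf_case": case.maf,
                    "maf_control": control.maf,
                    "odds_ratio": or_,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "chi2": chi2,
                    "p": p,
                    "zero_cell": zero_cell,
                }
            )
    out = pd.DataFrame(rows)
    m = len(variants)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    return out
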