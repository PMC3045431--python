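"""Empirical-error variant calling for pooled sequencing.

At the depths reached by pooled amplicon sequencing every position shows a
nonzero frequency of every substitution, almost all of it PCR/sequencing
error.  The error background differs systematically between the 12 ordered
base changes (ref -> alt), so the caller builds one empirical frequency
distribution per substitution type from all non-primer positions of the pool
and takes its 97.5th percentile as that type's calling cutoff.  Forward and
reverse strands are scored separately: a substitution is called only when it
exceeds the cutoff on *both* strands, which suppresses the strand-biased
artefacts that dominate pooled data.

Calling is per pool — case and control pools get their own thresholds — and
a strand-balance score (the forward/reverse frequency difference divided by
the mean frequency, range 0..2) is attached to every candidate for QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pileup import BASES, PileupColumn

logger = logging.getLogger(__name__)

#: minimum observations for a substitution type's threshold to be trusted
MIN_OBS_DEFAULT = 40
#: minimum per-strand depth for a position to enter calling
MIN_DEPTH_DEFAULT = 50

_QUANTILE_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


@dataclass(frozen=True)
class SubstitutionFrequency:
    """Per-strand observed frequency of one substitution at one position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    n_fwd: int
    n_rev: int
    depth_fwd: int
    depth_rev: int

    @property
    def f_fwd(self) -> float:
        return self.n_fwd / self.depth_fwd

    @property
    def f_rev(self) -> float:
        return self.n_rev / self.depth_rev

    @property
    def f_combined(self) -> float:
        return (self.n_fwd + self.n_rev) / (self.depth_fwd + self.depth_rev)

    @property
    def depth_total(self) -> int:
        return self.depth_fwd + self.depth_rev


def substitution_frequencies(column: PileupColumn) -> list[SubstitutionFrequency]:
    """All three alternate-base frequencies at one position.

    Zero-count records are retained — they are the bulk of the error
    distributions.  Positions with an N reference or zero depth on either
    strand yield nothing (skipped and logged by :func:`frequency_table`).
    """
    if column.ref not in BASES:
        return []
    if column.depth_fwd == 0 or column.depth_rev == 0:
        return []
    return [
        SubstitutionFrequency(
            chrom=column.chrom,
            pos=column.pos,
            ref=column.ref,
            alt=alt,
            n_fwd=column.counts_fwd[alt],
            n_rev=column.counts_rev[alt],
            depth_fwd=column.depth_fwd,
            depth_rev=column.depth_rev,
        )
        for alt in BASES
        if alt != column.ref
    ]


def frequency_table(columns: Iterable[PileupColumn]) -> pd.DataFrame:
    """Substitution frequencies of a whole pool as a DataFrame.

    Columns: chrom, pos, ref, alt, n_fwd, n_rev, depth_fwd, depth_rev,
    f_fwd, f_rev, f_combined, depth_total.
    """
    rows = []
    skipped = 0
    for col in columns:
        recs = substitution_frequencies(col)
        if not recs:
            skipped += 1
            continue
        for r in recs:
            rows.append(
                (r.chrom, r.pos, r.ref, r.alt, r.n_fwd, r.n_rev, r.depth_fwd, r.depth_rev)
            )
    if skipped:
        logger.info("frequency_table: skipped %d positions (N reference or empty strand)", skipped)
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "n_fwd", "n_rev", "depth_fwd", "depth_rev"],
    )
    if df.empty:
        for c in ("f_fwd", "f_rev", "f_combined"):
            df[c] = pd.Series(dtype=float)
        df["depth_total"] = pd.Series(dtype=int)
        return df
    df["f_fwd"] = df["n_fwd"] / df["depth_fwd"]
    df["f_rev"] = df["n_rev"] / df["depth_rev"]
    df["depth_total"] = df["depth_fwd"] + df["depth_rev"]
    df["f_combined"] = (df["n_fwd"] + df["n_rev"]) / df["depth_total"]
    return df


@dataclass
class ErrorThresholds:
    """Per-substitution-type calling cutoffs for one pool."""

    q: float
    fwd: dict[tuple[str, str], float]
    rev: dict[tuple[str, str], float]
    n_obs: dict[tuple[str, str], int]
    unreliable: frozenset[tuple[str, str]] = frozenset()
    mode: str = "pooled"  # "pooled" (one distribution per type) or "per-strand"

    def threshold_fwd(self, ref: str, alt: str) -> float:
        return self.fwd[(ref, alt)]

    def threshold_rev(self, ref: str, alt: str) -> float:
        return self.rev[(ref, alt)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.fwd):
            ref, alt = key
            rows.append(
                {
                    "ref": ref,
                    "alt": alt,
                    "threshold_fwd": self.fwd[key],
                    "threshold_rev": self.rev[key],
                    "n_obs": self.n_obs.get(key, 0),
                    "reliable": key not in self.unreliable,
                }
            )
        return pd.DataFrame(rows)


def error_thresholds(
    freqs: pd.DataFrame,
    q: float = 0.975,
    method: str = "linear",
    min_obs: int = MIN_OBS_DEFAULT,
    mode: str = "pooled",
    exclude_positions: Optional[set[int]] = None,
) -> ErrorThresholds:
    """Empirical q-quantile of the per-strand error frequencies per base change.

    By default ("pooled") the forward- and reverse-strand frequencies of a
    substitution type enter one distribution and yield one cutoff; with
    ``mode="per-strand"`` each strand gets its own.  ``method`` selects the
    quantile definition: "linear" interpolates between order statistics,
    "nearest-rank" takes the smallest observation with cumulative frequency
    >= q.  Types with fewer than ``min_obs`` observations are flagged
    unreliable; a type with no observations at all is an error.

    ``exclude_positions`` supports a two-pass scheme in which previously
    called variant positions are removed before re-estimating thresholds.
    """
    if not 0.5 < q < 1.0:
        raise ValueError(f"percentile q must be in (0.5, 1), got {q}")
    if method not in _QUANTILE_METHODS:
        raise ValueError(f"unknown quantile method {method!r}")
    if mode not in ("pooled", "per-strand"):
        raise ValueError(f"unknown error-distribution mode {mode!r}")
    np_method = _QUANTILE_METHODS[method]
    df = freqs
    if exclude_positions:
        df = df[~df["pos"].isin(exclude_positions)]
    fwd: dict[tuple[str, str], float] = {}
    rev: dict[tuple[str, str], float] = {}
    n_obs: dict[tuple[str, str], int] = {}
    unreliable = set()
    grouped = dict(tuple(df.groupby(["ref", "alt"], sort=True)))
    for ref in BASES:
        for alt in BASES:
            if alt == ref:
                continue
            key = (ref, alt)
            sub = grouped.get(key)
            if sub is None or sub.empty:
                raise ValueError(f"no observations for substitution type {ref}>{alt}")
            ff = sub["f_fwd"].to_numpy()
            fr = sub["f_rev"].to_numpy()
            if mode == "pooled":
                values = np.concatenate([ff, fr])
                t = float(np.quantile(values, q, method=np_method))
                fwd[key] = rev[key] = t
                n_obs[key] = values.size
            else:
                fwd[key] = float(np.quantile(ff, q, method=np_method))
                rev[key] = float(np.quantile(fr, q, method=np_method))
                n_obs[key] = ff.size + fr.size
            if n_obs[key] < min_obs:
                unreliable.add(key)
                logger.warning(
                    "threshold for %s>%s based on only %d observations (< %d): unreliable",
                    ref, alt, n_obs[key], min_obs,
                )
    return ErrorThresholds(
        q=q, fwd=fwd, rev=rev, n_obs=n_obs, unreliable=frozenset(unreliable), mode=mode
    )


def fr_ratio_score(f_fwd, f_rev):
    """Strand-balance score: |f_fwd - f_rev| / mean(f_fwd, f_rev), in [0, 2].

    NaN when both frequencies are zero (no signal to compare).  Accepts
    scalars or arrays.
    """
    f_fwd = np.asarray(f_fwd, dtype=float)
    f_rev = np.asarray(f_rev, dtype=float)
    total = f_fwd + f_rev
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(total > 0, np.abs(f_fwd - f_rev) / (total / 2.0), np.nan)
    if score.ndim == 0:
        return float(score)
    return score


def estimate_allele_count(f_combined: float, n_individuals: int) -> int:
    """Nearest-integer alternate-allele copies among 2N chromosomes.

    Ties round half away from zero, so f = 1.5/(2N) estimates 2 copies.
    """
    if not 0.0 <= f_combined <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {f_combined}")
    return int(math.floor(f_combined * 2 * n_individuals + 0.5))


def min_detectable_count(threshold: float, n_individuals: int) -> int:
    """Smallest variant copy number k whose pool frequency k/(2N) clears a
    calling cutoff (strict inequality)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    m = threshold * 2 * n_individuals
    # guard against 3.0 represented as 2.999...: k/(2N) == t must NOT detect
    if math.isclose(m, round(m), rel_tol=0, abs_tol=1e-9):
        return int(round(m)) + 1
    return int(math.floor(m)) + 1


def call_variants(
    freqs: pd.DataFrame,
    thresholds: ErrorThresholds,
    n_individuals: int,
    min_depth_per_strand: int = MIN_DEPTH_DEFAULT,
) -> pd.DataFrame:
    """Dual-strand threshold calling over a pool's substitution frequencies.

    Returns every candidate substitution (any nonzero read support) with its
    per-strand frequencies, strand-balance score, estimated pool allele count
    and a ``called`` flag, so near-threshold records remain inspectable.
    A substitution is called when its frequency *strictly* exceeds its type's
    cutoff on both strands and both strand depths reach
    ``min_depth_per_strand``.
    """
    df = freqs[(freqs["n_fwd"] + freqs["n_rev"]) > 0].copy()
    if df.empty:
        for c in ("fr_score", "threshold_fwd", "threshold_rev"):
            df[c] = pd.Series(dtype=float)
        df["k_hat"] = pd.Series(dtype=int)
        df["called"] = pd.Series(dtype=bool)
        return df
    df["fr_score"] = fr_ratio_score(df["f_fwd"].to_numpy(), df["f_rev"].to_numpy())
    df["threshold_fwd"] = [
        thresholds.threshold_fwd(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    df["threshold_rev"] = [
        thresholds.threshold_rev(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    df["k_hat"] = [
        estimate_allele_count(f, n_individuals) for f in df["f_combined"]
    ]
    deep_enough = (df["depth_fwd"] >= min_depth_per_strand) & (
        df["depth_rev"] >= min_depth_per_strand
    )
    df["called"] = (
        deep_enough
        & (df["f_fwd"] > df["threshold_fwd"])
        & (df["f_rev"] > df["threshold_rev"])
    )
    return df.reset_index(drop=True)


def run_calling(
    columns: Iterable[PileupColumn],
    n_individuals: int,
    amplicons=None,
    q: float = 0.975,
    quantile_method: str = "linear",
    mode: str = "pooled",
    min_depth_per_strand: int = MIN_DEPTH_DEFAULT,
    min_obs: int = MIN_OBS_DEFAULT,
    two_pass: bool = False,
) -> tuple[ErrorThresholds, pd.DataFrame]:
    """Primer masking -> frequency table -> thresholds -> dual-strand calls.

    With ``two_pass=True`` positions called in a first pass are excluded and
    the thresholds re-estimated before the final calling round (the default
    single pass keeps variant positions in the error histograms; at rare-
    variant densities the inflation is negligible).
    """
    from .pileup import mask_primers

    cols = list(mask_primers(columns, amplicons))
    freqs = frequency_table(cols)
    if freqs.empty:
        raise ValueError("no usable positions after primer masking")
    thresholds = error_thresholds(
        freqs, q=q, method=quantile_method, min_obs=min_obs, mode=mode
    )
    calls = call_variants(freqs, thresholds, n_individuals, min_depth_per_strand)
    if two_pass:
        hit_positions = set(calls.loc[calls["called"], "pos"])
        if hit_positions:
            thresholds = error_thresholds(
                freqs,
                q=q,
                method=quantile_method,
                min_obs=min_obs,
                mode=mode,
                exclude_positions=hit_positions,
            )
            calls = call_variants(freqs, thresholds, n_individuals, min_depth_per_strand)
    logger.info(
        "called %d of %d candidate substitutions at q=%.4f",
        int(calls["called"].sum()) if not calls.empty else 0,
        len(calls),
        q,
    )
    return thresholds, calls
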