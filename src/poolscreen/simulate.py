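"""Synthetic pooled-amplicon sequencing with known ground truth.

Emulates the screen design this package targets: genomic DNA of N diploid
individuals is pooled, a set of exon-spanning PCR products is amplified and
deep-sequenced, and the only observable at each position is an aggregate
allele frequency.  A variant carried by k of the 2N chromosomes appears at
pool frequency p = k/(2N); sequencing errors add substitution-type-specific
background on top.

Model, per position, per strand (strands are independent):

* depth d ~ Poisson(mean depth per strand of the covering amplicon);
* at a designed variant position, true alternate reads ~ Binomial(d, p);
* for every alternate base b != ref, error reads ~ Binomial(d - true_alt,
  lambda[ref->b]) drawn independently per b (a variant read mis-read as a
  third base is ignored — negligible at the rates modelled);
* the remaining reads match the reference.

Overlapping amplicons contribute additively to a position's counts; one
pileup line is emitted per position.  Output is byte-identical for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .pileup import BASES, Amplicon, AmpliconSet, PileupColumn, write_pileup

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: The 12 ordered reference->alternate substitution types.
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)

#: Default per-base error probabilities per substitution type.  The screen
#: this emulates reported that its error background differed by base change,
#: with G->A cleanest (variants down to 3 copies in 622 detectable) and A->C
#: noisiest (7 copies); values below span 0.001-0.01 with that ordering.
DEFAULT_ERROR_RATES: dict[tuple[str, str], float] = {
    ("A", "C"): 0.010,
    ("A", "G"): 0.002,
    ("A", "T"): 0.005,
    ("C", "A"): 0.006,
    ("C", "G"): 0.004,
    ("C", "T"): 0.0015,
    ("G", "A"): 0.001,
    ("G", "C"): 0.005,
    ("G", "T"): 0.007,
    ("T", "A"): 0.004,
    ("T", "C"): 0.002,
    ("T", "G"): 0.008,
}

MAX_ERROR_RATE = 0.05


def _normalize_rates(rates) -> dict[tuple[str, str], float]:
    """Accept {'G>A': x} or {('G','A'): x} keys; validate range."""
    out: dict[tuple[str, str], float] = {}
    for key, lam in rates.items():
        if isinstance(key, str):
            ref, alt = key.split(">")
        else:
            ref, alt = key
        ref, alt = ref.strip().upper(), alt.strip().upper()
        if ref not in BASES or alt not in BASES or ref == alt:
            raise ValueError(f"bad substitution type {key!r}")
        if not 0.0 <= lam <= MAX_ERROR_RATE:
            raise ValueError(f"error rate for {ref}>{alt} must be in [0, {MAX_ERROR_RATE}], got {lam}")
        out[(ref, alt)] = float(lam)
    return out


@dataclass(frozen=True)
class Variant:
    """A designed pool variant: k alternate copies among the 2N chromosomes."""

    pos: int
    ref: str
    alt: str
    count: int  # k

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError("variant ref/alt must be A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.pos} has ref == alt ({self.ref})")
        if self.count < 0:
            raise ValueError("variant copy number must be >= 0")


@dataclass
class PoolDesign:
    """Parameters of one simulated pool.

    ``mean_depth_per_strand`` may be a scalar (all amplicons) or a sequence
    with one mean per amplicon.  ``reference`` maps position -> base for any
    positions that should not be drawn at random; variant positions are
    forced to their variant's reference base.
    """

    n_individuals: int
    amplicons: list[Amplicon]
    mean_depth_per_strand: Union[float, Sequence[float]] = 1000.0
    error_rates: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_RATES))
    variants: list[Variant] = field(default_factory=list)
    reference: Optional[dict[int, str]] = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.error_rates = _normalize_rates(self.error_rates)
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        self.validate()

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals

    def amplicon_means(self) -> list[float]:
        m = self.mean_depth_per_strand
        if np.isscalar(m):
            return [float(m)] * len(self.amplicons)
        means = [float(x) for x in m]  # type: ignore[union-attr]
        if len(means) != len(self.amplicons):
            raise ValueError("one mean depth per amplicon required")
        return means

    def validate(self) -> None:
        self.amplicon_means()
        amps = AmpliconSet(self.amplicons)
        seen: set[tuple[int, str]] = set()
        for v in self.variants:
            if v.count > self.n_alleles:
                raise ValueError(
                    f"variant at {v.pos}: {v.count} copies exceeds 2N = {self.n_alleles}"
                )
            inside = any(
                a.insert_start <= v.pos < a.insert_end for a in self.amplicons
            )
            if not inside or amps.in_primer(self.chrom, v.pos):
                raise ValueError(
                    f"variant at {v.pos} lies outside the non-primer amplicon regions"
                )
            if (v.pos, v.alt) in seen:
                raise ValueError(f"duplicate variant {v.ref}>{v.alt} at {v.pos}")
            seen.add((v.pos, v.alt))
            if self.reference and self.reference.get(v.pos, v.ref) != v.ref:
                raise ValueError(f"variant at {v.pos} disagrees with supplied reference")


def _build_reference(design: PoolDesign, rng: np.random.Generator) -> dict[int, str]:
    """Reference base per covered position: supplied > variant ref > random."""
    positions = sorted(
        {p for a in design.amplicons for p in range(a.start, a.end)}
    )
    ref = dict(design.reference or {})
    for v in design.variants:
        ref[v.pos] = v.ref
    missing = [p for p in positions if p not in ref]
    draws = rng.integers(0, 4, size=len(missing))
    for p, d in zip(missing, draws):
        ref[p] = BASES[d]
    return {p: ref[p] for p in positions}


def simulate_columns(design: PoolDesign) -> tuple[list[PileupColumn], pd.DataFrame]:
    """Simulate one pool; returns pileup columns and the truth table.

    The truth table has one row per designed variant: ``position, ref, alt,
    count`` (k) and ``freq`` (p = k/2N).
    """
    rng = np.random.default_rng(design.seed)
    reference = _build_reference(design, rng)
    positions = np.array(sorted(reference), dtype=np.int64)
    index = {p: i for i, p in enumerate(positions)}
    ref_codes = np.array([_BASE_INDEX[reference[p]] for p in positions], dtype=np.int8)
    # counts[position, strand, base]
    counts = np.zeros((len(positions), 2, 4), dtype=np.int64)
    variants_by_pos: dict[int, list[Variant]] = {}
    for v in sorted(design.variants, key=lambda v: (v.pos, v.alt)):
        variants_by_pos.setdefault(v.pos, []).append(v)

    rates = np.zeros((4, 4))
    for (r, a), lam in design.error_rates.items():
        rates[_BASE_INDEX[r], _BASE_INDEX[a]] = lam

    for amp, mean_depth in zip(design.amplicons, design.amplicon_means()):
        local_pos = np.arange(amp.start, amp.end, dtype=np.int64)
        gidx = np.searchsorted(positions, local_pos)
        local_ref = ref_codes[gidx]
        var_local = [
            (i, variants_by_pos[p])
            for i, p in enumerate(local_pos)
            if p in variants_by_pos
        ]
        for strand in (0, 1):
            d = rng.poisson(mean_depth, size=len(local_pos)).astype(np.int64)
            alt_total = np.zeros(len(local_pos), dtype=np.int64)
            var_draws: list[tuple[int, int, int]] = []  # (local index, alt code, reads)
            for i, vs in var_local:
                while True:
                    draws = [int(rng.binomial(d[i], v.count / design.n_alleles)) for v in vs]
                    if sum(draws) <= d[i]:
                        break
                for v, x in zip(vs, draws):
                    var_draws.append((i, _BASE_INDEX[v.alt], x))
                alt_total[i] = sum(draws)
            avail = d - alt_total
            errors = np.zeros((len(local_pos), 4), dtype=np.int64)
            for rb in range(4):
                mask = local_ref == rb
                if not mask.any():
                    continue
                nav = avail[mask]
                draws = np.zeros((int(mask.sum()), 4), dtype=np.int64)
                for ab in range(4):
                    if ab == rb or rates[rb, ab] == 0.0:
                        continue
                    draws[:, ab] = rng.binomial(nav, rates[rb, ab])
                bad = draws.sum(axis=1) > nav
                while bad.any():  # astronomically rare; keeps counts conserved
                    for ab in range(4):
                        if ab == rb or rates[rb, ab] == 0.0:
                            continue
                        draws[bad, ab] = rng.binomial(nav[bad], rates[rb, ab])
                    bad = draws.sum(axis=1) > nav
                errors[mask] = draws
            ref_reads = avail - errors.sum(axis=1)
            counts[gidx, strand, :] += errors
            np.add.at(counts, (gidx, strand, local_ref), ref_reads)
            for i, alt_code, x in var_draws:
                counts[gidx[i], strand, alt_code] += x

    columns = []
    for i, p in enumerate(positions):
        columns.append(
            PileupColumn(
                chrom=design.chrom,
                pos=int(p),
                ref=BASES[ref_codes[i]],
                counts_fwd={b: int(counts[i, 0, j]) for j, b in enumerate(BASES)},
                counts_rev={b: int(counts[i, 1, j]) for j, b in enumerate(BASES)},
            )
        )
    truth = pd.DataFrame(
        [
            {
                "position": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "count": v.count,
                "freq": v.count / design.n_alleles,
            }
            for v in sorted(design.variants, key=lambda v: (v.pos, v.alt))
        ],
        columns=["position", "ref", "alt", "count", "freq"],
    )
    return columns, truth


def simulate_pileup(design: PoolDesign) -> tuple[str, pd.DataFrame]:
    """Simulate a pool and render it as samtools-pileup text."""
    columns, truth = simulate_columns(design)
    buf = io.StringIO()
    write_pileup(columns, buf)
    return buf.getvalue(), truth


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, sep="\t", index=False)


def load_design(path: Union[str, Path]) -> PoolDesign:
    """Read a :class:`PoolDesign` from a YAML config (keys mirror the fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    amplicons = [
        Amplicon(
            chrom=a.get("chrom", cfg.get("chrom", "chr1")),
            start=int(a["start"]),
            end=int(a["end"]),
            fwd_primer_len=int(a.get("fwd_primer_len", 0)),
            rev_primer_len=int(a.get("rev_primer_len", 0)),
        )
        for a in cfg["amplicons"]
    ]
    variants = [
        Variant(int(v["pos"]), v["ref"], v["alt"], int(v["count"]))
        for v in cfg.get("variants", [])
    ]
    reference = None
    if cfg.get("reference"):
        reference = {int(k): str(v).upper() for k, v in cfg["reference"].items()}
    return PoolDesign(
        n_individuals=int(cfg["n_individuals"]),
        amplicons=amplicons,
        mean_depth_per_strand=cfg.get("mean_depth_per_strand", 1000.0),
        error_rates=cfg.get("error_rates", dict(DEFAULT_ERROR_RATES)),
        variants=variants,
        reference=reference,
        chrom=cfg.get("chrom", "chr1"),
        seed=int(cfg.get("seed", 0)),
    )


def default_design(
    n_individuals: int = 311,
    mean_depth_per_strand: float = 20_000.0,
    seed: int = 0,
    variants: Optional[list[Variant]] = None,
) -> PoolDesign:
    """A design emulating the screen's geometry: 16 amplicons of 250 bp with
    20 bp primers tiling a ~16 kb gene region, 311 diploid individuals, and
    per-strand depth in the tens of thousands.

    Default variants plant one low-copy variant of the cleanest substitution
    type (G->A, k=3), one rare non-synonymous-like variant (A->T, k=7) and
    one polymorphism at ~3.5% MAF (C->T, k=22).
    """
    amplicons = [
        Amplicon("chr1", 158_579_600 + 1000 * i, 158_579_850 + 1000 * i, 20, 20)
        for i in range(16)
    ]
    if variants is None:
        variants = [
            Variant(158_579_700, "G", "A", 3),
            Variant(158_582_650, "A", "T", 7),
            Variant(158_590_680, "C", "T", 22),
        ]
    return PoolDesign(
        n_individuals=n_individuals,
        amplicons=amplicons,
        mean_depth_per_strand=mean_depth_per_strand,
        variants=variants,
        seed=seed,
    )
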