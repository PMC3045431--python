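"""Strand-aware pileup parsing and amplicon/primer masking.

The samtools text pileup records, for every covered reference position, one
line ``chrom  pos  ref  depth  read-bases`` where the read-base string encodes
both the observed base and the strand of the read it came from: ``.`` and
uppercase letters are forward-strand reads, ``,`` and lowercase letters are
reverse-strand reads.  Pooled-sequencing analyses need those per-strand counts
because strand-discordant signal is the main signature of PCR and sequencing
artefacts.

Conventions used throughout this package:

* Positions are 1-based, matching pileup itself.  Intervals are half-open
  ``[start, end)`` in 1-based coordinates; BED input (0-based half-open) is
  shifted on read.
* ``counts_fwd``/``counts_rev`` hold A/C/G/T only, with reference matches
  counted under the reference base.  Ambiguous reads (``N``/``n``) and
  deletion placeholders (``*``) contribute to the line's depth column — and
  are validated against it — but are excluded from the per-strand counts that
  serve as frequency denominators.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: characters that the fast decoding path can handle with plain counting
_SIMPLE = set(".,ACGTacgt")


class PileupParseError(ValueError):
    """Raised for a malformed pileup line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"pileup line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class PileupColumn:
    """One genomic position of one pool, with strand-resolved base counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    counts_fwd: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BASES, 0))
    counts_rev: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BASES, 0))
    n_fwd: int = 0  # ambiguous (N) reads per strand
    n_rev: int = 0
    deletions: int = 0  # '*' placeholders; strandless

    def __post_init__(self) -> None:
        if self.ref not in BASES and self.ref != "N":
            raise ValueError(f"reference base must be A/C/G/T/N, got {self.ref!r}")
        for counts in (self.counts_fwd, self.counts_rev):
            if any(v < 0 for v in counts.values()):
                raise ValueError("negative base count")

    @property
    def depth_fwd(self) -> int:
        """Forward-strand depth over unambiguous bases (frequency denominator)."""
        return sum(self.counts_fwd.values())

    @property
    def depth_rev(self) -> int:
        return sum(self.counts_rev.values())

    @property
    def line_depth(self) -> int:
        """Depth as printed in the pileup depth column (includes N and '*')."""
        return self.depth_fwd + self.depth_rev + self.n_fwd + self.n_rev + self.deletions


@dataclass(frozen=True)
class Amplicon:
    """A PCR product: genomic interval plus primer lengths at either end.

    ``start``/``end`` are a 1-based half-open interval.  The first
    ``fwd_primer_len`` and last ``rev_primer_len`` positions are primer
    sequence and carry no information about the template.
    """

    chrom: str
    start: int
    end: int
    fwd_primer_len: int = 0
    rev_primer_len: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"amplicon start {self.start} >= end {self.end}")
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise ValueError("primer lengths must be >= 0")
        if self.fwd_primer_len + self.rev_primer_len >= self.end - self.start:
            raise ValueError("primers cover the whole amplicon")

    @property
    def insert_start(self) -> int:
        """First non-primer position."""
        return self.start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        """One past the last non-primer position."""
        return self.end - self.rev_primer_len

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def in_primer(self, chrom: str, pos: int) -> bool:
        if not self.covers(chrom, pos):
            return False
        return pos < self.insert_start or pos >= self.insert_end


@dataclass
class AmpliconSet:
    """The amplicons of one assay design."""

    amplicons: list[Amplicon] = field(default_factory=list)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def in_primer(self, chrom: str, pos: int) -> bool:
        """True if *any* amplicon's primer covers the position (conservative:
        primer coverage wins even when another amplicon's insert overlaps)."""
        return any(a.in_primer(chrom, pos) for a in self.amplicons)

    @classmethod
    def from_bed(cls, path: Union[str, Path]) -> "AmpliconSet":
        """Read a BED-like TSV: chrom, start, end (0-based half-open), then
        forward and reverse primer lengths as two extra columns."""
        amps = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected 5 columns "
                        "(chrom, start, end, fwd_primer_len, rev_primer_len)"
                    )
                chrom, start, end, flen, rlen = fields[:5]
                amps.append(
                    Amplicon(chrom, int(start) + 1, int(end) + 1, int(flen), int(rlen))
                )
        return cls(amps)

    def to_bed(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for a in self.amplicons:
                fh.write(
                    f"{a.chrom}\t{a.start - 1}\t{a.end - 1}"
                    f"\t{a.fwd_primer_len}\t{a.rev_primer_len}\n"
                )


def decode_read_bases(bases: str, ref: str, lineno: int = 0) -> tuple[dict, dict, int, int, int]:
    """Decode a pileup read-base string into per-strand counts.

    Returns ``(counts_fwd, counts_rev, n_fwd, n_rev, deletions)``.  Handles
    the full dialect: ``^X`` read starts (mapping quality consumed), ``$``
    read ends, ``+n<seq>``/``-n<seq>`` indels (ignored), ``*`` deletion
    placeholders and ``N``/``n`` ambiguous calls.
    """
    counts_fwd = dict.fromkeys(BASES, 0)
    counts_rev = dict.fromkeys(BASES, 0)
    n_fwd = n_rev = deletions = 0

    core = bases
    # Fast path: after stripping an optional leading read-start marker and a
    # trailing read-end marker, most simulator/real lines are plain symbols.
    if core.startswith("^") and len(core) >= 2:
        core = core[2:]
    if core.endswith("$"):
        core = core[:-1]
    if set(core) <= _SIMPLE:
        if ref in BASES:
            counts_fwd[ref] += core.count(".")
            counts_rev[ref] += core.count(",")
        else:  # ref N: matches are ambiguous by definition
            n_fwd += core.count(".")
            n_rev += core.count(",")
        for b in BASES:
            counts_fwd[b] += core.count(b)
            counts_rev[b] += core.count(b.lower())
        return counts_fwd, counts_rev, n_fwd, n_rev, deletions

    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(lineno, "dangling '^' with no mapping quality")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(lineno, f"indel marker {c!r} without a length")
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise PileupParseError(lineno, "indel sequence truncated")
            i = j + length
            continue
        if c == ".":
            if ref in BASES:
                counts_fwd[ref] += 1
            else:
                n_fwd += 1
        elif c == ",":
            if ref in BASES:
                counts_rev[ref] += 1
            else:
                n_rev += 1
        elif c == "*":
            deletions += 1
        elif c == "N":
            n_fwd += 1
        elif c == "n":
            n_rev += 1
        elif c in "ACGT":
            counts_fwd[c] += 1
        elif c in "acgt":
            counts_rev[c.upper()] += 1
        else:
            raise PileupParseError(lineno, f"unexpected character {c!r} in read bases")
        i += 1
    return counts_fwd, counts_rev, n_fwd, n_rev, deletions


def parse_pileup(source: Union[str, Path, TextIO, Iterable[str]]) -> Iterator[PileupColumn]:
    """Parse pileup text into :class:`PileupColumn` records.

    ``source`` may be a path, an open text handle, or any iterable of lines.
    The decoded base count of every line is checked against its depth column;
    a mismatch (or any malformed token) raises :class:`PileupParseError`
    naming the offending line.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh: Iterable[str] = open(source)
        close = True
    else:
        fh = source
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PileupParseError(lineno, f"expected >= 5 columns, got {len(fields)}")
            chrom, pos_s, ref, depth_s, bases = fields[:5]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise PileupParseError(lineno, f"bad position/depth field: {exc}") from None
            ref = ref.upper()
            cf, cr, nf, nr, dels = decode_read_bases(bases, ref, lineno)
            col = PileupColumn(chrom, pos, ref, cf, cr, nf, nr, dels)
            if col.line_depth != depth:
                raise PileupParseError(
                    lineno,
                    f"decoded {col.line_depth} reads but depth column says {depth}",
                )
            yield col
    finally:
        if close:
            fh.close()  # type: ignore[union-attr]


def render_column(col: PileupColumn, read_start_marker: bool = True) -> str:
    """Serialize one column back to a pileup line (inverse of the parser).

    Forward reads are written first (``.``/uppercase), then reverse
    (``,``/lowercase).  When ``read_start_marker`` is set, the first read
    carries a ``^~`` start marker and the last a ``$`` end marker, which the
    parser consumes without counting.
    """
    parts = []
    if col.ref in BASES:
        parts.append("." * col.counts_fwd[col.ref])
    for b in BASES:
        if b != col.ref:
            parts.append(b * col.counts_fwd[b])
    parts.append("N" * col.n_fwd)
    if col.ref in BASES:
        parts.append("," * col.counts_rev[col.ref])
    for b in BASES:
        if b != col.ref:
            parts.append(b.lower() * col.counts_rev[b])
    parts.append("n" * col.n_rev)
    parts.append("*" * col.deletions)
    bases = "".join(parts)
    if read_start_marker and bases:
        bases = "^~" + bases + "$"
    return f"{col.chrom}\t{col.pos}\t{col.ref}\t{col.line_depth}\t{bases}"


def write_pileup(columns: Iterable[PileupColumn], stream: TextIO) -> int:
    """Write columns as pileup text; returns the number of lines written.

    Zero-depth columns are skipped, as samtools does.
    """
    n = 0
    for col in columns:
        if col.line_depth == 0:
            continue
        stream.write(render_column(col) + "\n")
        n += 1
    return n


def mask_primers(
    columns: Iterable[PileupColumn], amplicons: Union[AmpliconSet, None]
) -> Iterator[PileupColumn]:
    """Drop columns whose position falls inside any amplicon's primer.

    A position covered by the primer of one amplicon is excluded even if it
    lies in the interior of another, overlapping amplicon.  With no amplicons
    supplied this is the identity.
    """
    if amplicons is None or len(amplicons) == 0:
        yield from columns
        return
    dropped = 0
    for col in columns:
        if amplicons.in_primer(col.chrom, col.pos):
            dropped += 1
            continue
        yield col
    logger.debug("mask_primers: dropped %d primer positions", dropped)
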