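"""Genomic file I/O and the domain types every other module consumes.

All coordinates are 0-based, half-open (BED convention) everywhere inside
the package.  Input files in 1-based dialects must be converted explicitly
by the caller (the CLI exposes a flag); nothing here auto-detects the
dialect, because a silent off-by-one is fatal to a method that claims
single-base-pair resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Summit",
    "FragmentSet",
    "PWM",
    "ParseError",
    "read_summits",
    "write_summits",
    "read_fragments",
    "read_intervals",
    "write_intervals",
    "read_pwm",
    "write_pwm",
    "read_fasta",
    "write_fasta",
    "filter_blacklist",
    "write_bedgraph",
]


class ParseError(ValueError):
    """Raised for malformed input lines; always names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Mathematical middle of the interval, possibly half-integer."""
        return (self.start + self.end - 1) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Summit:
    """A single-bp predicted protein contact point in one sample."""

    interval: GenomicInterval
    sample_id: str
    protein: str
    height: float = 0.0

    def __post_init__(self) -> None:
        if self.interval.width != 1:
            raise ValueError(f"summit interval must have width 1: {self.interval}")
        if self.height < 0:
            raise ValueError(f"summit height must be >= 0: {self.height}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def position(self) -> int:
        return self.interval.start


@dataclass
class FragmentSet:
    """Strandless ChIP fragments from one sample, in input order."""

    sample_id: str
    fragments: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T (columns in that fixed order)."""

    matrix: np.ndarray  # (L, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # (4,) probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError("PWM must have at least one position")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("PWM background must sum to 1")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def length(self) -> int:
        return len(self)

    def log_odds(self) -> np.ndarray:
        """Natural-log odds ``ln(p/bg)`` with -inf for zero probabilities."""
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(self.background)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# readers


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_summits(path: str | Path, sample_id: str, protein: str) -> list[Summit]:
    """Read BED-like summit calls; >=3 columns, optional 5th column = height.

    Multi-bp peak intervals are collapsed to the single base pair at
    ``floor((start + end - 1) / 2)`` (the floored inclusive midpoint), a
    deterministic, strand-independent choice.
    """
    out: list[Summit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            height = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    height = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad height: {exc}") from None
            pos = (start + end - 1) // 2
            out.append(
                Summit(
                    interval=GenomicInterval(chrom, pos, pos + 1),
                    sample_id=sample_id,
                    protein=protein,
                    height=height,
                )
            )
    return out


def write_summits(path: str | Path, summits: Iterable[Summit]) -> None:
    with open(path, "w") as handle:
        for s in summits:
            handle.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                f"{s.protein}:{s.sample_id}\t{s.height:g}\n"
            )


def read_fragments(path: str | Path, sample_id: str) -> FragmentSet:
    """Read ChIP fragments from BED3+ or BEDPE (collapsed to the outer span).

    A row is treated as BEDPE when it has >=6 columns and columns 5 and 6
    both parse as integers (in BED6 the 6th column is a strand symbol).
    Inter-chromosomal BEDPE rows are skipped with a warning.
    """
    frags: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            is_bedpe = False
            if len(fields) >= 6:
                try:
                    int(fields[4]), int(fields[5])
                    is_bedpe = True
                except ValueError:
                    is_bedpe = False
            try:
                if is_bedpe:
                    c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                    c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
                    if c1 != c2:
                        logger.warning(
                            "%s:%d: skipping inter-chromosomal fragment %s/%s",
                            path,
                            lineno,
                            c1,
                            c2,
                        )
                        continue
                    frags.append(GenomicInterval(c1, min(s1, s2), max(e1, e2)))
                else:
                    frags.append(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                    )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return FragmentSet(sample_id=sample_id, fragments=frags)


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED3+ intervals (e.g. a blacklist)."""
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_intervals(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_pwm(
    path: str | Path,
    pseudocount: float = 0.0,
    background: Sequence[float] | None = None,
) -> PWM:
    """Read a plain-text L x 4 matrix (columns A C G T; counts or frequencies).

    Rows are normalized to probabilities after adding ``pseudocount``.
    Lines starting with ``#`` or ``>`` are ignored.  The background is
    uniform unless supplied explicitly.
    """
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", ">")):
                continue
            fields = _split_fields(line)
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: empty PWM")
    matrix = np.asarray(rows, dtype=float) + float(pseudocount)
    sums = matrix.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums <= 0)[0]) + 1
        raise ParseError(f"{path}: row {bad} sums to zero (increase pseudocount)")
    matrix /= sums[:, None]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(matrix=matrix, background=bg)


def write_pwm(path: str | Path, pwm: PWM) -> None:
    with open(path, "w") as handle:
        handle.write("# A C G T\n")
        for row in pwm.matrix:
            handle.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a chrom -> uppercase sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, genome: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_bedgraph(
    path: str | Path, chrom: str, start: int, depth: Sequence[float]
) -> None:
    """Write a per-bp depth vector as bedGraph, merging equal-value runs."""
    depth = np.asarray(depth, dtype=float)
    with open(path, "w") as handle:
        i = 0
        while i < len(depth):
            j = i
            while j + 1 < len(depth) and depth[j + 1] == depth[i]:
                j += 1
            handle.write(f"{chrom}\t{start + i}\t{start + j + 1}\t{depth[i]:g}\n")
            i = j + 1


# ---------------------------------------------------------------------------
# blacklist filtering


def _interval_of(record) -> GenomicInterval:
    if isinstance(record, GenomicInterval):
        return record
    return record.interval


def filter_blacklist(records: Sequence, blacklist: Sequence[GenomicInterval]) -> list:
    """Drop records whose interval overlaps any blacklist interval by >=1 bp.

    Records may be bare ``GenomicInterval``s or any object with an
    ``interval`` attribute (``Summit``, motif sites, ...).  Half-open
    semantics: an interval starting exactly at a blacklist end is kept.
    """
    if not blacklist:
        return list(records)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts[chrom] = np.array([iv.start for iv in ivs])
        # running max of ends guards against contained intervals
        ends[chrom] = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
    kept = []
    for rec in records:
        iv = _interval_of(rec)
        if iv.chrom not in starts:
            kept.append(rec)
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        # candidate blacklist entries starting before rec ends
        k = int(np.searchsorted(s, iv.end, side="left"))
        if k == 0 or e[k - 1] <= iv.start:
            kept.append(rec)
    return kept
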