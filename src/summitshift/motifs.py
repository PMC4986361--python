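"""PWM scanning for CTCF recognition sites (CTSs) and per-co-peak site
assignment.

A CTS is an oriented motif match; its *mathematical middle*
``(start + end - 1) / 2`` is the reference point for every downstream
offset, and is deliberately strand-independent (it can be half-integer
for even-length motifs; no rounding is applied so that strand-flip
antisymmetry of offsets is exact).

Scores are natural-log odds ``sum ln(p_base / bg_base)`` against a
uniform background by default; both are configurable because absolute
thresholds are dialect-dependent across motif tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .consensus import CoPeak
from .formats_io import PWM, GenomicInterval

__all__ = [
    "MotifSite",
    "CtsAssignment",
    "scan_pwm",
    "scan_genome",
    "assign_cts",
    "cts_center_and_orientation",
    "reverse_complement",
    "write_cts_bed",
    "write_assignments_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# map bases to 0..3, N (and anything else) to 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSite:
    """An oriented genomic motif match (a CTS when the motif is CTCF's)."""

    interval: GenomicInterval  # strand in {+, -}
    score: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif site strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> float:
        """Mathematical middle of the site; strand-independent."""
        return self.interval.midpoint

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.interval.start}-{self.interval.end}({self.strand})"


@dataclass(frozen=True)
class CtsAssignment:
    """The single CTS (or none) chosen for one co-peak, with the rule used."""

    copeak: CoPeak
    cts: MotifSite | None
    rule_used: str  # single | overlap_best_score | shift_following |
    #                 opposite_best_score | none_found


def _window_scores(encoded: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Score every window of an encoded sequence; windows with N -> -inf."""
    L = lodds.shape[0]
    n_win = encoded.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    # pad the log-odds table with a -inf column for code 4 (N)
    table = np.hstack([lodds, np.full((L, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return table[np.arange(L)[None, :], windows].sum(axis=1)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float = 6.0,
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifSite]:
    """Scan a sequence with a PWM, returning every hit scoring >= threshold.

    Plus-strand hits score the window itself; minus-strand hits score the
    reverse complement of the window and carry strand ``-`` on the same
    genomic interval.  Windows containing ``N`` score ``-inf`` and never
    pass.  Sequences shorter than the motif yield no hits.
    """
    encoded = _ENCODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    L = len(pwm)
    if encoded.size < L:
        return []
    lodds = pwm.log_odds()
    hits: list[MotifSite] = []
    fwd = _window_scores(encoded, lodds)
    strands_scores = [("+", fwd)]
    if both_strands:
        # scoring the window's reverse complement with the PWM is the same
        # as scoring the window with the reversed, complemented matrix
        lodds_rc = lodds[::-1, ::-1]
        strands_scores.append(("-", _window_scores(encoded, lodds_rc)))
    for strand, scores in strands_scores:
        for i in np.flatnonzero(scores >= threshold):
            start = offset + int(i)
            hits.append(
                MotifSite(
                    interval=GenomicInterval(chrom, start, start + L, strand),
                    score=float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def scan_genome(
    genome: dict[str, str],
    pwm: PWM,
    threshold: float = 6.0,
    both_strands: bool = True,
) -> list[MotifSite]:
    """Scan every chromosome of a genome dict with ``scan_pwm``."""
    hits: list[MotifSite] = []
    for chrom in sorted(genome):
        hits.extend(
            scan_pwm(genome[chrom], pwm, threshold=threshold,
                     both_strands=both_strands, chrom=chrom)
        )
    return hits


def cts_center_and_orientation(cts: MotifSite) -> tuple[float, str]:
    """Reference point (mathematical middle) and motif orientation."""
    return cts.center, cts.strand


def _follows_shift(cts: MotifSite, copeak: CoPeak) -> bool:
    """True if the cohesin consensus lies downstream of the CTS center in
    motif 5'->3' orientation (cohesin is almost always downstream of CTCF)."""
    d = copeak.cohesin.position - cts.center
    return d > 0 if cts.strand == "+" else d < 0


def _best(cands: Sequence[MotifSite]) -> MotifSite:
    # ties: higher score, then + strand, then lower start
    return min(
        cands, key=lambda c: (-c.score, 0 if c.strand == "+" else 1, c.interval.start)
    )


def assign_cts(
    copeak: CoPeak, candidates: Sequence[MotifSite], window: int = 50
) -> CtsAssignment:
    """Choose exactly one CTS (or none) for a co-peak.

    Rules in order: no candidate -> ``none_found``; exactly one ->
    ``single``; mutually overlapping candidates collapse to the best
    score (``overlap_best_score`` when that settles it); among multiple
    disjoint candidates, those whose orientation makes the CTCF->cohesin
    shift point downstream of the motif win (``shift_following``, then
    best score); if none follows the shift, the best-scoring remaining
    candidate is taken (``opposite_best_score``).
    """
    cands = [
        c
        for c in candidates
        if c.chrom == copeak.chrom and abs(c.center - copeak.ctcf.position) <= window
    ]
    if not cands:
        return CtsAssignment(copeak, None, "none_found")
    if len(cands) == 1:
        return CtsAssignment(copeak, cands[0], "single")
    # collapse mutually overlapping candidates (>=1 bp genomic overlap,
    # strand-blind) to the best-scoring member of each overlap group
    cands.sort(key=lambda c: (c.interval.start, c.interval.end))
    groups: list[list[MotifSite]] = []
    group_end = -1
    for c in cands:
        if groups and c.interval.start < group_end:
            groups[-1].append(c)
            group_end = max(group_end, c.interval.end)
        else:
            groups.append([c])
            group_end = c.interval.end
    collapsed = [_best(g) for g in groups]
    if len(collapsed) == 1:
        return CtsAssignment(copeak, collapsed[0], "overlap_best_score")
    following = [c for c in collapsed if _follows_shift(c, copeak)]
    if following:
        return CtsAssignment(copeak, _best(following), "shift_following")
    return CtsAssignment(copeak, _best(collapsed), "opposite_best_score")


def write_cts_bed(path: str | Path, sites: Iterable[MotifSite]) -> None:
    """BED6; score column is the motif score x100, rounded."""
    with open(path, "w") as handle:
        for s in sites:
            handle.write(
                f"{s.chrom}\t{s.interval.start}\t{s.interval.end}\tCTS\t"
                f"{round(s.score * 100)}\t{s.strand}\n"
            )


def write_assignments_tsv(path: str | Path, assignments: Iterable[CtsAssignment]) -> None:
    with open(path, "w") as handle:
        handle.write(
            "chrom\tctcf_summit\tcohesin_summit\tcts_start\tcts_end\t"
            "cts_strand\tcts_score\trule_used\n"
        )
        for a in assignments:
            if a.cts is None:
                cts_cols = ".\t.\t.\t."
            else:
                cts_cols = (
                    f"{a.cts.interval.start}\t{a.cts.interval.end}\t"
                    f"{a.cts.strand}\t{a.cts.score:.4f}"
                )
            handle.write(
                f"{a.copeak.chrom}\t{a.copeak.ctcf.position}\t"
                f"{a.copeak.cohesin.position}\t{cts_cols}\t{a.rule_used}\n"
            )
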