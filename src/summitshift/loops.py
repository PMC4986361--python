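"""ChIA-PET loop-anchor post-processing: replicate intersection and
convergent CTS assignment.

Chromatin loops anchored by CTCF almost always form between motifs that
point toward each other: the 5' anchor's CTS on the forward strand and
the 3' anchor's CTS on the reverse strand.  Given a replicate-consensus
interaction set and a CTS catalog (typically restricted to
CTCF+cohesin co-occupied regions), this module assigns to each anchor
the CTS closest to the anchor midpoint, preferring pairs in the
convergent configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .formats_io import GenomicInterval, ParseError, _split_fields
from .motifs import MotifSite

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "read_interactions",
    "write_interactions",
    "intersect_replicates",
    "assign_anchor_cts",
    "annotate_interactions",
    "convergence_summary",
]


@dataclass(frozen=True)
class Interaction:
    """One chromatin interaction: two anchor regions in genomic order."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float = 0.0
    cts1: MotifSite | None = None
    cts2: MotifSite | None = None
    convergent: bool = False

    def __post_init__(self) -> None:
        key1 = (self.anchor1.chrom, self.anchor1.start, self.anchor1.end)
        key2 = (self.anchor2.chrom, self.anchor2.start, self.anchor2.end)
        if key1 > key2:
            raise ValueError("anchor1 must precede anchor2 in genomic order")

    @property
    def anchor_key(self) -> tuple:
        return (
            self.anchor1.chrom,
            self.anchor1.start,
            self.anchor1.end,
            self.anchor2.chrom,
            self.anchor2.start,
            self.anchor2.end,
        )


def _ordered(a1: GenomicInterval, a2: GenomicInterval) -> tuple[GenomicInterval, GenomicInterval]:
    if (a1.chrom, a1.start, a1.end) <= (a2.chrom, a2.start, a2.end):
        return a1, a2
    return a2, a1


def read_interactions(path: str | Path) -> list[Interaction]:
    """Read a paired-anchor "junction BED":
    chrom1 start1 end1 chrom2 start2 end2 [score].  Anchors are sorted
    into genomic order.
    """
    out: list[Interaction] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split_fields(line)
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
                a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
                score = float(f[6]) if len(f) >= 7 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            a1, a2 = _ordered(a1, a2)
            out.append(Interaction(anchor1=a1, anchor2=a2, score=score))
    return out


def write_interactions(path: str | Path, interactions: Iterable[Interaction]) -> None:
    with open(path, "w") as handle:
        for x in interactions:
            handle.write(
                f"{x.anchor1.chrom}\t{x.anchor1.start}\t{x.anchor1.end}\t"
                f"{x.anchor2.chrom}\t{x.anchor2.start}\t{x.anchor2.end}\t"
                f"{x.score:g}\n"
            )


def _reciprocal(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= fraction * a.width and ov >= fraction * b.width


def intersect_replicates(
    rep1: Sequence[Interaction],
    rep2: Sequence[Interaction],
    reciprocal_fraction: float = 1.0,
) -> list[Interaction]:
    """Replicate-consensus interactions by reciprocal anchor overlap.

    An interaction from ``rep1`` is kept iff some interaction in ``rep2``
    overlaps its anchor1 and its anchor2, each reciprocally by at least
    ``reciprocal_fraction`` of both interval lengths (the strict default
    1.0 demands identical anchors).  Output is deduplicated on the
    anchor-pair coordinates.
    """
    if not 0 < reciprocal_fraction <= 1:
        raise ValueError("reciprocal_fraction must be in (0, 1]")
    seen: set[tuple] = set()
    out: list[Interaction] = []
    for x in rep1:
        if x.anchor_key in seen:
            continue
        for y in rep2:
            if _reciprocal(x.anchor1, y.anchor1, reciprocal_fraction) and _reciprocal(
                x.anchor2, y.anchor2, reciprocal_fraction
            ):
                seen.add(x.anchor_key)
                out.append(x)
                break
    return out


def _anchor_candidates(
    anchor: GenomicInterval, cts_catalog: Sequence[MotifSite]
) -> list[tuple[float, MotifSite]]:
    """CTSs contained in the anchor, ranked by distance to its midpoint."""
    mid = anchor.midpoint
    cands = [
        (abs(c.center - mid), c)
        for c in cts_catalog
        if c.chrom == anchor.chrom
        and c.interval.start >= anchor.start
        and c.interval.end <= anchor.end
    ]
    cands.sort(key=lambda t: (t[0], t[1].interval.start))
    return cands


def assign_anchor_cts(
    interaction: Interaction, cts_catalog: Sequence[MotifSite]
) -> Interaction:
    """Fill cts1/cts2 of an interaction from a CTS catalog.

    Among CTSs inside each anchor, the convergent pair (anchor1 CTS "+",
    anchor2 CTS "-") minimizing the summed midpoint distances is chosen
    when one exists; otherwise the closest CTS per anchor is reported
    with ``convergent=False``.  Anchors containing no CTS get none.
    """
    c1 = _anchor_candidates(interaction.anchor1, cts_catalog)
    c2 = _anchor_candidates(interaction.anchor2, cts_catalog)
    best_pair: tuple[float, MotifSite, MotifSite] | None = None
    for d1, s1 in c1:
        if s1.strand != "+":
            continue
        for d2, s2 in c2:
            if s2.strand != "-":
                continue
            key = d1 + d2
            if best_pair is None or key < best_pair[0]:
                best_pair = (key, s1, s2)
    if best_pair is not None:
        return replace(
            interaction, cts1=best_pair[1], cts2=best_pair[2], convergent=True
        )
    return replace(
        interaction,
        cts1=c1[0][1] if c1 else None,
        cts2=c2[0][1] if c2 else None,
        convergent=False,
    )


def annotate_interactions(
    interactions: Sequence[Interaction], cts_catalog: Sequence[MotifSite]
) -> list[Interaction]:
    return [assign_anchor_cts(x, cts_catalog) for x in interactions]


def convergence_summary(interactions: Sequence[Interaction]) -> dict[str, float]:
    """Counts of annotated interactions and the convergent fraction."""
    total = len(interactions)
    both = sum(1 for x in interactions if x.cts1 is not None and x.cts2 is not None)
    convergent = sum(1 for x in interactions if x.convergent)
    return {
        "total": total,
        "both_anchors_assigned": both,
        "convergent": convergent,
        "convergent_fraction": convergent / total if total else float("nan"),
    }
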