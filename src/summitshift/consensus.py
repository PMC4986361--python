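"""Cross-sample consensus summits, CTCF/cohesin co-peak pairing, and
subpeak splitting of composite coverage peaks.

A consensus summit is the averaged position of raw summits observed
reproducibly (>= ``min_samples`` distinct samples) within a small window.
A co-peak is a consensus CTCF summit lying within the pairing window of a
consensus cohesin summit; co-peaks are the loci at which shift analysis
is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats_io import Summit

__all__ = [
    "ConsensusSummit",
    "CoPeak",
    "cluster_summits",
    "pair_copeaks",
    "split_subpeak_summits",
    "write_consensus_bed",
    "write_copeaks_bed",
]


@dataclass(frozen=True)
class ConsensusSummit:
    chrom: str
    position: int  # floor of the arithmetic mean of member positions
    protein_class: str  # "CTCF" or "cohesin"
    n_samples: int  # distinct contributing samples
    members: tuple[Summit, ...] = field(default_factory=tuple, compare=False)


@dataclass(frozen=True)
class CoPeak:
    ctcf: ConsensusSummit
    cohesin: ConsensusSummit

    def __post_init__(self) -> None:
        if self.ctcf.chrom != self.cohesin.chrom:
            raise ValueError("co-peak members must share a chromosome")

    @property
    def chrom(self) -> str:
        return self.ctcf.chrom

    @property
    def distance(self) -> int:
        """Signed bp offset cohesin - CTCF in genomic orientation."""
        return self.cohesin.position - self.ctcf.position


def cluster_summits(
    summits: Sequence[Summit],
    max_span: int = 50,
    min_samples: int = 2,
    protein_class: str = "",
) -> list[ConsensusSummit]:
    """Chain position-sorted summits into consensus summits.

    Per chromosome, summits are sorted by position and chained while the
    gap to the previous member is <= ``max_span`` AND the chain's total
    span (max - min member position) stays <= ``max_span``; the span cap
    prevents chained drift far beyond the window.  Chains contributed by
    >= ``min_samples`` distinct samples become a ``ConsensusSummit`` at
    the floored mean position; smaller chains are discarded.

    Output is invariant to input order (ties broken by sample then
    protein label during the sort).
    """
    if max_span < 0:
        raise ValueError("max_span must be >= 0")
    by_chrom: dict[str, list[Summit]] = {}
    for s in summits:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[ConsensusSummit] = []
    for chrom in sorted(by_chrom):
        chain: list[Summit] = []
        ordered = sorted(
            by_chrom[chrom], key=lambda s: (s.position, s.sample_id, s.protein)
        )
        for s in ordered:
            if chain and (
                s.position - chain[-1].position > max_span
                or s.position - chain[0].position > max_span
            ):
                _emit_chain(chain, min_samples, protein_class, out)
                chain = []
            chain.append(s)
        _emit_chain(chain, min_samples, protein_class, out)
    return out


def _emit_chain(
    chain: list[Summit],
    min_samples: int,
    protein_class: str,
    out: list[ConsensusSummit],
) -> None:
    if not chain:
        return
    n_samples = len({s.sample_id for s in chain})
    if n_samples < min_samples:
        return
    positions = [s.position for s in chain]
    out.append(
        ConsensusSummit(
            chrom=chain[0].chrom,
            position=int(np.floor(np.mean(positions))),
            protein_class=protein_class or chain[0].protein,
            n_samples=n_samples,
            members=tuple(chain),
        )
    )


def pair_copeaks(
    ctcf: Sequence[ConsensusSummit],
    cohesin: Sequence[ConsensusSummit],
    max_dist: int = 50,
) -> list[CoPeak]:
    """Pair each consensus CTCF summit with its nearest consensus cohesin
    summit at distance <= ``max_dist`` bp.

    CTCF summits with no cohesin in range are dropped.  The mapping is
    nearest-neighbor, not bijective: one cohesin consensus may serve
    several CTCF summits.  Distance ties resolve to the cohesin summit at
    the smaller genomic position.
    """
    by_chrom: dict[str, list[ConsensusSummit]] = {}
    for c in cohesin:
        by_chrom.setdefault(c.chrom, []).append(c)
    for lst in by_chrom.values():
        lst.sort(key=lambda c: c.position)
    out: list[CoPeak] = []
    for cs in sorted(ctcf, key=lambda c: (c.chrom, c.position)):
        cands = by_chrom.get(cs.chrom)
        if not cands:
            continue
        positions = np.array([c.position for c in cands])
        i = int(np.searchsorted(positions, cs.position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(cands):
                d = abs(cands[j].position - cs.position)
                if best is None or d < best[0]:
                    best = (d, cands[j])
        if best is not None and best[0] <= max_dist:
            out.append(CoPeak(ctcf=cs, cohesin=best[1]))
    return out


def split_subpeak_summits(
    depth: Sequence[float],
    min_height: float,
    min_valley_frac: float = 0.5,
    start: int = 0,
) -> list[int]:
    """Split a per-bp coverage profile into well-separated subpeak summits.

    Returns the positions (``start`` + index) of all local maxima with
    depth >= ``min_height`` such that between any two reported maxima the
    depth drops below ``min_valley_frac`` times the lower of the two.
    Plateaus report their center bp.  Candidates are admitted highest
    first (ties to the smaller position), so of two insufficiently
    separated peaks the higher survives.
    """
    d = np.asarray(depth, dtype=float)
    if d.size == 0 or not np.any(d > 0):
        return []
    # plateau-aware local maxima
    candidates: list[tuple[int, float]] = []  # (center index, height)
    i = 0
    n = d.size
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        left_ok = i == 0 or d[i - 1] < d[i]
        right_ok = j == n - 1 or d[j + 1] < d[i]
        if left_ok and right_ok and d[i] >= min_height:
            candidates.append(((i + j) // 2, float(d[i])))
        i = j + 1
    accepted: list[tuple[int, float]] = []
    for idx, h in sorted(candidates, key=lambda c: (-c[1], c[0])):
        ok = True
        for aidx, ah in accepted:
            lo, hi = min(idx, aidx), max(idx, aidx)
            valley = float(d[lo : hi + 1].min())
            if valley >= min_valley_frac * min(h, ah):
                ok = False
                break
        if ok:
            accepted.append((idx, h))
    return [start + idx for idx, _ in sorted(accepted)]


def write_consensus_bed(path: str | Path, consensus: Iterable[ConsensusSummit]) -> None:
    """BED5 + protein class + n_samples extra columns."""
    with open(path, "w") as handle:
        for c in consensus:
            handle.write(
                f"{c.chrom}\t{c.position}\t{c.position + 1}\t{c.protein_class}\t"
                f"{c.n_samples}\t{c.protein_class}\t{c.n_samples}\n"
            )


def write_copeaks_bed(path: str | Path, copeaks: Iterable[CoPeak]) -> None:
    with open(path, "w") as handle:
        for cp in copeaks:
            lo = min(cp.ctcf.position, cp.cohesin.position)
            hi = max(cp.ctcf.position, cp.cohesin.position) + 1
            handle.write(
                f"{cp.chrom}\t{lo}\t{hi}\tcopeak\t{cp.distance}\t"
                f"{cp.ctcf.position}\t{cp.cohesin.position}\n"
            )
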