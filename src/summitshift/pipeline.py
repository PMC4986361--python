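"""End-to-end orchestration: summits + genome + PWM -> consensus summits
-> co-peaks -> CTS assignment -> strand-specific shift tables -> summaries,
with optional statistics, helix projection, and loop annotation stages.

All thresholds default to the measured-study values (50 bp consensus
span and pairing windows, PWM log-odds threshold 6, 5 bp smoothing,
10.5 bp/turn helix) and every one is a parameter, never a hard-code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import (
    CoPeak,
    ConsensusSummit,
    cluster_summits,
    pair_copeaks,
    write_consensus_bed,
    write_copeaks_bed,
)
from .formats_io import (
    GenomicInterval,
    PWM,
    Summit,
    filter_blacklist,
    read_fasta,
    read_intervals,
    read_pwm,
    read_summits,
)
from .motifs import (
    CtsAssignment,
    MotifSite,
    assign_cts,
    scan_genome,
    write_assignments_tsv,
    write_cts_bed,
)
from .shifts import records_to_frame, summarize_shifts, summit_shift_table

logger = logging.getLogger(__name__)

CTCF_LABEL = "CTCF"

__all__ = [
    "ShiftParams",
    "ShiftResult",
    "run_shift_analysis",
    "run_shift_from_objects",
    "run_shift_from_dataset",
]


@dataclass
class ShiftParams:
    max_span: int = 50  # consensus chain span cap, bp
    pair_window: int = 50  # CTCF-cohesin co-peak pairing window, bp
    pwm_threshold: float = 6.0  # natural-log odds
    cts_window: int = 50  # CTS candidate window around the CTCF consensus
    pairing_window: int = 50  # summit-to-CTS pairing window for shift records
    min_samples: int = 2
    smooth_window: int = 5

    def validate(self) -> None:
        for name in ("max_span", "pair_window", "cts_window", "pairing_window",
                     "min_samples", "smooth_window"):
            if getattr(self, name) <= 0 and name != "max_span":
                raise ValueError(f"{name} must be positive")
        if self.max_span < 0:
            raise ValueError("max_span must be >= 0")


@dataclass
class ShiftResult:
    consensus_ctcf: list[ConsensusSummit]
    consensus_cohesin: list[ConsensusSummit]
    copeaks: list[CoPeak]
    cts_sites: list[MotifSite]
    assignments: list[CtsAssignment]
    records: pd.DataFrame  # protein, sample_id, cts_id, offset
    summaries: pd.DataFrame  # per-protein distribution summary
    summaries_by_sample: pd.DataFrame
    params: ShiftParams = field(default_factory=ShiftParams)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_consensus_bed(outdir / "consensus_ctcf.bed", self.consensus_ctcf)
        write_consensus_bed(outdir / "consensus_cohesin.bed", self.consensus_cohesin)
        write_copeaks_bed(outdir / "copeaks.bed", self.copeaks)
        write_cts_bed(outdir / "cts_assigned.bed",
                      [a.cts for a in self.assignments if a.cts is not None])
        write_assignments_tsv(outdir / "cts_assignments.tsv", self.assignments)
        self.records.to_csv(outdir / "shift_records.tsv", sep="\t", index=False)
        self.summaries.to_csv(outdir / "shift_summary.tsv", sep="\t", index=False)
        self.summaries_by_sample.to_csv(
            outdir / "shift_summary_by_sample.tsv", sep="\t", index=False
        )
        manifest = {
            "package": "summitshift",
            "version": __version__,
            "params": self.params.__dict__,
            "n_consensus_ctcf": len(self.consensus_ctcf),
            "n_consensus_cohesin": len(self.consensus_cohesin),
            "n_copeaks": len(self.copeaks),
            "n_cts_assigned": sum(1 for a in self.assignments if a.cts is not None),
            "n_shift_records": int(len(self.records)),
        }
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)


def run_shift_from_objects(
    summits: list[Summit],
    genome: dict[str, str],
    pwm: PWM,
    params: ShiftParams | None = None,
    blacklist: list[GenomicInterval] | None = None,
    cts_candidates: list[MotifSite] | None = None,
) -> ShiftResult:
    """Core pipeline on in-memory objects.

    ``summits`` must contain >= 2 CTCF samples (protein label "CTCF")
    and >= 1 cohesin-class sample; everything that is not CTCF is
    treated as cohesin for consensus building.  ``cts_candidates`` lets
    a caller reuse a precomputed genome scan.
    """
    params = params or ShiftParams()
    params.validate()
    if blacklist:
        summits = filter_blacklist(summits, blacklist)
    ctcf_summits = [s for s in summits if s.protein == CTCF_LABEL]
    cohesin_summits = [s for s in summits if s.protein != CTCF_LABEL]
    n_ctcf_samples = len({s.sample_id for s in ctcf_summits})
    n_cohesin_samples = len({s.sample_id for s in cohesin_summits})
    if n_ctcf_samples < params.min_samples:
        raise ValueError(
            f"need >= {params.min_samples} CTCF samples, got {n_ctcf_samples}"
        )
    if n_cohesin_samples < 1:
        raise ValueError("need at least one cohesin-class sample")

    consensus_ctcf = cluster_summits(
        ctcf_summits, max_span=params.max_span, min_samples=params.min_samples,
        protein_class="CTCF",
    )
    consensus_cohesin = cluster_summits(
        cohesin_summits, max_span=params.max_span, min_samples=params.min_samples,
        protein_class="cohesin",
    )
    copeaks = pair_copeaks(consensus_ctcf, consensus_cohesin,
                           max_dist=params.pair_window)
    if cts_candidates is None:
        cts_candidates = scan_genome(genome, pwm, threshold=params.pwm_threshold)
    if blacklist:
        cts_candidates = filter_blacklist(cts_candidates, blacklist)
    # bucket candidates by chromosome for the per-co-peak window query
    by_chrom: dict[str, list[MotifSite]] = {}
    for c in cts_candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    assignments = [
        assign_cts(cp, by_chrom.get(cp.chrom, ()), window=params.cts_window)
        for cp in copeaks
    ]
    records = summit_shift_table(
        summits, assignments, pairing_window=params.pairing_window
    )
    frame = records_to_frame(records)
    if frame.empty:
        logger.warning("pipeline produced no shift records")
        summaries = summarize_shifts(frame)
        by_sample = summaries
    else:
        summaries = summarize_shifts(frame, by="protein")
        by_sample = summarize_shifts(frame, by="protein_sample")
    return ShiftResult(
        consensus_ctcf=consensus_ctcf,
        consensus_cohesin=consensus_cohesin,
        copeaks=copeaks,
        cts_sites=cts_candidates,
        assignments=assignments,
        records=frame,
        summaries=summaries,
        summaries_by_sample=by_sample,
        params=params,
    )


def run_shift_from_dataset(dataset, params: ShiftParams | None = None) -> ShiftResult:
    """Run the core pipeline on a ``SyntheticDataset``."""
    return run_shift_from_objects(
        summits=dataset.summits,
        genome=dataset.genome,
        pwm=dataset.pwm,
        params=params,
    )


def run_shift_analysis(
    manifest_path: str | Path,
    genome_path: str | Path,
    pwm_path: str | Path,
    outdir: str | Path,
    params: ShiftParams | None = None,
    blacklist_path: str | Path | None = None,
    pwm_pseudocount: float = 1e-3,
) -> ShiftResult:
    """File-based pipeline entry point.

    The manifest is a TSV with columns ``sample_id``, ``protein``,
    ``summits`` (path, relative paths resolved against the manifest
    location); extra columns are ignored.  Inputs are validated before
    any computation starts.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("sample_id", "protein", "summits"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    paths = []
    for _, row in manifest.iterrows():
        p = Path(row["summits"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"summit file not found: {p}")
        paths.append(p)
    for p in (Path(genome_path), Path(pwm_path)):
        if not p.exists():
            raise FileNotFoundError(p)

    summits: list[Summit] = []
    for p, (_, row) in zip(paths, manifest.iterrows()):
        summits.extend(read_summits(p, str(row["sample_id"]), str(row["protein"])))
    genome = read_fasta(genome_path)
    pwm = read_pwm(pwm_path, pseudocount=pwm_pseudocount)
    blacklist = read_intervals(blacklist_path) if blacklist_path else None
    result = run_shift_from_objects(
        summits, genome, pwm, params=params, blacklist=blacklist
    )
    result.write(outdir)
    return result
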