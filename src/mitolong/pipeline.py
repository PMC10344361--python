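"""End-to-end orchestration: reads → alignments → calls → estimates → plot.

`analyze_reads` is the in-memory pipeline used by the CLI, the tests and
the acceptance script; `run_pipeline` wraps it with file input/output
(FASTQ in; alignments TSV, calls VCF, estimates TSV, bedGraph, circular
plot, point-variant VCF, recommendation and run log out).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import align as _align
from . import pointvar as _pointvar
from . import quantify as _quantify
from . import svcall as _svcall
from . import viz as _viz
from .refgenome import CircularReference, RestrictionEnzyme, cut_positions, load_reference
from .simulate import SimRead

__all__ = ["PipelineParams", "PipelineResult", "analyze_reads", "run_pipeline", "read_fastq"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    align: _align.AlignParams = field(default_factory=_align.AlignParams)
    min_del_size: int = 100
    tol: int = 50
    min_support: int = 2
    margin: int = 100
    spike_halfwidth: int = 300
    min_flank: int = 50
    mode: str = "transposase"
    enzyme: RestrictionEnzyme | None = None
    call_point_variants: bool = False
    min_h: float = 0.05
    min_depth: int = 20


@dataclass
class PipelineResult:
    alignments: list[_align.ReadAlignment]
    profile: _quantify.CoverageProfile
    calls: list[_svcall.DeletionCall]
    estimates: list[_quantify.HeteroplasmyEstimate]
    recommendation: _quantify.Recommendation
    point_variants: list | None = None
    n_unmapped: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.alignments) - self.n_unmapped


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load (read_id, sequence) pairs from FASTQ via Biopython."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def analyze_reads(
    reads: Sequence[SimRead] | Sequence[tuple[str, str]],
    ref: CircularReference,
    params: PipelineParams | None = None,
    alignments: Sequence[_align.ReadAlignment] | None = None,
) -> PipelineResult:
    """Run alignment, deletion calling and quantification over reads.

    Pre-computed ``alignments`` may be supplied (e.g. after downsampling)
    to skip the alignment stage.
    """
    params = params or PipelineParams()
    L = ref.length
    if alignments is None:
        index = _align.index_reference(ref, params.align.k, params.align.max_occ)
        alignments = _align.align_reads(reads, index, params.align)
    alignments = list(alignments)
    n_unmapped = sum(1 for a in alignments if not a.mapped)

    profile = _quantify.coverage_profile(alignments, ref)
    signals = _svcall.extract_del_signals(alignments, params.min_del_size, L)
    calls = _svcall.cluster_signals(signals, params.tol, params.min_support, L)

    sites = cut_positions(ref, params.enzyme) if params.enzyme is not None else []
    excluded = _quantify.enzyme_exclusion_zones(sites, L, params.spike_halfwidth)

    estimates = []
    for call in calls:
        flags: set[str] = set()
        if any(call.contains(s, L) for s in sites):
            flags.add("enzyme_site_in_deletion")
        h_cov = None
        if len(calls) == 1:
            # the coverage ratio is confounded when deletions overlap
            try:
                h_cov = _quantify.heteroplasmy_coverage_ratio(
                    profile, call, params.margin, excluded
                )
            except ValueError as exc:
                logger.warning("coverage-ratio estimate unavailable: %s", exc)
        h_span = _quantify.heteroplasmy_spanning_reads(
            alignments, call, L, params.min_flank, params.tol
        )
        outside_mean = profile.mean_depth
        if outside_mean < 100:
            flags.add("low_coverage")
        estimates.append(
            _quantify.HeteroplasmyEstimate(call, h_cov, h_span, flags)
        )

    recommendation = _quantify.recommend_next_step(calls, sites, params.mode, L)

    point_variants = None
    if params.call_point_variants:
        read_dict = {
            (r.read_id if hasattr(r, "read_id") else r[0]): (
                r.sequence if hasattr(r, "sequence") else r[1]
            )
            for r in reads
        }
        counts = _pointvar.pileup(alignments, read_dict, ref)
        point_variants = _pointvar.call_point_variants(
            counts, params.min_h, params.min_depth
        )

    return PipelineResult(
        alignments=alignments,
        profile=profile,
        calls=calls,
        estimates=estimates,
        recommendation=recommendation,
        point_variants=point_variants,
        n_unmapped=n_unmapped,
    )


def _write_estimates_tsv(estimates, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tsize\tsupport\th_coverage\th_spanning\tflags\n")
        for e in estimates:
            fh.write(
                f"{e.call.start}\t{e.call.end}\t{e.call.size}\t{e.call.support}\t"
                f"{e.format_h('coverage')}\t{e.format_h('spanning')}\t"
                f"{','.join(sorted(e.flags)) or '.'}\n"
            )


def run_pipeline(
    fastq_path: str | Path,
    ref_or_fasta: CircularReference | str | Path,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    annotations: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
    write_sam: bool = False,
) -> PipelineResult:
    """File-based pipeline; writes every artifact into ``out_dir``."""
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = (
        ref_or_fasta
        if isinstance(ref_or_fasta, CircularReference)
        else load_reference(ref_or_fasta)
    )
    reads = read_fastq(fastq_path)
    result = analyze_reads(reads, ref, params)

    _align.write_alignments_tsv(result.alignments, out / "alignments.tsv")
    if write_sam:
        _align.write_sam(result.alignments, dict(reads), ref, out / "alignments.sam")
    _svcall.write_vcf(result.calls, ref, out / "calls.vcf")
    _write_estimates_tsv(result.estimates, out / "estimates.tsv")
    _quantify.write_bedgraph(result.profile, ref.name, out / "coverage.bedgraph")
    _viz.circular_plot(result.profile, result.calls, list(annotations), out / "plot.svg")
    if result.point_variants is not None:
        _pointvar.write_snv_vcf(result.point_variants, ref, out / "point_variants.vcf")
    (out / "recommendation.txt").write_text(result.recommendation.value + "\n")

    log = {
        "seed": seed,
        "fastq": str(fastq_path),
        "reference": ref.name,
        "reference_length": ref.length,
        "n_reads": len(reads),
        "n_mapped": result.n_mapped,
        "n_unmapped": result.n_unmapped,
        "mean_depth": result.profile.mean_depth,
        "n_calls": len(result.calls),
        "recommendation": result.recommendation.value,
        "params": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else getattr(v, "name", v))
            for k, v in dataclasses.asdict(params).items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return result
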