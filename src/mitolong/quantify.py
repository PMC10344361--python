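"""Coverage profiling, heteroplasmy estimation, downsampling and the
protocol-selection rule.

Deletion heteroplasmy is estimated two ways:

* **coverage ratio** — ``h = 1 - mean(depth inside the deletion) /
  mean(depth outside)``, with breakpoint margins trimmed on both sides and
  user-specified regions (e.g. the coverage spike around a linearization
  site) excluded from the outside mean;
* **spanning reads** — ``h = J / (J + W)`` where J counts reads whose
  reference gap matches the call and W counts reads aligned contiguously
  across either breakpoint, each with a minimum aligned flank.

The coverage ratio mirrors how heteroplasmy is read off an IGV coverage
track; the spanning-read estimator is junction evidence and remains
meaningful when several deletions overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import ReadAlignment
from .refgenome import CircularReference, circular_distance, circular_gap
from .svcall import DeletionCall

__all__ = [
    "CoverageProfile",
    "HeteroplasmyEstimate",
    "Recommendation",
    "coverage_profile",
    "heteroplasmy_coverage_ratio",
    "heteroplasmy_spanning_reads",
    "downsample",
    "mtdna_ratio",
    "recommend_next_step",
    "enzyme_exclusion_zones",
    "write_bedgraph",
]

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Per-base depth over the circular reference (index 0 = position 1)."""

    depth: np.ndarray
    n_reads: int

    @property
    def length(self) -> int:
        return len(self.depth)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


@dataclass
class HeteroplasmyEstimate:
    call: DeletionCall
    h_coverage: float | None
    h_spanning: float | None
    flags: set[str] = field(default_factory=set)

    def format_h(self, which: str = "coverage") -> str:
        h = self.h_coverage if which == "coverage" else self.h_spanning
        return "NA" if h is None else f"{100.0 * h:.1f}"


class Recommendation(str, Enum):
    """Terminal / follow-up statuses of the protocol-selection workflow."""

    DONE_NEGATIVE = "done_negative"
    DONE_SINGLE_DELETION = "done_single_deletion"
    DONE_MULTIPLE_DELETIONS = "done_multiple_deletions"
    REDIGEST_PVUII = "redigest_pvuii"
    USE_RAPID_KIT = "use_rapid_kit"


def coverage_profile(
    alignments: Sequence[ReadAlignment], ref: CircularReference
) -> CoverageProfile:
    """Per-base depth: each aligned segment increments its reference span
    (modulo L); reference gaps contribute nothing."""
    L = ref.length
    depth = np.zeros(L, dtype=np.int64)
    n_mapped = 0
    for aln in alignments:
        if not aln.mapped:
            continue
        n_mapped += 1
        for s in aln.segments:
            if s.ref_start <= s.ref_end:
                depth[s.ref_start - 1 : s.ref_end] += 1
            else:  # wraps the origin
                depth[s.ref_start - 1 :] += 1
                depth[: s.ref_end] += 1
    return CoverageProfile(depth=depth, n_reads=n_mapped)


def _interval_mask(L: int, start: int, end: int) -> np.ndarray:
    """Boolean mask of circular bases ``start .. end-1`` (right-open)."""
    mask = np.zeros(L, dtype=bool)
    gap = circular_gap(start, end, L)
    idx = (np.arange(gap) + start - 1) % L
    mask[idx] = True
    return mask


def enzyme_exclusion_zones(
    cut_sites: Sequence[int], L: int, halfwidth: int = 300
) -> list[tuple[int, int]]:
    """±``halfwidth`` bases around each linearization site (coverage spike)."""
    zones = []
    for s in cut_sites:
        lo = ((s - halfwidth - 1) % L) + 1
        hi = ((s + halfwidth - 1) % L) + 1
        zones.append((lo, hi))
    return zones


def heteroplasmy_coverage_ratio(
    profile: CoverageProfile,
    call: DeletionCall,
    margin: int = 100,
    excluded_regions: Sequence[tuple[int, int]] = (),
) -> float:
    """``1 - mean(depth inside)/mean(depth outside)``, clamped to [0, 1].

    ``margin`` bases are trimmed on both sides of each breakpoint (inside
    and outside), and ``excluded_regions`` (1-based inclusive intervals,
    e.g. from :func:`enzyme_exclusion_zones`) are removed from the
    outside mean.
    """
    L = profile.length
    size = call.size
    if size - 2 * margin < 1:
        raise ValueError("deleted interval empty after margin trimming")
    inside = _interval_mask(L, ((call.start + margin - 1) % L) + 1,
                            ((call.end - margin - 1) % L) + 1)
    outside = _interval_mask(L, ((call.end + margin - 1) % L) + 1,
                             ((call.start - margin - 1) % L) + 1)
    for lo, hi in excluded_regions:
        outside &= ~_interval_mask(L, lo, (hi % L) + 1)
    if not outside.any():
        raise ValueError("no outside bases left after exclusions")
    mean_out = float(profile.depth[outside].mean())
    if mean_out == 0:
        raise ValueError("outside mean depth is zero")
    mean_in = float(profile.depth[inside].mean())
    return float(np.clip(1.0 - mean_in / mean_out, 0.0, 1.0))


def _segment_spans(seg, pos: int, min_flank: int, L: int) -> bool:
    """Does the segment cover ``pos-min_flank .. pos+min_flank-1`` contiguously?"""
    span = circular_gap(seg.ref_start, seg.ref_end, L) + 1
    lo = ((pos - min_flank - 1) % L) + 1
    off = circular_gap(seg.ref_start, lo, L)
    return off + 2 * min_flank <= span


def heteroplasmy_spanning_reads(
    alignments: Sequence[ReadAlignment],
    call: DeletionCall,
    length: int,
    min_flank: int = 50,
    tol: int = 50,
) -> float | None:
    """Junction-read estimator ``h = J / (J + W)``; ``None`` when no read
    touches either breakpoint.

    J counts reads with a reference gap matching the call (both breakpoints
    within ``tol`` circular distance) and >= ``min_flank`` aligned bases on
    both sides of the gap.  W is the *per-breakpoint average* count of reads
    aligned contiguously across a breakpoint with >= ``min_flank`` bases on
    both sides: an intact circle presents two separate breakpoint loci while
    the deleted molecule presents one junction, so averaging the two
    wild-type crossing counts (rather than summing reads that cross either
    locus) keeps the estimator centred on the molecule fraction.
    """
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    L = length
    J = 0
    w1 = w2 = 0
    for aln in alignments:
        if not aln.mapped or not aln.segments:
            continue
        is_junction = False
        for i, (gs, ge) in enumerate(aln.ref_gaps):
            if (
                circular_distance(gs, call.start, L) <= tol
                and circular_distance(ge, call.end, L) <= tol
            ):
                left, right = aln.segments[i], aln.segments[i + 1]
                if (
                    left.read_end - left.read_start + 1 >= min_flank
                    and right.read_end - right.read_start + 1 >= min_flank
                ):
                    is_junction = True
                    break
        if is_junction:
            J += 1
            continue
        for seg in aln.segments:
            if _segment_spans(seg, call.start, min_flank, L):
                w1 += 1
            if _segment_spans(seg, call.end, min_flank, L):
                w2 += 1
    if J + w1 + w2 == 0:
        return None
    W = (w1 + w2) / 2.0
    return J / (J + W)


def write_bedgraph(profile: CoverageProfile, name: str, path: str | Path) -> None:
    """Export depth as bedGraph (0-based, half-open, runs collapsed)."""
    d = profile.depth
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(d) + 1):
            if i == len(d) or d[i] != d[start]:
                fh.write(f"{name}\t{start}\t{i}\t{int(d[start])}\n")
                start = i


def downsample(
    alignments: Sequence[ReadAlignment],
    target_mean_depth: float,
    ref: CircularReference,
    rng: np.random.Generator,
) -> list[ReadAlignment]:
    """Random read subsampling without replacement down to a mean depth.

    Reads are removed in a random order until the mean depth first drops
    to <= ``target_mean_depth``; deterministic given the generator state.
    """
    L = ref.length
    bases = np.array(
        [
            sum(circular_gap(s.ref_start, s.ref_end, L) + 1 for s in a.segments)
            if a.mapped
            else 0
            for a in alignments
        ],
        dtype=np.int64,
    )
    total = int(bases.sum())
    if target_mean_depth > total / L + 1e-9:
        raise ValueError(
            f"target depth {target_mean_depth} exceeds current {total / L:.1f}"
        )
    if total / L <= target_mean_depth:
        return list(alignments)
    order = rng.permutation(len(alignments))
    removed = np.cumsum(bases[order])
    means = (total - removed) / L
    # smallest number of removals bringing the mean to <= target
    n_remove = int(np.searchsorted(-means, -target_mean_depth)) + 1
    drop = set(order[:n_remove].tolist())
    return [a for i, a in enumerate(alignments) if i not in drop]


def mtdna_ratio(n_mapped_mt: int, n_unmapped_or_nuclear: int) -> float:
    """mtDNA/nDNA read-count ratio (relative mtDNA content)."""
    if n_unmapped_or_nuclear <= 0:
        raise ValueError("denominator must be > 0")
    return n_mapped_mt / n_unmapped_or_nuclear


def recommend_next_step(
    calls: Sequence[DeletionCall],
    enzyme_sites: Sequence[int],
    mode: str,
    length: int,
) -> Recommendation:
    """Protocol-selection rule for the next sequencing step.

    Endonuclease (Ligation-kit) runs: a single deletion containing the
    linearization site is unreliable (heteroplasmy underestimated) →
    re-digest with PvuII; two or more calls suggest multiple deletions →
    re-sequence with the Rapid kit.  Transposase runs are unbiased and
    always terminal.
    """
    if mode not in ("endonuclease", "transposase"):
        raise ValueError(f"unknown mode {mode!r}")
    if not calls:
        rec = Recommendation.DONE_NEGATIVE
    elif mode == "transposase":
        rec = (
            Recommendation.DONE_SINGLE_DELETION
            if len(calls) == 1
            else Recommendation.DONE_MULTIPLE_DELETIONS
        )
    elif len(calls) >= 2:
        rec = Recommendation.USE_RAPID_KIT
    else:
        call = calls[0]
        if any(call.contains(s, length) for s in enzyme_sites):
            rec = Recommendation.REDIGEST_PVUII
        else:
            rec = Recommendation.DONE_SINGLE_DELETION
    logger.info(
        "recommendation %s (mode=%s, calls=%d, sites=%s)",
        rec.value, mode, len(calls), list(enzyme_sites),
    )
    return rec
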