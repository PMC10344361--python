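"""Naive pileup point-variant calling with exact binomial intervals.

Substituted/matching read bases are counted per reference position
(read indels and inserted bases are excluded, as are positions inside a
read's deletion gap).  Site heteroplasmy is the alternate-base fraction
with a Clopper-Pearson exact two-sided confidence interval — asymmetric
at the boundary, where the upper bound for zero alternate reads out of n
is ``1 - (alpha/2)^(1/n)``.  The mean of these per-site upper bounds over
a control sample is the sequencing error floor: sites below it cannot be
distinguished from noise, which is why the practical heteroplasmy
detection limit for nanopore point variants sits around 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
from scipy.stats import beta

from .align import ReadAlignment
from .refgenome import CircularReference, circular_slice
from .simulate import reverse_complement

__all__ = [
    "PositionCounts",
    "PointVariant",
    "pileup",
    "site_heteroplasmy_ci",
    "call_point_variants",
    "error_rate_summary",
    "write_snv_vcf",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class PositionCounts:
    """Per-position A/C/G/T counts over the reference circle.

    ``counts`` has shape (4, L); ``ref_sequence`` is kept so alternate
    fractions can be computed against the reference base.
    """

    counts: np.ndarray
    ref_sequence: str

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def ref_base_index(self) -> np.ndarray:
        arr = np.frombuffer(self.ref_sequence.encode(), dtype=np.uint8)
        idx = np.full(len(arr), -1, dtype=np.int64)
        for b, i in _BASE_IDX.items():
            idx[arr == ord(b)] = i
        return idx

    def alt_counts(self) -> np.ndarray:
        """Non-reference base count per position (N reference bases -> all)."""
        ridx = self.ref_base_index()
        depth = self.depth
        ref_count = np.zeros(self.length, dtype=np.int64)
        valid = ridx >= 0
        ref_count[valid] = self.counts[ridx[valid], np.flatnonzero(valid)]
        return depth - ref_count


@dataclass(frozen=True)
class PointVariant:
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    h: float
    ci_low: float
    ci_high: float


def pileup(
    alignments: Sequence[ReadAlignment],
    reads: dict[str, str],
    ref: CircularReference,
) -> PositionCounts:
    """Count matching/substituted bases per reference position.

    Base-level correspondence is recovered per segment by global
    edit-distance alignment; insertions and deletions are skipped, and
    reference positions inside a read's deletion gap contribute nothing.
    """
    L = ref.length
    counts = np.zeros((4, L), dtype=np.int64)
    for aln in alignments:
        if not aln.mapped:
            continue
        seq = reads.get(aln.read_id)
        if seq is None:
            continue
        oriented = seq if aln.strand == "+" else reverse_complement(seq)
        for seg in aln.segments:
            read_seg = oriented[seg.read_start - 1 : seg.read_end]
            ref_seg = circular_slice(ref.sequence, seg.ref_start, seg.ref_end + 1)
            if not read_seg or not ref_seg:
                continue
            res = edlib.align(read_seg, ref_seg, mode="NW", task="path")
            _accumulate(counts, res["cigar"], read_seg, seg.ref_start, L)
    return PositionCounts(counts=counts, ref_sequence=ref.sequence)


def _accumulate(counts: np.ndarray, cigar: str, read_seg: str, ref_start: int, L: int) -> None:
    q = 0  # read offset
    t = ref_start - 1  # 0-based reference offset (may exceed L-1 before modulo)
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            for i in range(ln):
                b = _BASE_IDX.get(read_seg[q + i])
                if b is not None:
                    counts[b, (t + i) % L] += 1
            q += ln
            t += ln
        elif ch == "I":
            q += ln
        elif ch == "D":
            t += ln


def site_heteroplasmy_ci(
    alt_count: int, depth: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Alternate fraction with its Clopper-Pearson exact interval.

    Returns ``(h, lower, upper)``.  At the boundaries the interval is
    one-sided in closed form: ``upper = 1 - (alpha/2)^(1/n)`` for zero
    successes (and symmetrically for ``alt_count == depth``).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count outside [0, depth]")
    alpha = 1.0 - level
    h = alt_count / depth
    lower = 0.0 if alt_count == 0 else float(beta.ppf(alpha / 2, alt_count, depth - alt_count + 1))
    upper = 1.0 if alt_count == depth else float(beta.ppf(1 - alpha / 2, alt_count + 1, depth - alt_count))
    return h, lower, upper


def _cp_upper(alt: np.ndarray, depth: np.ndarray, level: float) -> np.ndarray:
    alpha = 1.0 - level
    upper = np.ones(len(alt))
    interior = alt < depth
    upper[interior] = beta.ppf(
        1 - alpha / 2, alt[interior] + 1, (depth - alt)[interior]
    )
    return upper


def call_point_variants(
    counts: PositionCounts,
    min_h: float = 0.05,
    min_depth: int = 20,
    level: float = 0.95,
) -> list[PointVariant]:
    """Positions whose strongest non-reference base reaches ``min_h``.

    ``min_h`` defaults to 0.05, the practical nanopore detection floor.
    Thresholding uses the point estimate only; the exact interval is
    reported, never used to drop a call.
    """
    if min_h < 0 or min_depth < 0:
        raise ValueError("thresholds must be >= 0")
    depth = counts.depth
    ridx = counts.ref_base_index()
    out = []
    for pos0 in np.flatnonzero(depth >= max(min_depth, 1)):
        r = ridx[pos0]
        col = counts.counts[:, pos0]
        alt_candidates = [(int(col[b]), b) for b in range(4) if b != r]
        alt_count, b = max(alt_candidates)
        h = alt_count / depth[pos0]
        if h < min_h:
            continue
        h, lo, hi = site_heteroplasmy_ci(alt_count, int(depth[pos0]), level)
        out.append(
            PointVariant(
                position=int(pos0) + 1,
                ref=counts.ref_sequence[pos0],
                alt=_BASES[b],
                alt_count=alt_count,
                depth=int(depth[pos0]),
                h=h,
                ci_low=lo,
                ci_high=hi,
            )
        )
    return out


def error_rate_summary(
    counts: PositionCounts, level: float = 0.95
) -> tuple[float, float]:
    """Mean ± sd of the per-site upper CI bound of the alternate fraction.

    Averaged over covered positions only; on a clean control sample this
    is the sequencing error floor for point-variant detection.
    """
    depth = counts.depth
    covered = depth >= 1
    if not covered.any():
        raise ValueError("no covered positions")
    alt = counts.alt_counts()[covered]
    upper = _cp_upper(alt, depth[covered], level)
    return float(upper.mean()), float(upper.std(ddof=0))


_SNV_HEADER = """\
##fileformat=VCFv4.2
##source=mitolong-pointvar
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate (heteroplasmy) fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">
##INFO=<ID=CILOW,Number=1,Type=Float,Description="Clopper-Pearson lower bound">
##INFO=<ID=CIHIGH,Number=1,Type=Float,Description="Clopper-Pearson upper bound">
##contig=<ID={name},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snv_vcf(
    variants: Sequence[PointVariant], ref: CircularReference, path: str | Path
) -> None:
    lines = [_SNV_HEADER.format(name=ref.name, length=ref.length)]
    for v in variants:
        info = f"AF={v.h:.4f};DP={v.depth};CILOW={v.ci_low:.4f};CIHIGH={v.ci_high:.4f}"
        lines.append(f"{ref.name}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
    Path(path).write_text("".join(lines))
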