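"""Circular-aware long-read alignment by k-mer anchoring and gapped chaining.

The reference circle is indexed as a doubled sequence so that alignments
may cross the origin.  For each read, exact k-mer anchors are chained by
dynamic programming with a concave (logarithmic) reference-gap penalty:
a multi-kilobase deletion between two co-linear anchor blocks is cheap,
while co-linearity itself is enforced.  Inter-block junctions are then
refined to base precision by exhaustive breakpoint placement scored with
edit distance (edlib), with ties resolved to the leftmost reference
position so that repeat-flanked deletions are reported reproducibly.

Segment reference coordinates are reported modulo L in [1, L]; the gap
between consecutive segments of one read is the deletion evidence consumed
by :mod:`mitolong.svcall`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import edlib
import numpy as np
import pandas as pd

from .refgenome import CircularReference, circular_gap
from .simulate import reverse_complement

__all__ = [
    "Anchor",
    "Segment",
    "ReadAlignment",
    "AlignParams",
    "ReferenceIndex",
    "index_reference",
    "chain_anchors",
    "refine_breakpoints",
    "align_read",
    "align_reads",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "write_sam",
]

logger = logging.getLogger(__name__)


class Anchor(NamedTuple):
    """Exact k-mer match: 1-based read position / doubled-reference position."""

    read_pos: int
    ref_pos: int
    k: int
    strand: str = "+"


@dataclass(frozen=True)
class Segment:
    """One gap-free (up to small indels) aligned block of a read.

    Coordinates are 1-based inclusive; ``ref_start``/``ref_end`` are modulo
    L, so a segment crossing the origin has ``ref_end < ref_start``.
    """

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    edit_distance: int


@dataclass
class ReadAlignment:
    read_id: str
    strand: str
    segments: list[Segment]
    ref_gaps: list[tuple[int, int]]  # deletion intervals (start, end), right-open
    mapped: bool
    read_length: int
    score: float = 0.0

    @property
    def total_edit_distance(self) -> int:
        return sum(s.edit_distance for s in self.segments)

    def aligned_read_bases(self) -> int:
        return sum(s.read_end - s.read_start + 1 for s in self.segments)


@dataclass
class AlignParams:
    """Tunables for anchoring/chaining, sized for a ~16.6-kb circular
    reference and ~5%-error reads; all exposed to the CLI."""

    k: int = 15
    max_occ: int = 20
    min_cov_frac: float = 0.4
    window: int = 200
    gap_open_scale: float = 4.0
    min_seg_gap: int = 30
    refine_slack: int = 12
    max_anchors: int = 260
    max_ref_gap: int | None = None  # defaults to L - 1


class ReferenceIndex:
    """k-mer index over the doubled reference sequence."""

    def __init__(self, ref: CircularReference, k: int = 15, max_occ: int = 20):
        if not 8 <= k <= 31:
            raise ValueError("k must be in [8, 31]")
        self.ref = ref
        self.k = k
        self.L = ref.length
        self.doubled = ref.sequence + ref.sequence
        index: dict[str, list[int]] = {}
        for p in range(1, self.L + 1):
            kmer = self.doubled[p - 1 : p - 1 + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(p)
        self.index = {km: pos for km, pos in index.items() if len(pos) <= max_occ}

    def lookup(self, kmer: str) -> list[int]:
        """Doubled-sequence hit positions (both copies) for an exact k-mer."""
        circ = self.index.get(kmer)
        if not circ:
            return []
        return [p for q in circ for p in (q, q + self.L)]


def index_reference(ref: CircularReference, k: int = 15, max_occ: int = 20) -> ReferenceIndex:
    return ReferenceIndex(ref, k=k, max_occ=max_occ)


def collect_anchors(
    read: str, index: ReferenceIndex, strand: str, max_anchors: int = 260
) -> list[Anchor]:
    """Sample k-mers along the read (adaptive stride) and look them up."""
    k = index.k
    n_pos = len(read) - k + 1
    if n_pos <= 0:
        return []
    stride = max(1, n_pos // max_anchors)
    anchors = []
    for i in range(0, n_pos, stride):
        for p in index.lookup(read[i : i + k]):
            anchors.append(Anchor(i + 1, p, k, strand))
    anchors.sort(key=lambda a: (a.read_pos, a.ref_pos))
    return anchors


def chain_anchors(
    anchors: Sequence[Anchor],
    max_ref_gap: int,
    gap_open_scale: float = 4.0,
) -> tuple[list[Anchor], float]:
    """Best co-linear anchor chain under a log-scaled reference-gap cost.

    Each anchor contributes ``min(k, Delta read)`` matched bases; a
    reference-vs-read gap of g between consecutive anchors costs
    ``gap_open_scale * log2(1 + g)``.  Returns ``(chain, score)``;
    ties break to the chain with the leftmost reference start.
    """
    if not anchors:
        return [], 0.0
    k = anchors[0].k
    rp = np.array([a.read_pos for a in anchors], dtype=np.int64)
    fp = np.array([a.ref_pos for a in anchors], dtype=np.int64)
    n = len(anchors)
    score = np.full(n, float(k))
    parent = np.full(n, -1, dtype=np.int64)
    root_fp = fp.copy()  # ref start of each chain for tie-breaking
    for j in range(1, n):
        dr = rp[j] - rp[:j]
        dg = fp[j] - fp[:j]
        ok = (dr > 0) & (dg > 0) & (dg <= max_ref_gap + dr)
        if not ok.any():
            continue
        gap = np.abs(dg - dr)
        cand = score[:j] + np.minimum(k, dr) - gap_open_scale * np.log2(1.0 + gap)
        cand[~ok] = -np.inf
        best = float(cand.max())
        if best > score[j]:
            ties = np.flatnonzero(cand == best)
            i = int(ties[np.argmin(root_fp[ties])])
            score[j] = best
            parent[j] = i
            root_fp[j] = root_fp[i]
    top = float(score.max())
    ends = np.flatnonzero(score == top)
    j = int(ends[np.argmin(root_fp[ends])])
    chain = []
    while j != -1:
        chain.append(anchors[j])
        j = int(parent[j])
    chain.reverse()
    return chain, top


def _edit_distance(query: str, target: str) -> int:
    if not query and not target:
        return 0
    if not query or not target:
        return max(len(query), len(target))
    return edlib.align(query, target, mode="NW", task="distance")["editDistance"]


def _segment_align(
    read_seg: str,
    doubled: str,
    f_a: int,
    f_b: int,
    pin_left: bool,
    pin_right: bool,
    window: int,
) -> tuple[int, int, int]:
    """Base-level placement of one segment: returns (ed, ref_start, ref_end)
    in doubled coordinates (1-based inclusive).  Unpinned ends are located
    by semi-global edit-distance alignment within ``window`` extra bases."""
    m = len(read_seg)
    pad = min(window, int(0.3 * m) + 15)
    if pin_left and pin_right:
        target = doubled[f_a - 1 : f_b]
        return _edit_distance(read_seg, target), f_a, f_b
    if pin_left:
        target = doubled[f_a - 1 : f_a - 1 + m + pad]
        res = edlib.align(read_seg, target, mode="SHW", task="locations")
        end = min(loc[1] for loc in res["locations"])
        return res["editDistance"], f_a, f_a + end
    if pin_right:
        lo = max(0, f_b - m - pad)
        target = doubled[lo:f_b][::-1]
        res = edlib.align(read_seg[::-1], target, mode="SHW", task="locations")
        end = min(loc[1] for loc in res["locations"])
        return res["editDistance"], f_b - end, f_b
    lo = max(0, f_a - 1 - pad)
    target = doubled[lo : f_b + pad]
    res = edlib.align(read_seg, target, mode="HW", task="locations")
    start, end = min(res["locations"], key=lambda t: t[0])
    return res["editDistance"], lo + start + 1, lo + end + 1


def _refine_junction(
    read: str,
    doubled: str,
    left: Anchor,
    right: Anchor,
    slack: int,
    window: int,
) -> tuple[int, int, int, int]:
    """Place one deletion breakpoint pair to base precision.

    ``left``/``right`` are the flanking chain anchors.  Candidate
    placements extend the left flank by ``x`` reference bases and the
    right flank by ``y``; the read bases between the anchors are scored
    by edit distance against the concatenated flanks.  Returns
    ``(del_start, del_end, x, read_split)`` in doubled coordinates, where
    ``read_split`` is the number of junction read bases assigned to the
    left flank.  Ties go to the leftmost deletion start.
    """
    rp_e = left.read_pos + left.k - 1  # last read base of left anchor
    fp_e = left.ref_pos + left.k - 1
    rp_s, fp_s = right.read_pos, right.ref_pos
    mid = read[rp_e : rp_s - 1]
    m = len(mid)
    G = fp_s - fp_e - 1  # reference bases between the anchors

    def candidates(x_values, d_values):
        best = None
        for x in x_values:
            left_flank = doubled[fp_e : fp_e + x]
            for d in d_values:
                y = m + d - x
                if y < 0 or x + y >= G:
                    continue
                target = left_flank + doubled[fp_s - 1 - y : fp_s - 1]
                ed = _edit_distance(mid, target)
                key = (ed, x, -y)
                if best is None or key < best[0]:
                    best = (key, x, y)
        return best

    s = min(slack, max(2, m))
    if m <= 60:
        best = candidates(range(0, m + s + 1), range(-s, s + 1))
    else:
        step = max(1, (m + s) // 60)
        coarse = candidates(range(0, m + s + 1, step), (-s, 0, s))
        x0 = coarse[1] if coarse else 0
        best = candidates(
            range(max(0, x0 - step), min(m + s, x0 + step) + 1), range(-s, s + 1)
        )
    if best is None:  # no room for a deletion: treat flanks as contiguous
        x, y = m, 0
    else:
        _, x, y = best

    # read split: how many of the mid bases belong to the left flank
    if x == 0:
        read_split = 0
    elif x >= m and y == 0:
        read_split = m
    else:
        res = edlib.align(
            mid, doubled[fp_e : fp_e + x] + doubled[fp_s - 1 - y : fp_s - 1],
            mode="NW", task="path",
        )
        read_split = _query_bases_for_target_prefix(res["cigar"], x)
    del_start = fp_e + x + 1
    del_end = fp_s - y
    return del_start, del_end, x, read_split


def _query_bases_for_target_prefix(cigar: str, target_bases: int) -> int:
    """Query bases consumed when the alignment has used ``target_bases``
    of the target (extended cigar with =, X, I, D)."""
    q = t = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            take = min(ln, target_bases - t)
            q += take
            t += take
            if t >= target_bases:
                return q
            q += ln - take
        elif ch == "I":
            q += ln
        elif ch == "D":
            take = min(ln, target_bases - t)
            t += take
            if t >= target_bases:
                return q
    return q


def refine_breakpoints(
    chain: Sequence[Anchor],
    read: str,
    ref: CircularReference,
    window: int = 200,
    params: AlignParams | None = None,
    read_id: str = "read",
    doubled: str | None = None,
) -> ReadAlignment:
    """Turn an anchor chain into base-precise segments and reference gaps."""
    params = params or AlignParams(window=window)
    if not chain:
        return ReadAlignment(read_id, "+", [], [], False, len(read))
    L = ref.length
    doubled = doubled or (ref.sequence + ref.sequence)
    min_gap = params.min_seg_gap

    # split the chain into co-linear blocks at large implied reference gaps
    blocks: list[list[Anchor]] = [[chain[0]]]
    for prev, cur in zip(chain, chain[1:]):
        dg = cur.ref_pos - prev.ref_pos
        dr = cur.read_pos - prev.read_pos
        if dg - dr > min_gap:
            blocks.append([cur])
        else:
            blocks[-1].append(cur)

    # refine each junction between consecutive blocks
    junctions = []  # (del_start, del_end, read_split_abs)
    for b1, b2 in zip(blocks, blocks[1:]):
        left, right = b1[-1], b2[0]
        ds, de, x, read_split = _refine_junction(
            read, doubled, left, right, params.refine_slack, window
        )
        junctions.append((ds, de, left.read_pos + left.k - 1 + read_split))

    segments: list[Segment] = []
    strand = chain[0].strand
    n_blocks = len(blocks)
    for i, block in enumerate(blocks):
        pin_left = i > 0
        pin_right = i < n_blocks - 1
        if pin_left:
            r_a = junctions[i - 1][2] + 1
            f_a = junctions[i - 1][1]
        else:
            r_a = 1
            f_a = max(1, block[0].ref_pos - (block[0].read_pos - 1))
        if pin_right:
            r_b = junctions[i][2]
            f_b = junctions[i][0] - 1
        else:
            r_b = len(read)
            f_b = block[-1].ref_pos + block[-1].k - 1 + (len(read) - (block[-1].read_pos + block[-1].k - 1))
        if r_b < r_a or f_b < f_a:
            continue
        ed, fs, fe = _segment_align(
            read[r_a - 1 : r_b], doubled, f_a, f_b, pin_left, pin_right, window
        )
        segments.append(
            Segment(
                read_start=r_a,
                read_end=r_b,
                ref_start=((fs - 1) % L) + 1,
                ref_end=((fe - 1) % L) + 1,
                edit_distance=int(ed),
            )
        )

    ref_gaps = []
    for (ds, de, _), _s in zip(junctions, range(len(junctions))):
        ref_gaps.append((((ds - 1) % L) + 1, ((de - 1) % L) + 1))

    return ReadAlignment(
        read_id=read_id,
        strand=strand,
        segments=segments,
        ref_gaps=ref_gaps,
        mapped=True,
        read_length=len(read),
    )


def _chain_coverage(chain: Sequence[Anchor]) -> int:
    """Read span of the chain (first anchor start to last anchor end).

    Error bases between anchors still belong to the aligned span, so the
    span — not the summed anchor lengths — is compared against
    ``min_cov_frac``; random (nuclear) reads only ever produce isolated
    anchors with span ~k.
    """
    if len(chain) < 3:  # require a minimum of corroborating anchors
        return 0
    return chain[-1].read_pos + chain[-1].k - chain[0].read_pos


def align_read(
    read_id: str,
    read: str,
    index: ReferenceIndex,
    params: AlignParams | None = None,
) -> ReadAlignment:
    """Best-strand circular alignment of one read.

    Returns ``mapped=False`` when no anchor chain covers at least
    ``min_cov_frac`` of the read (e.g. nuclear-background reads).
    Alignments spanning more than one full circle are rejected.
    """
    params = params or AlignParams()
    L = index.L
    max_ref_gap = params.max_ref_gap if params.max_ref_gap is not None else L - 1
    if len(read) < index.k:
        logger.warning("read %s shorter than k=%d: unmapped", read_id, index.k)
        return ReadAlignment(read_id, "+", [], [], False, len(read))

    best_chain: list[Anchor] = []
    best_score = -math.inf
    best_strand = "+"
    best_cov = 0
    for strand in "+-":
        oriented = read if strand == "+" else reverse_complement(read)
        anchors = collect_anchors(oriented, index, strand, params.max_anchors)
        chain, score = chain_anchors(anchors, max_ref_gap, params.gap_open_scale)
        cov = _chain_coverage(chain)
        if score > best_score:
            best_chain, best_score, best_strand, best_cov = chain, score, strand, cov
        if strand == "+" and cov >= 0.9 * len(read):
            break  # unambiguous forward alignment; skip the reverse strand

    if not best_chain or best_cov < params.min_cov_frac * len(read):
        return ReadAlignment(read_id, best_strand, [], [], False, len(read))
    span = best_chain[-1].ref_pos + best_chain[-1].k - best_chain[0].ref_pos
    if span > L:
        return ReadAlignment(read_id, best_strand, [], [], False, len(read))

    oriented = read if best_strand == "+" else reverse_complement(read)
    aln = refine_breakpoints(
        best_chain, oriented, index.ref, params.window, params, read_id, index.doubled
    )
    aln.strand = best_strand
    aln.score = best_score
    return aln


def align_reads(
    reads,
    index: ReferenceIndex,
    params: AlignParams | None = None,
) -> list[ReadAlignment]:
    """Align an iterable of ``(read_id, sequence)`` pairs (or SimReads)."""
    params = params or AlignParams()
    out = []
    for item in reads:
        if hasattr(item, "read_id"):
            rid, seq = item.read_id, item.sequence
        else:
            rid, seq = item
        out.append(align_read(rid, seq, index, params))
    return out


# ---------------------------------------------------------------------------
# exchange formats


def write_alignments_tsv(alignments: Sequence[ReadAlignment], path: str | Path) -> None:
    """Primary exchange format: one row per aligned segment."""
    rows = []
    for aln in alignments:
        if not aln.mapped:
            rows.append(
                dict(read_id=aln.read_id, strand=aln.strand, mapped=0,
                     read_length=aln.read_length, seg=0, read_start=0, read_end=0,
                     ref_start=0, ref_end=0, edit_distance=0)
            )
            continue
        for i, s in enumerate(aln.segments):
            rows.append(
                dict(read_id=aln.read_id, strand=aln.strand, mapped=1,
                     read_length=aln.read_length, seg=i,
                     read_start=s.read_start, read_end=s.read_end,
                     ref_start=s.ref_start, ref_end=s.ref_end,
                     edit_distance=s.edit_distance)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path, length: int) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rid, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("seg")
        first = grp.iloc[0]
        if first["mapped"] == 0:
            out.append(ReadAlignment(str(rid), str(first["strand"]), [], [], False,
                                     int(first["read_length"])))
            continue
        segs = [
            Segment(int(r.read_start), int(r.read_end), int(r.ref_start),
                    int(r.ref_end), int(r.edit_distance))
            for r in grp.itertuples()
        ]
        gaps = [
            (((segs[i].ref_end) % length) + 1, segs[i + 1].ref_start)
            for i in range(len(segs) - 1)
        ]
        out.append(ReadAlignment(str(rid), str(first["strand"]), segs, gaps, True,
                                 int(first["read_length"])))
    return out


def write_sam(
    alignments: Sequence[ReadAlignment],
    reads: dict[str, str],
    ref: CircularReference,
    path: str | Path,
) -> None:
    """Optional SAM export (N for intra-read reference gaps, NM tag).

    Alignments wrapping the reference origin cannot be expressed in linear
    SAM and are written as unmapped.  Per-segment CIGARs come from global
    edit-distance alignment of the segment pair.
    """
    import pysam

    from .refgenome import circular_slice

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": ref.name, "LN": ref.length}],
        }
    )
    L = ref.length
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(header)
            a.query_name = aln.read_id
            seq = reads.get(aln.read_id, "")
            oriented = seq if aln.strand == "+" else reverse_complement(seq)
            wraps = any(s.ref_end < s.ref_start for s in aln.segments)
            if not aln.mapped or not aln.segments or wraps:
                a.is_unmapped = True
                a.query_sequence = seq or None
                fh.write(a)
                continue
            a.is_reverse = aln.strand == "-"
            a.reference_id = 0
            a.reference_start = aln.segments[0].ref_start - 1
            cigar = []
            if aln.segments[0].read_start > 1:
                cigar.append((4, aln.segments[0].read_start - 1))
            nm = 0
            for i, s in enumerate(aln.segments):
                read_seg = oriented[s.read_start - 1 : s.read_end]
                ref_seg = circular_slice(ref.sequence, s.ref_start, s.ref_end + 1)
                res = edlib.align(read_seg, ref_seg, mode="NW", task="path")
                nm += res["editDistance"]
                cigar.extend(_edlib_cigar_tuples(res["cigar"]))
                if i < len(aln.segments) - 1:
                    gs, ge = aln.ref_gaps[i]
                    cigar.append((3, circular_gap(gs, ge, L)))
            if aln.segments[-1].read_end < aln.read_length:
                cigar.append((4, aln.read_length - aln.segments[-1].read_end))
            a.cigartuples = _merge_cigar(cigar)
            a.query_sequence = oriented
            a.set_tag("NM", nm)
            fh.write(a)


_EDLIB_OP = {"=": 7, "X": 8, "I": 1, "D": 2}


def _edlib_cigar_tuples(cigar: str) -> list[tuple[int, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((_EDLIB_OP[ch], int(num)))
            num = ""
    return out


def _merge_cigar(tuples: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for op, ln in tuples:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out
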