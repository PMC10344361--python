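"""Deletion calling from per-read reference gaps.

Reads spanning a deletion junction align as two blocks separated by a
multi-kilobase reference gap; each such gap is one deletion signal.
Signals are clustered by single linkage on circular breakpoint distance,
and clusters supported by fewer than ``min_support`` reads are discarded
(the Sniffles ``-s 2`` semantics).  Consensus breakpoints are per-cluster
medians with leftmost tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import ReadAlignment
from .refgenome import CircularReference, circular_distance, circular_gap

__all__ = [
    "DelSignal",
    "DeletionCall",
    "extract_del_signals",
    "cluster_signals",
    "write_vcf",
    "read_vcf",
]


@dataclass(frozen=True)
class DelSignal:
    """One spanning-read deletion observation (bases start..end-1 deleted)."""

    read_id: str
    start: int
    end: int


@dataclass
class DeletionCall:
    start: int
    end: int
    size: int
    support: int
    member_reads: list[str] = field(default_factory=list)

    def wraps_origin(self) -> bool:
        return self.end <= self.start

    def contains(self, pos: int, length: int) -> bool:
        """Is 1-based ``pos`` among the deleted bases?"""
        return circular_gap(self.start, pos, length) < self.size


def extract_del_signals(
    alignments: Sequence[ReadAlignment],
    min_del_size: int,
    length: int,
) -> list[DelSignal]:
    """One signal per reference gap of size >= ``min_del_size``.

    Smaller gaps are nanopore indel noise and ignored; unmapped reads
    contribute nothing.
    """
    out = []
    for aln in alignments:
        if not aln.mapped:
            continue
        for gs, ge in aln.ref_gaps:
            if circular_gap(gs, ge, length) >= min_del_size:
                out.append(DelSignal(aln.read_id, gs, ge))
    return out


def _leftmost_median(values: np.ndarray) -> int:
    """Median with ties to the lower value (even counts take the lower mid)."""
    v = np.sort(values)
    return int(v[(len(v) - 1) // 2])


def cluster_signals(
    signals: Sequence[DelSignal],
    tol: int,
    min_support: int,
    length: int,
) -> list[DeletionCall]:
    """Single-linkage clustering of deletion signals.

    Two signals link iff both breakpoint circular distances are <= ``tol``.
    Consensus breakpoints are leftmost medians (computed after unwrapping
    each cluster around its first member so clusters straddling the origin
    behave correctly); clusters below ``min_support`` are discarded, and
    calls are sorted by start.
    """
    n = len(signals)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                circular_distance(signals[i].start, signals[j].start, length) <= tol
                and circular_distance(signals[i].end, signals[j].end, length) <= tol
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[DelSignal]] = {}
    for i, sig in enumerate(signals):
        clusters.setdefault(find(i), []).append(sig)

    calls = []
    for members in clusters.values():
        if len(members) < min_support:
            continue
        ref_s, ref_e = members[0].start, members[0].end
        # unwrap each breakpoint to the representative +/- L/2
        starts = np.array(
            [ref_s + ((m.start - ref_s + length // 2) % length) - length // 2 for m in members]
        )
        ends = np.array(
            [ref_e + ((m.end - ref_e + length // 2) % length) - length // 2 for m in members]
        )
        start = ((_leftmost_median(starts) - 1) % length) + 1
        end = ((_leftmost_median(ends) - 1) % length) + 1
        calls.append(
            DeletionCall(
                start=start,
                end=end,
                size=circular_gap(start, end, length),
                support=len(members),
                member_reads=sorted(m.read_id for m in members),
            )
        )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mitolong
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="1-based position of the last anchor base before the right breakpoint">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles (negative for deletions)">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of reads supporting the deletion">
##ALT=<ID=DEL,Description="Deletion">
##comment=Deletions wrapping the circular origin are split into two records sharing an ID with suffixes _a/_b
##contig=<ID={name},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    calls: Sequence[DeletionCall], ref: CircularReference, path: str | Path
) -> None:
    """VCF 4.2 with symbolic <DEL> records; POS is the anchor base start-1.

    A deletion wrapping the origin cannot be expressed as one linear VCF
    record, so it is emitted as two records (``start..L`` and ``1..end-1``)
    sharing an ID with ``_a``/``_b`` suffixes.
    """
    L = ref.length
    lines = [_VCF_HEADER.format(name=ref.name, length=L)]
    for i, call in enumerate(calls):
        if not (1 <= call.start <= L and 1 <= call.end <= L):
            raise ValueError(f"call coordinates outside [1, {L}]: {call}")
        if not call.wraps_origin():
            lines.append(
                _vcf_record(ref, f"DEL{i + 1}", call.start, call.end, call.size, call)
            )
        else:
            # each half carries the SVLEN of its own linear interval
            lines.append(
                _vcf_record(ref, f"DEL{i + 1}_a", call.start, L + 1,
                            L + 1 - call.start, call)
            )
            if call.end > 1:
                lines.append(
                    _vcf_record(ref, f"DEL{i + 1}_b", 1, call.end, call.end - 1, call)
                )
    Path(path).write_text("".join(lines))


def _vcf_record(
    ref: CircularReference,
    vid: str,
    start: int,
    end: int,
    size: int,
    call: DeletionCall,
) -> str:
    pos = start - 1 if start > 1 else 1  # anchor base before the deleted run
    refbase = ref.base(pos)
    info = f"SVTYPE=DEL;END={end - 1};SVLEN=-{size};SUPPORT={call.support}"
    return f"{ref.name}\t{pos}\t{vid}\t{refbase}\t<DEL>\t.\tPASS\t{info}\n"


def read_vcf(path: str | Path, length: int) -> list[DeletionCall]:
    """Read SVTYPE=DEL records back into calls (cyvcf2 parser).

    Also accepts deletion records from external SV callers; origin-split
    record pairs (``_a``/``_b`` ID suffixes) are rejoined.
    """
    import cyvcf2

    halves: dict[str, dict[str, tuple[int, int, int]]] = {}
    calls = []
    for rec in cyvcf2.VCF(str(path)):
        if str(rec.INFO.get("SVTYPE", "")) != "DEL":
            continue
        support = int(rec.INFO.get("SUPPORT", 0))
        end_info = rec.INFO.get("END")
        svlen = rec.INFO.get("SVLEN")
        vid = rec.ID or ""
        if end_info is not None:
            end = int(end_info) + 1
        elif svlen is not None:
            end = ((rec.POS + abs(int(svlen))) % length) + 1
        else:
            continue
        if vid.endswith(("_a", "_b")):
            halves.setdefault(vid[:-2], {})[vid[-1]] = (rec.POS + 1, end, support)
            continue
        if svlen is not None:
            size = abs(int(svlen))
            start = ((end - size - 1) % length) + 1
        else:
            start = rec.POS + 1
            size = circular_gap(start, end, length)
        calls.append(DeletionCall(start, end, size, support))
    for parts in halves.values():
        a = parts.get("a")
        b = parts.get("b")
        start = a[0] if a else 1
        end = b[1] if b else 1
        support = (a or b)[2]
        size = circular_gap(start, end, length)
        calls.append(DeletionCall(start, end, size, support))
    calls.sort(key=lambda c: (c.start, c.end))
    return calls
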