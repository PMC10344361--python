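"""Circular reference genome handling.

The human mitochondrial genome is a 16,569-bp circle (rCRS, NC_012920).
All coordinates in this package are 1-based positions in [1, L]; a deletion
``(start, end)`` removes bases ``start .. end-1`` (left-closed, right-open),
so its size is the circular forward distance from ``start`` to ``end``.
This module provides the circular-coordinate arithmetic, restriction-site
search and origin rotation used by every other stage.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularReference",
    "RestrictionEnzyme",
    "BAMHI",
    "PVUII",
    "circular_gap",
    "circular_distance",
    "circular_slice",
    "load_reference",
    "write_reference",
    "load_annotations_bed",
    "find_restriction_sites",
    "cut_positions",
    "rotate_origin",
    "longest_homopolymer",
    "random_reference",
    "fetch_rcrs",
]

_ALLOWED = set("ACGTN")

RCRS_LENGTH = 16_569
RCRS_EFETCH_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nucleotide&id=NC_012920.1&rettype=fasta&retmode=text"
)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease with its top-strand cut offset.

    ``cut_offset`` is the number of bases from the recognition start to the
    cut point, so the first base of the downstream fragment sits at
    ``recognition_start + cut_offset`` (1-based, modulo L).  BamHI cuts
    G^GATCC (offset 1); PvuII cuts CAG^CTG (offset 3, blunt).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition sequence must be >= 4 bases")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")
        if set(self.recognition) - set("ACGT"):
            raise ValueError("recognition must be over {A,C,G,T}")


BAMHI = RestrictionEnzyme("BamHI", "GGATCC", 1)
PVUII = RestrictionEnzyme("PvuII", "CAGCTG", 3)


@dataclass
class CircularReference:
    """A single circular DNA sequence with optional interval annotations.

    ``annotations`` is a list of ``(label, start, end)`` with 1-based
    inclusive coordinates (an annotation may wrap the origin, start > end).
    """

    name: str
    sequence: str
    annotations: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("empty reference sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(f"invalid bases in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based circular position ``pos``."""
        return self.sequence[(pos - 1) % self.length]


def circular_gap(a: int, b: int, length: int) -> int:
    """Forward-strand distance from position ``a`` to ``b`` modulo ``length``.

    Result is in ``[0, length)``; this is the size of a deletion whose
    breakpoints are ``(a, b)``.
    """
    return (b - a) % length


def circular_distance(a: int, b: int, length: int) -> int:
    """Smaller of the two arc distances between positions ``a`` and ``b``."""
    d = (b - a) % length
    return min(d, length - d)


def circular_slice(seq: str, start: int, end: int) -> str:
    """Bases ``start .. end-1`` (1-based, right-open) walking forward, circularly.

    ``start == end`` returns the empty string; a slice may wrap the origin.
    """
    n = len(seq)
    gap = (end - start) % n
    i = (start - 1) % n
    if i + gap <= n:
        return seq[i : i + gap]
    return seq[i:] + seq[: i + gap - n]


def load_reference(fasta_path: str | Path) -> CircularReference:
    """Load a single-record FASTA as a circular reference.

    The sequence is uppercased; ``N`` is allowed, RNA ``U`` is rejected.
    A multi-record file is an error ("expected single circular sequence").
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected single circular sequence, found {len(records)} records"
        )
    rec = records[0]
    return CircularReference(name=rec.id, sequence=str(rec.seq))


def write_reference(ref: CircularReference, fasta_path: str | Path) -> None:
    """Write the reference as single-record FASTA, wrapped at 60 columns."""
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def load_annotations_bed(bed_path: str | Path, length: int) -> list[tuple[str, int, int]]:
    """Read a BED file (0-based, half-open) into 1-based inclusive intervals.

    Only the first four columns are used; the name column defaults to the
    interval coordinates when absent.
    """
    out: list[tuple[str, int, int]] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start0, end0 = int(parts[1]), int(parts[2])
            if not (0 <= start0 < end0 <= length):
                raise ValueError(f"BED interval out of range: {line!r}")
            label = parts[3] if len(parts) > 3 else f"{start0 + 1}-{end0}"
            out.append((label, start0 + 1, end0))
    return out


def find_restriction_sites(
    ref: CircularReference, enzyme: RestrictionEnzyme
) -> list[int]:
    """1-based recognition-start positions of ``enzyme`` on the circle.

    The search is top-strand only (BamHI and PvuII recognitions are
    palindromic, so nothing is lost); matches wrapping the origin are
    included; ``N`` never matches.
    """
    L = ref.length
    k = len(enzyme.recognition)
    doubled = ref.sequence + ref.sequence[: min(k - 1, L)]
    sites = []
    start = 0
    while True:
        i = doubled.find(enzyme.recognition, start)
        if i == -1 or i >= L:
            break
        sites.append(i + 1)
        start = i + 1
    return sites


def cut_positions(ref: CircularReference, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based positions of the first base downstream of each cut."""
    L = ref.length
    return sorted(
        ((s - 1 + enzyme.cut_offset) % L) + 1 for s in find_restriction_sites(ref, enzyme)
    )


def rotate_origin(ref: CircularReference, new_origin: int) -> CircularReference:
    """Return the reference rotated so ``new_origin`` becomes position 1.

    Annotations are remapped modulo L.  Old position ``p`` maps to
    ``((p - new_origin) mod L) + 1``.
    """
    L = ref.length
    if not 1 <= new_origin <= L:
        raise ValueError(f"new_origin {new_origin} outside [1, {L}]")
    seq = ref.sequence[new_origin - 1 :] + ref.sequence[: new_origin - 1]

    def remap(p: int) -> int:
        return ((p - new_origin) % L) + 1

    ann = [(label, remap(s), remap(e)) for label, s, e in ref.annotations]
    return CircularReference(name=ref.name, sequence=seq, annotations=ann)


def remap_position(p: int, new_origin: int, length: int) -> int:
    """Map a position on the original circle onto the rotated one."""
    return ((p - new_origin) % length) + 1


def longest_homopolymer(sequence: str) -> tuple[str, int, int]:
    """Longest homopolymer run: ``(base, start, run_length)``, 1-based start.

    Runs are scanned linearly (the run wrapping the origin is not joined);
    ties resolve to the leftmost run.
    """
    best_base, best_start, best_len = sequence[0], 1, 1
    cur_start, cur_len = 1, 1
    for i in range(1, len(sequence)):
        if sequence[i] == sequence[i - 1]:
            cur_len += 1
        else:
            cur_start, cur_len = i + 1, 1
        if cur_len > best_len:
            best_base, best_start, best_len = sequence[i], cur_start, cur_len
    return best_base, best_start, best_len


def random_reference(
    length: int, seed: int, name: str = "synthetic_circular", gc: float = 0.44
) -> CircularReference:
    """Generate an i.i.d. random circular reference (synthetic stand-in).

    GC fraction defaults to 0.44, the approximate GC content of human
    mtDNA.  Used throughout the tests in place of the real rCRS.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    return CircularReference(name=name, sequence="".join(bases))


def fetch_rcrs(dest: str | Path, timeout: float = 30.0) -> CircularReference:
    """Download the rCRS (NC_012920.1) from NCBI efetch and cache it.

    Returns the cached copy without touching the network when ``dest``
    already exists.  Requires internet access otherwise.
    """
    dest = Path(dest)
    if not dest.exists():
        with urllib.request.urlopen(RCRS_EFETCH_URL, timeout=timeout) as resp:
            data = resp.read().decode()
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.write_text(data)
    return load_reference(dest)
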