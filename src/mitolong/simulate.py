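"""Nanopore-like read simulation from heteroplasmic circular molecule mixtures.

A sample is modelled as a population of circular mtDNA species (wild type
plus molecules carrying one or more large deletions) mixed at fixed
fractions.  Molecules are linearized either at restriction-enzyme sites
(Ligation-kit chemistry: BamHI / PvuII digestion) or by random transposase
fragmentation (Rapid-kit chemistry), then read out with an indel-dominated
error model at a ~4-6% total error rate.  Every read carries ground truth
(source species, reference coordinates, deletion junctions spanned) so that
downstream alignment and calling can be scored exactly.

The key protocol bias reproduced here: when the single linearization site
falls *inside* a deletion, the deleted molecules have no cut site left and
mostly stay circular; uncut circles sequence poorly (probability ``p_uncut``
of being read at all), so the deleted species is under-sampled and its
heteroplasmy underestimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refgenome import (
    BAMHI,
    CircularReference,
    RestrictionEnzyme,
    circular_gap,
    find_restriction_sites,
)

__all__ = [
    "Deletion",
    "Species",
    "MoleculePopulation",
    "ErrorModel",
    "ERROR_FREE",
    "LogNormalLengths",
    "ConstantLength",
    "SimConfig",
    "SimRead",
    "SimResult",
    "realize_molecule",
    "fragment_endonuclease",
    "fragment_transposase",
    "apply_error_model",
    "simulate_run",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Deletion:
    """Deleted bases ``start .. end-1`` (1-based, may wrap the origin)."""

    start: int
    end: int

    def size(self, length: int) -> int:
        return circular_gap(self.start, self.end, length)

    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def contains(self, pos: int, length: int) -> bool:
        """Is 1-based position ``pos`` among the deleted bases?"""
        return circular_gap(self.start, pos, length) < self.size(length)


@dataclass(frozen=True)
class Species:
    """One molecular species: a set of non-overlapping deletions + fraction."""

    deletions: tuple[Deletion, ...]
    fraction: float
    name: str = ""

    def display_name(self) -> str:
        if self.name:
            return self.name
        if not self.deletions:
            return "WT"
        return "del:" + ",".join(d.label() for d in self.deletions)


@dataclass
class MoleculePopulation:
    ref: CircularReference
    species: list[Species]

    def __post_init__(self) -> None:
        fracs = [s.fraction for s in self.species]
        if any(f <= 0 for f in fracs):
            raise ValueError("species fractions must be > 0")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(f"species fractions must sum to 1, got {sum(fracs)}")
        L = self.ref.length
        for sp in self.species:
            for d in sp.deletions:
                if d.start == d.end or not (1 <= d.start <= L and 1 <= d.end <= L):
                    raise ValueError(f"invalid deletion {d}")
        # non-overlap within a species is validated when the molecule is realized

    @classmethod
    def two_species(
        cls, ref: CircularReference, deletion: Deletion, fraction_deleted: float
    ) -> "MoleculePopulation":
        """Wild type + one deleted species at the given heteroplasmy."""
        return cls(
            ref,
            [
                Species((), 1.0 - fraction_deleted),
                Species((deletion,), fraction_deleted),
            ],
        )


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution / insertion / deletion probabilities.

    Defaults (sub 0.02, ins 0.015, del 0.025, total 6%) reflect the
    indel-dominated error profile of R9.4.1 nanopore reads; deletion
    probability is multiplied by ``homopolymer_multiplier`` inside
    homopolymer runs of length >= 4.  ``quality_char`` is the constant
    FASTQ quality ('-' = Q12).
    """

    sub_rate: float = 0.02
    ins_rate: float = 0.015
    del_rate: float = 0.025
    homopolymer_multiplier: float = 2.0
    quality_char: str = "-"

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 0.5:
                raise ValueError("error rates must be in [0, 0.5)")


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class LogNormalLengths:
    """Log-normal fragment-length law parameterized on the natural-log scale."""

    mu: float
    sigma: float

    @classmethod
    def from_mean(cls, mean: float, sigma: float = 0.6) -> "LogNormalLengths":
        """Law with the given arithmetic mean: mu = ln(mean) - sigma^2/2."""
        return cls(math.log(mean) - sigma**2 / 2.0, sigma)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.maximum(1, rng.lognormal(self.mu, self.sigma, size).astype(np.int64))


@dataclass(frozen=True)
class ConstantLength:
    """Degenerate length law (every fragment the same length)."""

    value: int

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, max(1, int(self.value)), dtype=np.int64)


@dataclass
class SimConfig:
    """Study conditions for one simulated sequencing run.

    ``mode`` selects Ligation-kit endonuclease linearization
    ("endonuclease") or Rapid-kit transposase fragmentation
    ("transposase").  ``fragment_mean`` (transposase) defaults to 4,403
    bases, the Rapid-kit average mtDNA read length; ``breakage_rate``
    (endonuclease) adds random degradation nicks so Ligation-kit reads
    average ~6 kb rather than full-circle length.  ``p_uncut`` is the
    probability that a molecule left circular (no remaining cut site)
    is nevertheless sequenced.
    """

    population: MoleculePopulation
    mode: str = "transposase"
    enzyme: RestrictionEnzyme = BAMHI
    p_uncut: float = 0.1
    fragment_mean: float = 4403.0
    fragment_sigma: float = 0.6
    breakage_rate: float = 1.5e-4
    target_depth: float = 100.0
    nuclear_fraction: float = 0.0
    min_read_length: int = 200
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("endonuclease", "transposase"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if not 0 <= self.p_uncut <= 1:
            raise ValueError("p_uncut must be in [0, 1]")
        if not 0 <= self.nuclear_fraction < 1:
            raise ValueError("nuclear_fraction must be in [0, 1)")

    @property
    def fragment_law(self) -> LogNormalLengths:
        return LogNormalLengths.from_mean(self.fragment_mean, self.fragment_sigma)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    species: str
    ref_start: int
    ref_end: int
    strand: str
    junctions: str  # comma-joined "start-end" labels, "." when none
    is_nuclear: bool


@dataclass
class SimResult:
    reads: list[SimRead]
    config: SimConfig

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "species": r.species,
                    "ref_start": r.ref_start,
                    "ref_end": r.ref_end,
                    "strand": r.strand,
                    "junctions": r.junctions,
                    "is_nuclear": int(r.is_nuclear),
                }
                for r in self.reads
            ]
        )

    def write_fastq(self, path: str | Path) -> None:
        q = self.config.error_model.quality_char
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q * len(r.sequence)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth_table().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# molecule realization


def _molecule_map(ref: CircularReference, deletions: Sequence[Deletion]) -> np.ndarray:
    """1-based reference positions of the kept bases, in reference order.

    Raises on overlapping deletions (a base deleted twice).
    """
    L = ref.length
    keep = np.ones(L, dtype=bool)
    removed = 0
    for d in deletions:
        size = d.size(L)
        idx = (np.arange(size) + d.start - 1) % L
        keep[idx] = False
        removed += size
    if removed != int((~keep).sum()):
        raise ValueError("overlapping deletions")
    if keep.sum() == 0:
        raise ValueError("deletions remove the whole molecule")
    return np.flatnonzero(keep) + 1


def realize_molecule(ref: CircularReference, deletions: Sequence[Deletion]) -> str:
    """Circular molecule sequence with the deleted intervals excised."""
    refmap = _molecule_map(ref, deletions)
    seq = ref.sequence
    return "".join(seq[p - 1] for p in refmap)


def _junction_boundaries(refmap: np.ndarray, length: int) -> list[tuple[int, str]]:
    """Molecule indices (0-based) after which a deletion junction sits.

    Returns ``(index, "start-end")`` pairs: the reference jump between
    molecule base ``index`` and ``index+1`` (mod molecule length).
    """
    n = len(refmap)
    out = []
    for j in range(n):
        a = refmap[j]
        b = refmap[(j + 1) % n]
        gap = (b - a) % length
        if gap != 1:
            out.append((j, f"{(a % length) + 1}-{b}"))
    return out


# ---------------------------------------------------------------------------
# fragmentation

Fragment = tuple[int, int]  # (0-based start on the molecule, length)


def _molecule_length(molecule: str | int) -> int:
    return molecule if isinstance(molecule, int) else len(molecule)


def fragment_endonuclease(
    molecule: str | int,
    cut_sites: Sequence[int],
    p_uncut: float,
    breakage_rate: float,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Cut a circular molecule at every restriction site, then nick randomly.

    ``cut_sites`` are 1-based molecule positions of the first base
    downstream of each cut.  A molecule with no remaining site is
    sequenced only with probability ``p_uncut`` (linearized at a uniform
    random phase) — the source of the linearization bias.  Each resulting
    linear fragment then suffers independent random breaks at
    ``breakage_rate`` per internal bond.  Fragments are ``(start, length)``
    pairs in 0-based molecule coordinates.
    """
    n = _molecule_length(molecule)
    sites = sorted({((s - 1) % n) for s in cut_sites})
    if sites:
        frags = []
        for i, s in enumerate(sites):
            nxt = sites[(i + 1) % len(sites)]
            frags.append((s, (nxt - s) % n or n))
    else:
        if rng.random() >= p_uncut:
            return []
        frags = [(int(rng.integers(n)), n)]
    if breakage_rate > 0:
        frags = _random_breaks(frags, breakage_rate, rng)
    return frags


def _random_breaks(
    frags: list[Fragment], rate: float, rng: np.random.Generator
) -> list[Fragment]:
    out: list[Fragment] = []
    for start, length in frags:
        if length < 2:
            out.append((start, length))
            continue
        breaks = np.flatnonzero(rng.random(length - 1) < rate) + 1
        prev = 0
        for b in breaks:
            out.append((start + prev, int(b - prev)))
            prev = int(b)
        out.append((start + prev, length - prev))
    return out


def fragment_transposase(
    molecule: str | int,
    length_law,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Random tagmentation: cut the circle at a uniform phase, then chop.

    Consecutive fragment lengths are drawn from ``length_law`` (the last
    fragment is truncated), so the fragments always partition the circle.
    """
    n = _molecule_length(molecule)
    phase = int(rng.integers(n))
    frags: list[Fragment] = []
    covered = 0
    while covered < n:
        ln = int(length_law.sample(rng, 1)[0])
        ln = min(ln, n - covered)
        frags.append(((phase + covered) % n, ln))
        covered += ln
    return frags


# ---------------------------------------------------------------------------
# error model

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE_FULL = np.full(256, ord("N"), dtype=np.uint8)
_DECODE_FULL[:4] = _DECODE


def _homopolymer_mask(codes: np.ndarray, min_run: int = 4) -> np.ndarray:
    if len(codes) < min_run:
        return np.zeros(len(codes), dtype=bool)
    change = np.concatenate([[True], codes[1:] != codes[:-1]])
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def apply_error_model(
    fragment: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, str]:
    """Corrupt a fragment and pick a strand; returns ``(read, strand)``.

    Per base, mutually exclusively: substitute (uniform over the three
    alternatives), delete, or insert a uniform random base before it.
    Deletion probability is scaled by the homopolymer multiplier inside
    runs >= 4.  The read is reverse-complemented with probability 0.5.
    """
    if not fragment:
        raise ValueError("empty fragment")
    arr = np.frombuffer(fragment.encode(), dtype=np.uint8)
    codes = _CODE[arr]
    n = len(arr)

    del_p = np.full(n, model.del_rate)
    if model.homopolymer_multiplier != 1.0 and model.del_rate > 0:
        mask = _homopolymer_mask(codes)
        del_p[mask] = np.minimum(0.95, model.del_rate * model.homopolymer_multiplier)

    u = rng.random(n)
    sub = u < model.sub_rate
    dele = (~sub) & (u < model.sub_rate + del_p)
    ins = (~sub) & (~dele) & (u < model.sub_rate + del_p + model.ins_rate)

    out = codes.copy()
    n_sub = int(sub.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        valid = codes[sub] < 4
        out[sub] = np.where(valid, (codes[sub] + shift) % 4, rng.integers(0, 4, n_sub))

    keep = ~dele
    filtered = out[keep]
    n_ins = int(ins.sum())
    if n_ins:
        ins_bases = rng.integers(0, 4, size=n_ins).astype(np.uint8)
        kept_before = np.concatenate([[0], np.cumsum(keep)[:-1]])
        filtered = np.insert(filtered, kept_before[ins], ins_bases)

    read = _DECODE_FULL[filtered].tobytes().decode()
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        read = reverse_complement(read)
    return read, strand


# ---------------------------------------------------------------------------
# full run


def _circular_find_sites(molecule: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut positions (1-based) of ``enzyme`` on a realized circular molecule."""
    tmp = CircularReference(name="mol", sequence=molecule)
    n = len(molecule)
    return [((s - 1 + enzyme.cut_offset) % n) + 1 for s in find_restriction_sites(tmp, enzyme)]


def simulate_run(
    config: SimConfig,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> SimResult:
    """Simulate one sequencing run; optionally write FASTQ + truth TSV.

    Molecules are drawn by species fraction until the emitted
    mitochondrial bases reach ``target_depth x L``; ``nuclear_fraction``
    of the final reads are i.i.d.-random background sequence flagged as
    nuclear in the truth table.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    pop = config.population
    ref = pop.ref
    L = ref.length

    realized = []
    for sp in pop.species:
        refmap = _molecule_map(ref, sp.deletions)
        seq = "".join(ref.sequence[p - 1] for p in refmap)
        junctions = _junction_boundaries(refmap, L)
        cuts = (
            _circular_find_sites(seq, config.enzyme)
            if config.mode == "endonuclease"
            else []
        )
        realized.append((sp, seq, refmap, junctions, cuts))

    fractions = np.array([sp.fraction for sp in pop.species])
    target_bases = config.target_depth * L
    reads: list[SimRead] = []
    emitted = 0
    counter = 0
    while emitted < target_bases:
        si = int(rng.choice(len(fractions), p=fractions))
        sp, mol, refmap, junctions, cuts = realized[si]
        n = len(mol)
        if config.mode == "endonuclease":
            frags = fragment_endonuclease(
                n, cuts, config.p_uncut, config.breakage_rate, rng
            )
        else:
            frags = fragment_transposase(n, config.fragment_law, rng)
        for start, length in frags:
            start %= n
            if length < config.min_read_length:
                continue
            frag_seq = mol[start : start + length]
            if len(frag_seq) < length:  # wraps the molecule origin
                frag_seq += mol[: length - len(frag_seq)]
            read, strand = apply_error_model(frag_seq, config.error_model, rng)
            spanned = [
                lab
                for j, lab in junctions
                if (j - start) % n < length - 1
            ]
            reads.append(
                SimRead(
                    read_id=f"mt{counter:06d}",
                    sequence=read,
                    species=sp.display_name(),
                    ref_start=int(refmap[start]),
                    ref_end=int(refmap[(start + length - 1) % n]),
                    strand=strand,
                    junctions=",".join(spanned) if spanned else ".",
                    is_nuclear=False,
                )
            )
            counter += 1
            emitted += length

    if config.nuclear_fraction > 0:
        n_mt = len(reads)
        n_nuc = int(round(config.nuclear_fraction / (1 - config.nuclear_fraction) * n_mt))
        lengths = config.fragment_law.sample(rng, n_nuc)
        for i in range(n_nuc):
            ln = max(int(lengths[i]), config.min_read_length)
            seq = _DECODE[rng.integers(0, 4, ln)].tobytes().decode()
            reads.append(
                SimRead(
                    read_id=f"nuc{i:06d}",
                    sequence=seq,
                    species="nuclear",
                    ref_start=0,
                    ref_end=0,
                    strand="+",
                    junctions=".",
                    is_nuclear=True,
                )
            )

    result = SimResult(reads=reads, config=config)
    if fastq_path is not None:
        result.write_fastq(fastq_path)
    if truth_path is not None:
        result.write_truth(truth_path)
    return result
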