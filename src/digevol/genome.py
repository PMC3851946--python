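"""Circular double-stranded binary chromosome.

The chromosome is a circular string of binary nucleotides where 0 is
complementary to 1.  Only one strand (the "leading" strand, read 5'->3')
is stored; reading the lagging strand yields the complement of the stored
symbols in reverse order.  All position arithmetic is modulo the genome
length L; the origin (stored index 0) is a bookkeeping anchor with no
biological meaning.

Coordinate conventions
----------------------
* Positions are 0-based.
* A segment ``{p1, ..., p2}`` is the inclusive run of positions walked
  clockwise (increasing stored index, mod L) from ``p1`` to ``p2``; when
  ``p1 > p2`` the segment wraps through the origin.
* Lagging-strand coordinates are strand-local: position ``p`` on the
  lagging strand corresponds to stored index ``L - 1 - p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "Strand",
    "Genome",
    "complement",
    "read_window",
    "splice",
    "Insert",
    "Delete",
    "Replace",
    "segment_indices",
    "random_genome",
    "read_genome_file",
    "write_genome_file",
]


class Strand(Enum):
    """The two strands of the circular chromosome."""

    LEADING = 0
    LAGGING = 1


def complement(symbol: int) -> int:
    """Complement of a binary nucleotide (0 <-> 1)."""
    if symbol not in (0, 1):
        raise ValueError(f"nucleotide must be 0 or 1, got {symbol!r}")
    return 1 - symbol


class Genome:
    """Immutable circular binary genome (stored leading strand).

    Parameters
    ----------
    bits:
        Sequence of 0/1 symbols (string, iterable of ints, or uint8 array)
        giving the stored strand read 5'->3'.  Must contain at least one
        symbol.
    """

    __slots__ = ("bits",)

    @classmethod
    def _trusted(cls, arr: np.ndarray) -> "Genome":
        """Internal fast path: wrap an already-validated uint8 0/1 array."""
        g = object.__new__(cls)
        arr = np.ascontiguousarray(arr, dtype=np.uint8)
        arr.setflags(write=False)
        g.bits = arr
        return g

    def __init__(self, bits: Union[str, Sequence[int], np.ndarray]):
        if isinstance(bits, str):
            arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
        else:
            arr = np.asarray(bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("genome must hold at least one nucleotide")
        if arr.size and not np.all((arr == 0) | (arr == 1)):
            raise ValueError("genome symbols must all be 0 or 1")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        self.bits = arr

    # -- basic protocol -------------------------------------------------

    def __len__(self) -> int:
        return int(self.bits.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.bits.shape == other.bits.shape and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())

    def __repr__(self) -> str:
        s = self.to_string()
        if len(s) > 40:
            s = s[:37] + "..."
        return f"Genome({s!r}, L={len(self)})"

    def to_string(self) -> str:
        return "".join("01"[b] for b in self.bits.tolist())

    # -- strand access ---------------------------------------------------

    def strand_sequence(self, strand: Strand) -> np.ndarray:
        """Full 5'->3' sequence of one strand as a uint8 array.

        The lagging strand is the reverse complement of the stored strand.
        """
        if strand is Strand.LEADING:
            return self.bits
        return (1 - self.bits[::-1]).astype(np.uint8)

    def reverse_complement(self) -> "Genome":
        """Genome re-stored with the lagging strand as the leading one."""
        return Genome(self.strand_sequence(Strand.LAGGING))

    def rotated(self, r: int) -> "Genome":
        """Genome with the stored origin moved by ``r`` positions.

        Stored index ``i`` of the result equals stored index ``(i + r) % L``
        of the original; a pure bookkeeping change on a circular molecule.
        """
        r %= len(self)
        return Genome(np.roll(self.bits, -r))


def read_window(genome: Genome, strand: Strand, start: int, length: int) -> str:
    """Read ``length`` symbols 5'->3' on ``strand`` from strand-local ``start``.

    Wraps circularly; repeated wrapping is permitted when
    ``length > len(genome)``.
    """
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    L = len(genome)
    if not 0 <= start < L:
        raise ValueError(f"start must be in [0, {L}), got {start}")
    seq = genome.strand_sequence(strand)
    idx = (start + np.arange(length)) % L
    return "".join("01"[b] for b in seq[idx].tolist())


def segment_indices(p1: int, p2: int, L: int) -> np.ndarray:
    """Stored indices of the clockwise-inclusive segment {p1, ..., p2}."""
    seg_len = (p2 - p1) % L + 1
    return (p1 + np.arange(seg_len)) % L


# -- segment edits -------------------------------------------------------


@dataclass(frozen=True)
class Insert:
    """Insert ``seq`` before position ``at``."""

    at: int
    seq: Union[str, Sequence[int]]


@dataclass(frozen=True)
class Delete:
    """Delete the clockwise-inclusive segment {p1, ..., p2}."""

    p1: int
    p2: int


@dataclass(frozen=True)
class Replace:
    """Replace the clockwise-inclusive segment {p1, ..., p2} by ``seq``."""

    p1: int
    p2: int
    seq: Union[str, Sequence[int]]


Edit = Union[Insert, Delete, Replace]


def _as_bits(seq) -> np.ndarray:
    if isinstance(seq, str):
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8) - ord("0")
    return np.asarray(seq, dtype=np.uint8)


class RejectedEditError(ValueError):
    """An edit would empty the genome."""


def splice(genome: Genome, edits: Iterable[Edit]) -> Genome:
    """Apply an ordered list of segment edits, returning a new genome.

    Each edit sees the genome state left by the previous one.  An edit that
    would leave the genome empty raises :class:`RejectedEditError`.
    """
    bits = genome.bits
    for edit in edits:
        L = bits.size
        if isinstance(edit, Insert):
            bits = np.insert(bits, edit.at % L if L else 0, _as_bits(edit.seq))
        elif isinstance(edit, Delete):
            idx = segment_indices(edit.p1, edit.p2, L)
            if idx.size >= L:
                raise RejectedEditError("deletion would empty the genome")
            bits = np.delete(bits, idx)
        elif isinstance(edit, Replace):
            idx = segment_indices(edit.p1, edit.p2, L)
            repl = _as_bits(edit.seq)
            if idx.size >= L and repl.size == 0:
                raise RejectedEditError("replacement would empty the genome")
            remainder = np.delete(bits, idx)
            at = min(edit.p1 % L, remainder.size)
            bits = np.insert(remainder, at, repl)
        else:  # pragma: no cover - guarded by type hints
            raise TypeError(f"unknown edit {edit!r}")
    return Genome(bits)


def random_genome(length: int, rng: np.random.Generator) -> Genome:
    """Uniform random genome of the given length."""
    return Genome(rng.integers(0, 2, size=length, dtype=np.uint8))


# -- plain-text persistence ----------------------------------------------


def write_genome_file(genome: Genome, path, header: str | None = None) -> None:
    """Dump a genome as text: one 0/1 line, optionally FASTA-style header."""
    with open(path, "w") as fh:
        if header is not None:
            fh.write(f">{header}\n")
        fh.write(genome.to_string() + "\n")


def read_genome_file(path) -> Genome:
    """Read a genome written by :func:`write_genome_file`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    seq = "".join(ln for ln in lines if not ln.startswith(">"))
    return Genome(seq)
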