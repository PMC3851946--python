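"""Replication with mutations and chromosomal rearrangements.

When a genome replicates, the numbers of events of each type are drawn
from binomial laws B(L, u_type).  The four rearrangements (large
deletion, duplication, inversion, translocation) are counted against the
parental length, shuffled, and applied first; the three local events
(point mutation, small insertion, small deletion) are then counted
against the post-rearrangement length, shuffled, and applied.  Breakpoints
are drawn against the genome length current at each application, so the
length can vary throughout the process.

Segments {p1, ..., p2} are clockwise-inclusive (wrapping through the
origin when p1 > p2).  Inversion is double-stranded: the segment is
replaced by its reverse complement, so inverted genes stay readable on the
opposite strand.  Events that would empty the genome are skipped and
recorded as such, not redrawn.

Every event records the positions and sequences it used, so a recorded
event log can be replayed exactly on the parental genome
(:func:`apply_event`), without any random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome import Genome

__all__ = [
    "EventType",
    "MutationRates",
    "MutationEvent",
    "draw_event_counts",
    "apply_point_mutation",
    "apply_small_indel",
    "apply_rearrangement",
    "apply_event",
    "mutate_genome",
    "REARRANGEMENT_TYPES",
    "LOCAL_TYPES",
]


class EventType(Enum):
    POINT = "point"
    SMALL_INS = "small_ins"
    SMALL_DEL = "small_del"
    LARGE_DEL = "large_del"
    DUPLICATION = "duplication"
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"


REARRANGEMENT_TYPES: Tuple[EventType, ...] = (
    EventType.LARGE_DEL, EventType.DUPLICATION,
    EventType.INVERSION, EventType.TRANSLOCATION,
)
LOCAL_TYPES: Tuple[EventType, ...] = (
    EventType.POINT, EventType.SMALL_INS, EventType.SMALL_DEL,
)


@dataclass(frozen=True)
class MutationRates:
    """Per-base-pair, per-replication event rates.

    Local events default to 5e-6/bp, rearrangements to 5e-5/bp; small
    indel lengths are uniform on {1, ..., indel_len_max}.
    """

    point: float = 5e-6
    small_ins: float = 5e-6
    small_del: float = 5e-6
    large_del: float = 5e-5
    duplication: float = 5e-5
    inversion: float = 5e-5
    translocation: float = 5e-5
    indel_len_max: int = 6

    def __post_init__(self):
        for t in EventType:
            if self.rate(t) < 0:
                raise ValueError("mutation rates must be >= 0")
        if self.indel_len_max < 1:
            raise ValueError("indel_len_max must be >= 1")

    def rate(self, etype: EventType) -> float:
        return getattr(self, etype.value)

    @classmethod
    def zero(cls) -> "MutationRates":
        return cls(0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class MutationEvent:
    """One recorded replication event, replayable via :func:`apply_event`."""

    type: EventType
    p1: Optional[int] = None
    p2: Optional[int] = None
    p3: Optional[int] = None
    length: Optional[int] = None  # small-indel length
    seq: Optional[str] = None  # inserted sequence (small insertion)
    dL: int = 0  # signed genome-length change
    applied: bool = True  # False when the event was skipped

    def to_record(self) -> dict:
        return {
            "type": self.type.value, "p1": self.p1, "p2": self.p2,
            "p3": self.p3, "length": self.length, "seq": self.seq,
            "dL": self.dL, "applied": self.applied,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "MutationEvent":
        rec = dict(rec)
        rec["type"] = EventType(rec["type"])
        return cls(**rec)


def draw_event_counts(L: int, rates: MutationRates, rng: np.random.Generator,
                      types: Tuple[EventType, ...] = REARRANGEMENT_TYPES
                      ) -> Dict[EventType, int]:
    """Independent Binomial(L, u_type) counts, one per requested type.

    By default draws the four rearrangement counts; pass ``LOCAL_TYPES``
    for the three local-mutation counts (the caller supplies the
    post-rearrangement length).
    """
    if L < 1:
        raise ValueError("genome length must be >= 1")
    return {t: int(rng.binomial(L, rates.rate(t))) for t in types}


# -- application of individual events ---------------------------------------


def _skipped(etype: EventType, **kw) -> MutationEvent:
    return MutationEvent(type=etype, dL=0, applied=False, **kw)


def _segment(bits: np.ndarray, p1: int, p2: int) -> np.ndarray:
    """Copy of the clockwise-inclusive segment {p1, ..., p2}."""
    if p1 <= p2:
        return bits[p1: p2 + 1]
    return np.concatenate([bits[p1:], bits[: p2 + 1]])


def _without_segment(bits: np.ndarray, p1: int, p2: int) -> np.ndarray:
    """Genome bits with the clockwise-inclusive segment removed."""
    if p1 <= p2:
        return np.concatenate([bits[:p1], bits[p2 + 1:]])
    return bits[p2 + 1: p1].copy()


def _insert_at(bits: np.ndarray, at: int, seg: np.ndarray) -> np.ndarray:
    return np.concatenate([bits[:at], seg, bits[at:]])


def apply_event(genome: Genome, event: MutationEvent) -> Genome:
    """Deterministically re-apply a recorded event (used for lineage replay)."""
    if not event.applied:
        return genome
    bits = genome.bits
    L = bits.size
    t = event.type
    if t is EventType.POINT:
        out = bits.copy()
        out[event.p1] ^= 1
        return Genome._trusted(out)
    if t is EventType.SMALL_INS:
        ins = np.frombuffer(event.seq.encode("ascii"), dtype=np.uint8) - ord("0")
        return Genome._trusted(_insert_at(bits, event.p1, ins))
    if t is EventType.SMALL_DEL:
        p2 = (event.p1 + event.length - 1) % L
        return Genome._trusted(_without_segment(bits, event.p1, p2))
    if t is EventType.LARGE_DEL:
        return Genome._trusted(_without_segment(bits, event.p1, event.p2))
    if t is EventType.DUPLICATION:
        seg = _segment(bits, event.p1, event.p2)
        return Genome._trusted(_insert_at(bits, event.p3, seg))
    if t is EventType.INVERSION:
        out = bits.copy()
        inverted = 1 - _segment(bits, event.p1, event.p2)[::-1]
        if event.p1 <= event.p2:
            out[event.p1: event.p2 + 1] = inverted
        else:
            head = L - event.p1
            out[event.p1:] = inverted[:head]
            out[: event.p2 + 1] = inverted[head:]
        return Genome._trusted(out)
    if t is EventType.TRANSLOCATION:
        seg = _segment(bits, event.p1, event.p2)
        remainder = _without_segment(bits, event.p1, event.p2)
        return Genome._trusted(_insert_at(remainder, event.p3, seg))
    raise ValueError(f"unknown event type {t!r}")  # pragma: no cover


def apply_point_mutation(genome: Genome, rng: np.random.Generator
                         ) -> Tuple[Genome, MutationEvent]:
    """Flip one uniformly chosen position."""
    p = int(rng.integers(len(genome)))
    ev = MutationEvent(type=EventType.POINT, p1=p, dL=0)
    return apply_event(genome, ev), ev


def apply_small_indel(genome: Genome, kind: str, rng: np.random.Generator,
                      indel_len_max: int = 6) -> Tuple[Genome, MutationEvent]:
    """Insert or delete a short segment (length uniform on {1..max}).

    ``kind`` is "insertion" or "deletion".  Insertions add fresh uniform
    random symbols before a uniform position; deletions remove a clockwise
    run (wrapping) and are skipped if they would empty the genome.
    """
    L = len(genome)
    ell = int(rng.integers(1, indel_len_max + 1))
    p = int(rng.integers(L))
    if kind == "insertion":
        seq = "".join("01"[b] for b in rng.integers(0, 2, size=ell).tolist())
        ev = MutationEvent(type=EventType.SMALL_INS, p1=p, length=ell,
                           seq=seq, dL=ell)
        return apply_event(genome, ev), ev
    if kind == "deletion":
        if L - ell < 1:
            return genome, _skipped(EventType.SMALL_DEL, p1=p, length=ell)
        ev = MutationEvent(type=EventType.SMALL_DEL, p1=p, length=ell, dL=-ell)
        return apply_event(genome, ev), ev
    raise ValueError(f"kind must be 'insertion' or 'deletion', got {kind!r}")


def apply_rearrangement(genome: Genome, etype: EventType,
                        rng: np.random.Generator
                        ) -> Tuple[Genome, MutationEvent]:
    """Apply one large rearrangement with uniformly drawn breakpoints.

    Draw order (fixed for reproducibility): p1, then p2, then p3 where
    applicable.  For a translocation, p3 is drawn uniformly on the
    re-ligated remainder (length L - segment), honouring "moved after
    circularization"; whole-genome deletions/translocations are skipped.
    """
    L = len(genome)
    p1 = int(rng.integers(L))
    p2 = int(rng.integers(L))
    seg_len = (p2 - p1) % L + 1
    if etype is EventType.LARGE_DEL:
        if seg_len >= L:
            return genome, _skipped(EventType.LARGE_DEL, p1=p1, p2=p2)
        ev = MutationEvent(type=EventType.LARGE_DEL, p1=p1, p2=p2, dL=-seg_len)
        return apply_event(genome, ev), ev
    if etype is EventType.INVERSION:
        ev = MutationEvent(type=EventType.INVERSION, p1=p1, p2=p2, dL=0)
        return apply_event(genome, ev), ev
    if etype is EventType.DUPLICATION:
        p3 = int(rng.integers(L))
        ev = MutationEvent(type=EventType.DUPLICATION, p1=p1, p2=p2, p3=p3,
                           dL=seg_len)
        return apply_event(genome, ev), ev
    if etype is EventType.TRANSLOCATION:
        if seg_len >= L:
            return genome, _skipped(EventType.TRANSLOCATION, p1=p1, p2=p2)
        p3 = int(rng.integers(L - seg_len))  # position on the remainder
        ev = MutationEvent(type=EventType.TRANSLOCATION, p1=p1, p2=p2, p3=p3,
                           dL=0)
        return apply_event(genome, ev), ev
    raise ValueError(f"{etype} is not a rearrangement type")


_LOCAL_APPLY = {
    EventType.POINT: lambda g, rng, rates: apply_point_mutation(g, rng),
    EventType.SMALL_INS: lambda g, rng, rates: apply_small_indel(
        g, "insertion", rng, rates.indel_len_max),
    EventType.SMALL_DEL: lambda g, rng, rates: apply_small_indel(
        g, "deletion", rng, rates.indel_len_max),
}


def mutate_genome(genome: Genome, rates: MutationRates,
                  rng: np.random.Generator
                  ) -> Tuple[Genome, List[MutationEvent]]:
    """Replicate a genome with mutations; returns (child, ordered event log).

    RNG consumption order: four rearrangement counts (large deletion,
    duplication, inversion, translocation), one shuffle, per-event draws;
    then three local counts (point, small insertion, small deletion), one
    shuffle, per-event draws.  Shuffles are only drawn when at least two
    events of the batch exist.
    """
    events: List[MutationEvent] = []

    rearr_counts = draw_event_counts(len(genome), rates, rng,
                                     REARRANGEMENT_TYPES)
    batch: List[EventType] = []
    for t in REARRANGEMENT_TYPES:
        batch.extend([t] * rearr_counts[t])
    if len(batch) > 1:
        order = rng.permutation(len(batch))
        batch = [batch[i] for i in order]
    for t in batch:
        genome, ev = apply_rearrangement(genome, t, rng)
        events.append(ev)

    local_counts = draw_event_counts(len(genome), rates, rng, LOCAL_TYPES)
    batch = []
    for t in LOCAL_TYPES:
        batch.extend([t] * local_counts[t])
    if len(batch) > 1:
        order = rng.permutation(len(batch))
        batch = [batch[i] for i in order]
    for t in batch:
        genome, ev = _LOCAL_APPLY[t](genome, rng, rates)
        events.append(ev)

    return genome, events
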