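"""Hand-built genomes with known decoded content (synthetic test support).

A fixture recipe lists transcription units (promoter, one or more coding
sequences, terminator) with requested protein parameters (m, w, h) and
codon counts.  The compiler inverse-encodes the parameters by Gray-coding
their quantised raw integers, interlaces the M/W/H codons, assembles the
unit and plants it on an all-zero background (which contains neither
promoter nor terminator windows).  Binary sequences fold into stem-loops
easily, so each unit is repaired until its planted terminator is the
first fold after the promoter: bad windows over a gene body are cut by
inserting silent START codons, bad windows over free bits (spacers,
inter-signal gaps) by re-drawing them.  The assembled genome is finally
decoded and compared against the planted feature set, and re-built until
the decode matches exactly, so the returned genome is guaranteed to
decode to precisely what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .decoding import (
    DecodingRules,
    M0, M1, W0, W1, H0, H1,
    Promoter,
    decode_genome,
    expression_level,
    find_promoters,
    int_to_gray,
)
from .genome import Genome, Strand

__all__ = [
    "CdsSpec",
    "TranscriptSpec",
    "FixtureSpec",
    "PlantedFeatures",
    "FixtureError",
    "compile_fixture",
]

#: A valid stem-loop: arms "0101" / "0101" are mutually reverse-complementary.
DEFAULT_TERMINATOR = "01011110101"


class FixtureError(ValueError):
    """The requested fixture cannot be built as specified."""


@dataclass(frozen=True)
class CdsSpec:
    """One planted gene: requested parameters and codon counts."""

    m: float
    w: float
    h: float
    n_m: int = 8
    n_w: int = 4
    n_h: int = 3

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise FixtureError(f"m must be in [0,1], got {self.m}")
        if not -1.0 <= self.h <= 1.0:
            raise FixtureError(f"h must be in [-1,1], got {self.h}")
        if min(self.n_m, self.n_w, self.n_h) < 0:
            raise FixtureError("codon counts must be >= 0")


@dataclass(frozen=True)
class TranscriptSpec:
    """One transcription unit: a promoter, its genes, a terminator."""

    cds: Tuple[CdsSpec, ...]
    promoter_mismatches: int = 0
    strand: Strand = Strand.LEADING

    def __post_init__(self):
        object.__setattr__(self, "cds", tuple(self.cds))


@dataclass(frozen=True)
class FixtureSpec:
    transcripts: Tuple[TranscriptSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "transcripts", tuple(self.transcripts))


@dataclass(frozen=True)
class PlantedProtein:
    strand: Strand
    init_pos: int
    m: float
    w: float
    h: float
    e: float


@dataclass(frozen=True)
class PlantedFeatures:
    """What the compiled genome is guaranteed to decode to."""

    promoters: Tuple[Promoter, ...]
    rnas: Tuple[Tuple[Strand, int, int], ...]  # (strand, first, last)
    proteins: Tuple[PlantedProtein, ...]


def _quantise(value: float, lo: float, hi: float, n: int, name: str) -> int:
    """Nearest representable raw Gray integer for ``value`` on [lo, hi]."""
    if not lo <= value <= hi:
        raise FixtureError(f"{name}={value} outside [{lo}, {hi}]")
    if n == 0:
        if value == 0.0:
            return 0
        raise FixtureError(
            f"{name}={value} not representable with 0 codons (nearest: 0.0)")
    span = (1 << n) - 1
    return min(max(round((value - lo) / (hi - lo) * span), 0), span)


def _interlace(per_role, rng: np.random.Generator, shuffle: bool) -> List[str]:
    order = [i for i, lst in enumerate(per_role) for _ in lst]
    if shuffle and len(order) > 1:
        order = [order[i] for i in rng.permutation(len(order))]
    cursors = [0, 0, 0]
    codons = []
    for role in order:
        codons.append(per_role[role][cursors[role]])
        cursors[role] += 1
    return codons


def _encode_cds(spec: CdsSpec, rules: DecodingRules, rng: np.random.Generator,
                shuffle: bool) -> Tuple[List[str], float, float, float]:
    """Interlaced codon list and the exact (m, w, h) it decodes to.

    The representable values mirror the decoder's arithmetic step for step
    so the decoded floats compare equal bit for bit.
    """
    codon = rules.codon_of_role
    raw_m = _quantise(spec.m, 0.0, 1.0, spec.n_m, "m")
    raw_w = _quantise(spec.w, 0.0, rules.w_max, spec.n_w, "w")
    raw_h = _quantise(spec.h, -1.0, 1.0, spec.n_h, "h")
    rep_m = raw_m / ((1 << spec.n_m) - 1) if spec.n_m else 0.0
    rep_w = rules.w_max * (raw_w / ((1 << spec.n_w) - 1)) if spec.n_w else 0.0
    rep_h = (2.0 * (raw_h / ((1 << spec.n_h) - 1)) - 1.0) if spec.n_h else 0.0

    per_role = []
    for raw, n, zero, one in ((raw_m, spec.n_m, M0, M1),
                              (raw_w, spec.n_w, W0, W1),
                              (raw_h, spec.n_h, H0, H1)):
        if n:
            per_role.append([codon[one] if b == "1" else codon[zero]
                             for b in int_to_gray(raw, n)])
        else:
            per_role.append([])
    return _interlace(per_role, rng, shuffle), rep_m, rep_w, rep_h


def _find_fold(seq: str, start: int, stop: int,
               stem: int, tl: int) -> Optional[int]:
    """First stem-loop window starting in [start, stop), or None."""
    for p in range(start, stop):
        win = seq[p: p + tl]
        if len(win) == tl and all(win[i] != win[tl - 1 - i]
                                  for i in range(stem)):
            return p
    return None


def _find_spurious_init(seq: str, start: int, stop: int, rules: DecodingRules,
                        planted: set) -> Optional[int]:
    sd = rules.shine_dalgarno
    off = len(sd) + rules.spacer_len
    for p in range(start, stop):
        if p in planted:
            continue
        if (seq[p: p + len(sd)] == sd
                and seq[p + off: p + off + rules.codon_len]
                == rules.start_codon):
            return p
    return None


def _build_unit(tr: TranscriptSpec, rules: DecodingRules,
                rng: np.random.Generator, shuffle: bool,
                max_repairs: int = 600):
    """One clean transcription unit as a bit string.

    Layout: promoter | gap | (SD + spacer + start + codons + stop | gap)*
    | terminator.  The unit is repaired until the planted terminator is the
    first stem-loop after the promoter and no spurious initiation signal
    hides in the transcript:

    * a window overlapping a gene body is cut by inserting a silent START
      codon (which decodes to nothing) at a random boundary inside it;
    * a window overlapping an inter-signal gap or a spacer is broken by
      re-drawing those free bits.
    """
    prom = _promoter_bits(rules, tr.promoter_mismatches, rng)
    glen = 3

    def bits(n):
        return "".join(rng.choice(["0", "1"], size=n))

    # gaps[0] follows the promoter; gaps[i] follows gene i's stop codon
    gaps = ["111"] * (len(tr.cds) + 1)
    encoded = []
    for cs in tr.cds:
        codons, m, w, h = _encode_cds(cs, rules, rng, shuffle)
        encoded.append({"codons": codons, "spacer": bits(rules.spacer_len),
                        "params": (m, w, h)})

    stem, tl = rules.stem_len, rules.terminator_len

    def assemble():
        parts = [prom, gaps[0]]
        cds_info, body_spans, head_spans, gap_spans = [], [], [], []
        cursor = len(prom)
        gap_spans.append((0, cursor, cursor + glen))
        cursor += glen
        for gi, enc in enumerate(encoded):
            body = "".join(enc["codons"])
            head = rules.shine_dalgarno + enc["spacer"] + rules.start_codon
            cds_info.append((cursor, *enc["params"]))
            head_spans.append((gi, cursor, cursor + len(head)))
            body_start = cursor + len(head)
            body_spans.append((gi, body_start, body_start + len(body) + 3))
            parts.append(head + body + rules.stop_codon + gaps[gi + 1])
            cursor += len(head) + len(body) + 3
            gap_spans.append((gi + 1, cursor, cursor + glen))
            cursor += glen
        parts.append(DEFAULT_TERMINATOR)
        return ("".join(parts), cds_info, body_spans, head_spans, gap_spans,
                cursor)

    for _ in range(max_repairs):
        (unit, cds_info, body_spans, head_spans, gap_spans,
         term_at) = assemble()
        t_start = len(prom)
        bad = _find_fold(unit, t_start, term_at, stem, tl)
        window = tl
        if bad is None:
            bad = _find_spurious_init(unit, t_start, term_at, rules,
                                      {c[0] for c in cds_info})
            window = rules.init_signal_len
        if bad is None:
            return unit, cds_info
        w_end = bad + window
        # candidate repairs the window admits, in random order
        actions = []
        for gi, b0, b1 in body_spans:
            jlo = max(-(-(bad + 1 - b0) // 3), 0)
            jhi = min((w_end - 1 - b0) // 3, len(encoded[gi]["codons"]))
            if jlo <= jhi and b0 + 3 * jhi > bad:
                actions.append(("insert", gi, jlo, jhi))
        for gi, g0, g1 in gap_spans:
            if bad < g1 and w_end > g0:
                actions.append(("gap", gi, 0, 0))
        for gi, h0, h1 in head_spans:
            if bad < h1 and w_end > h0:
                actions.append(("spacer", gi, 0, 0))
        if actions:
            kind, gi, jlo, jhi = actions[int(rng.integers(len(actions)))]
            if kind == "insert":
                j = int(rng.integers(jlo, jhi + 1))
                encoded[gi]["codons"].insert(j, rules.start_codon)
            elif kind == "gap":
                gaps[gi] = bits(glen)
            else:
                encoded[gi]["spacer"] = bits(rules.spacer_len)
        else:  # window touches only fixed signals: re-draw all free bits
            gaps[:] = [bits(glen) for _ in gaps]
            for enc in encoded:
                enc["spacer"] = bits(rules.spacer_len)
    raise FixtureError("could not build a clean transcription unit "
                       f"for {tr!r}")


def _promoter_bits(rules: DecodingRules, d: int,
                   rng: np.random.Generator) -> str:
    if not 0 <= d <= rules.d_max:
        raise FixtureError(
            f"promoter mismatches must be in [0, {rules.d_max}], got {d}")
    bits = list(rules.consensus)
    for i in rng.choice(len(bits), size=d, replace=False):
        bits[i] = "1" if bits[i] == "0" else "0"
    return "".join(bits)


def _revcomp_str(s: str) -> str:
    return "".join("1" if c == "0" else "0" for c in reversed(s))


def compile_fixture(spec: FixtureSpec, background_length: int,
                    rng: np.random.Generator,
                    rules: Optional[DecodingRules] = None,
                    max_attempts: int = 200,
                    unit_gap: int = 40,
                    ) -> Tuple[Genome, PlantedFeatures]:
    """Compile a fixture recipe into a genome plus its guaranteed decode.

    Raises :class:`FixtureError` when the requested features cannot be
    realised (unrepresentable parameters, colliding features, or a recipe
    whose fixed parts unavoidably contain spurious signals).
    """
    rules = rules or DecodingRules()
    if not spec.transcripts:
        genome = Genome(np.zeros(background_length, dtype=np.uint8))
        return genome, PlantedFeatures((), (), ())

    last_mismatch = None
    for attempt in range(max_attempts):
        shuffle = attempt > 0
        try:
            genome, planted = _assemble(spec, background_length, rng, rules,
                                        shuffle, unit_gap)
        except FixtureError:
            raise
        mismatch = _verify(genome, planted, rules)
        if mismatch is None:
            return genome, planted
        last_mismatch = mismatch
    raise FixtureError(
        f"could not realise fixture in {max_attempts} attempts; "
        f"last mismatch: {last_mismatch}")


def _assemble(spec: FixtureSpec, background_length: int,
              rng: np.random.Generator, rules: DecodingRules,
              shuffle: bool, unit_gap: int
              ) -> Tuple[Genome, PlantedFeatures]:
    units: List[Tuple[str, TranscriptSpec, List[Tuple[int, float, float, float]]]] = []
    for tr in spec.transcripts:
        unit, cds_info = _build_unit(tr, rules, rng, shuffle)
        units.append((unit, tr, cds_info))

    total_units = sum(len(u) for u, _, _ in units)
    needed = total_units + unit_gap * len(units)
    if needed > background_length:
        raise FixtureError(
            f"background of {background_length} bp too small for planted "
            f"features ({needed} bp needed)")
    L = background_length
    bits = np.zeros(L, dtype=np.uint8)
    promoters, rnas, proteins = [], [], []
    offset = unit_gap // 2
    for unit, tr, cds_info in units:
        u_len = len(unit)
        stored = unit if tr.strand is Strand.LEADING else _revcomp_str(unit)
        seg = np.frombuffer(stored.encode(), dtype=np.uint8) - ord("0")
        bits[offset: offset + u_len] = seg
        if tr.strand is Strand.LEADING:
            local = offset
        else:
            local = L - offset - u_len
        d = tr.promoter_mismatches
        e = expression_level(d, rules.d_max)
        promoters.append(Promoter(tr.strand, local, d, e))
        first = local + rules.promoter_len
        last = local + u_len - 1
        rnas.append((tr.strand, first, last))
        for off, m, w, h in cds_info:
            proteins.append(PlantedProtein(tr.strand, local + off, m, w, h, e))
        offset += u_len + unit_gap
    genome = Genome(bits)
    return genome, PlantedFeatures(tuple(promoters), tuple(rnas),
                                   tuple(proteins))


def _verify(genome: Genome, planted: PlantedFeatures,
            rules: DecodingRules) -> Optional[str]:
    """None when the genome decodes exactly to the planted features."""
    found_proms = {(p.strand, p.pos, p.d) for p in find_promoters(genome, rules)}
    want_proms = {(p.strand, p.pos, p.d) for p in planted.promoters}
    if found_proms != want_proms:
        return f"promoters differ: {found_proms ^ want_proms}"
    proteome = decode_genome(genome, rules)
    found_rnas = {(r.strand, r.first, r.last) for r, _ in proteome}
    want_rnas = set(planted.rnas)
    if not found_rnas <= want_rnas:
        return f"unexpected RNAs: {found_rnas - want_rnas}"
    found_prots = {(p.cds.strand, p.cds.init_pos, p.m, p.w, p.h, p.e)
                   for _, p in proteome}
    want_prots = {(p.strand, p.init_pos, p.m, p.w, p.h, p.e)
                  for p in planted.proteins}
    if found_prots != want_prots:
        return f"proteins differ: {found_prots ^ want_prots}"
    return None
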