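"""Transcription/translation grammar: from binary genome to proteins.

Decoding is a pure function of (genome, rules).  Both strands are scanned
for promoters (windows within ``d_max`` mismatches of a consensus) and
rho-independent-like terminators (stem-loop windows).  Each promoter is
extended to the first downstream terminator, giving an RNA with expression
level ``e = 1 - d / (d_max + 1)``.  Inside each RNA, every occurrence of
the translation initiation signal (Shine-Dalgarno-like motif, four spacer
bases, then the start codon) opens a reading frame that is translated
codon by codon until the in-frame stop codon; frames with no in-frame stop
inside the RNA yield no protein.

A coding sequence is the interlacing of the Gray codes of three real
parameters: ``m`` (the protein's main cellular process, in [0,1]),
``w`` (its pleiotropy half-width, in [0, w_max]) and ``h`` (its efficiency,
in [-1,1]; the sign decides activation vs inhibition).  Each parameter has
two dedicated codons whose last bit supplies the next bit of its Gray code.
The protein's phenotypic height is ``H = e * |h|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .genome import Genome, Strand

__all__ = [
    "DecodingRules",
    "Promoter",
    "Rna",
    "CodingSequence",
    "Protein",
    "expression_level",
    "gray_to_int",
    "int_to_gray",
    "find_promoters",
    "is_terminator",
    "find_transcripts",
    "find_coding_sequences",
    "decode_protein",
    "decode_genome",
    "strand_local_to_stored",
    "annotation_table",
]

# Codon roles.  START opens translation, STOP closes it; the three
# parameter roles each come in a 0-flavour and a 1-flavour whose last bit
# is the next Gray-code bit of that parameter.
START = "START"
STOP = "STOP"
M0, M1 = "M0", "M1"
W0, W1 = "W0", "W1"
H0, H1 = "H0", "H1"

DEFAULT_GENETIC_CODE: Dict[str, str] = {
    "000": START,
    "001": STOP,
    "010": W0,
    "011": W1,
    "100": M0,
    "101": M1,
    "110": H0,
    "111": H1,
}


def _bits_of(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0")


@dataclass(frozen=True)
class DecodingRules:
    """All constants of the transcription/translation grammar.

    Defaults follow the standard parameterisation: 22-bp promoter
    consensus with up to 4 mismatches, 4-bp stem / 3-bp loop terminator,
    initiation motif ``011011`` + 4 wildcards + start codon ``000``, stop
    codon ``001``, and maximal pleiotropy ``w_max = 5e-3``.
    """

    consensus: str = "0101011001110010010110"
    d_max: int = 4
    stem_len: int = 4
    loop_len: int = 3
    shine_dalgarno: str = "011011"
    spacer_len: int = 4
    start_codon: str = "000"
    stop_codon: str = "001"
    codon_len: int = 3
    genetic_code: Tuple[Tuple[str, str], ...] = tuple(
        sorted(DEFAULT_GENETIC_CODE.items())
    )
    w_max: float = 5e-3

    def __post_init__(self):
        if not 0 <= self.d_max < len(self.consensus):
            raise ValueError("d_max must satisfy 0 <= d_max < len(consensus)")
        code = dict(self.genetic_code)
        n = self.codon_len
        if sorted(code) != [format(i, f"0{n}b") for i in range(2 ** n)]:
            raise ValueError("genetic code must cover every codon exactly once")
        if sorted(code.values()) != sorted([START, STOP, M0, M1, W0, W1, H0, H1]):
            raise ValueError("genetic code must be a bijection onto the 8 roles")

    # Derived, cached numeric views ------------------------------------

    @cached_property
    def consensus_bits(self) -> np.ndarray:
        return _bits_of(self.consensus)

    @cached_property
    def promoter_len(self) -> int:
        return len(self.consensus)

    @cached_property
    def terminator_len(self) -> int:
        return 2 * self.stem_len + self.loop_len

    @cached_property
    def init_signal_len(self) -> int:
        return len(self.shine_dalgarno) + self.spacer_len + self.codon_len

    @cached_property
    def sd_bits(self) -> np.ndarray:
        return _bits_of(self.shine_dalgarno)

    @cached_property
    def start_bits(self) -> np.ndarray:
        return _bits_of(self.start_codon)

    @cached_property
    def stop_bits(self) -> np.ndarray:
        return _bits_of(self.stop_codon)

    @cached_property
    def code(self) -> Dict[str, str]:
        return dict(self.genetic_code)

    @cached_property
    def role_of_codon(self) -> Tuple[str, ...]:
        """Role of codon value v (codon bits read as a binary integer)."""
        n = self.codon_len
        return tuple(self.code[format(v, f"0{n}b")] for v in range(2 ** n))

    @cached_property
    def codon_of_role(self) -> Dict[str, str]:
        return {role: codon for codon, role in self.code.items()}

    @cached_property
    def _param_cache(self) -> dict:
        # decoded (m, w, h, n_m, n_w, n_h) per body-codon tuple; gene content
        # recurs across individuals and generations, so this hits constantly
        return {}


@dataclass(slots=True)
class Promoter:
    strand: Strand
    pos: int  # strand-local position of the first consensus-matched symbol
    d: int  # Hamming distance to the consensus
    e: float  # expression level 1 - d/(d_max+1)


class CodingSequence:
    """One open reading frame: initiation signal through stop codon.

    Body codons are stored compactly as ``bytes`` of codon values (0-7);
    ``codon_values`` exposes them as a tuple.  Evolved genomes carry many
    long junk ORFs, so compact storage matters for population memory.
    """

    __slots__ = ("strand", "init_pos", "start_codon_pos", "stop_codon_pos",
                 "codon_bytes")

    def __init__(self, strand: Strand, init_pos: int, start_codon_pos: int,
                 stop_codon_pos: int, codon_values=b""):
        self.strand = strand
        self.init_pos = init_pos
        self.start_codon_pos = start_codon_pos
        self.stop_codon_pos = stop_codon_pos
        self.codon_bytes = bytes(codon_values)

    @property
    def codon_values(self) -> Tuple[int, ...]:
        return tuple(self.codon_bytes)

    def codons(self, rules: DecodingRules) -> Tuple[str, ...]:
        """Role labels of the body codons."""
        return tuple(rules.role_of_codon[v] for v in self.codon_bytes)

    def __eq__(self, other):
        if not isinstance(other, CodingSequence):
            return NotImplemented
        return (self.strand, self.init_pos, self.start_codon_pos,
                self.stop_codon_pos, self.codon_bytes) == \
               (other.strand, other.init_pos, other.start_codon_pos,
                other.stop_codon_pos, other.codon_bytes)

    def __hash__(self):
        return hash((self.strand, self.init_pos, self.stop_codon_pos,
                     self.codon_bytes))

    def __repr__(self):
        return (f"CodingSequence({self.strand}, init={self.init_pos}, "
                f"start={self.start_codon_pos}, stop={self.stop_codon_pos}, "
                f"n_codons={len(self.codon_bytes)})")


@dataclass(slots=True)
class Protein:
    m: float
    w: float
    h: float
    e: float
    H: float
    functional: bool
    n_m: int
    n_w: int
    n_h: int
    cds: Optional[CodingSequence] = None

    @property
    def is_activator(self) -> bool:
        return self.h > 0


@dataclass(slots=True)
class Rna:
    strand: Strand
    promoter: Promoter
    first: int  # strand-local position of the first transcribed symbol
    last: int  # strand-local position of the terminator's last symbol
    length: int
    e: float
    cds_list: List[CodingSequence] = field(default_factory=list)


# -- elementary operations -------------------------------------------------


def expression_level(d: int, d_max: int) -> float:
    """Expression level of a promoter with ``d`` mismatches: 1 - d/(d_max+1)."""
    if not 0 <= d <= d_max:
        raise ValueError(f"d must be in [0, {d_max}], got {d}")
    return 1.0 - d / (d_max + 1)


def gray_to_int(bits: Union[str, Sequence[int], np.ndarray]) -> int:
    """Decode a reflected-binary (Gray) code to its integer value."""
    if isinstance(bits, str):
        seq = [int(c) for c in bits]
    else:
        seq = [int(b) for b in bits]
    if len(seq) == 0:
        raise ValueError("Gray code must contain at least one bit")
    if any(b not in (0, 1) for b in seq):
        raise ValueError("Gray code bits must be 0 or 1")
    value = 0
    acc = 0
    for b in seq:
        acc ^= b
        value = (value << 1) | acc
    return value


def int_to_gray(value: int, n_bits: int) -> str:
    """Inverse of :func:`gray_to_int` for ``value`` in [0, 2**n_bits)."""
    if not 0 <= value < 2 ** n_bits:
        raise ValueError(f"value {value} not representable in {n_bits} Gray bits")
    g = value ^ (value >> 1)
    return format(g, f"0{n_bits}b")


def strand_local_to_stored(strand: Strand, pos: int, L: int) -> int:
    """Map a strand-local position to the stored-strand index."""
    pos %= L
    return pos if strand is Strand.LEADING else (L - 1 - pos) % L


# -- whole-strand signal scans ---------------------------------------------


class _StrandScan:
    """Vectorised signal maps of one strand (promoters, terminators, ...)."""

    __slots__ = (
        "seq", "prom_pos", "prom_d", "term_pos", "init_pos", "is_stop", "codon_val",
    )

    def __init__(self, seq: np.ndarray, rules: DecodingRules):
        L = seq.size
        self.seq = seq
        need = max(rules.promoter_len, rules.terminator_len,
                   rules.init_signal_len) - 1
        reps = -(-(L + need) // L)  # ceil
        ext = np.tile(seq, reps)[: L + need]

        # Promoters: Hamming distance of every window to the consensus,
        # accumulated one consensus position (= one shifted slice) at a
        # time; distances fit in uint8.
        d = np.zeros(L, dtype=np.uint8)
        for i, c in enumerate(rules.consensus_bits.tolist()):
            if c:
                d += 1 - ext[i: i + L]
            else:
                d += ext[i: i + L]
        mask = d <= rules.d_max
        self.prom_pos = np.nonzero(mask)[0]
        self.prom_d = d[mask].astype(int)

        # Terminators: stem positions must be pairwise complementary, i.e.
        # unequal in a binary alphabet.  Loop bases are unconstrained.
        tl = rules.terminator_len
        term = ext[:L] != ext[tl - 1: tl - 1 + L]
        for i in range(1, rules.stem_len):
            term &= ext[i: i + L] != ext[tl - 1 - i: tl - 1 - i + L]
        self.term_pos = np.nonzero(term)[0]

        # Translation initiation signals: motif + wildcards + start codon.
        sd = rules.sd_bits
        off = len(sd) + rules.spacer_len
        init = ext[:L] == sd[0]
        for j in range(1, len(sd)):
            init &= ext[j: j + L] == sd[j]
        for k, b in enumerate(rules.start_bits.tolist()):
            init &= ext[off + k: off + k + L] == b
        self.init_pos = np.nonzero(init)[0]

        # Per-position codon values and stop-codon mask, tiled to 2L so
        # in-frame scans can use plain strided slices without wrapping.
        val = ext[:L].astype(np.uint8).copy()
        for j in range(1, rules.codon_len):
            val <<= 1
            val += ext[j: j + L]
        self.codon_val = np.concatenate([val, val])
        self.is_stop = self.codon_val == int(rules.stop_codon, 2)


def _scan(genome: Genome, rules: DecodingRules) -> Dict[Strand, _StrandScan]:
    return {s: _StrandScan(genome.strand_sequence(s), rules) for s in Strand}


def find_promoters(genome: Genome, rules: DecodingRules) -> List[Promoter]:
    """All promoter windows on both strands, sorted by (strand, position)."""
    out: List[Promoter] = []
    for strand, scan in _scan(genome, rules).items():
        for pos, d in zip(scan.prom_pos.tolist(), scan.prom_d.tolist()):
            out.append(Promoter(strand, pos, d, expression_level(d, rules.d_max)))
    return out


def is_terminator(genome: Genome, strand: Strand, pos: int,
                  rules: DecodingRules) -> bool:
    """Whether the stem-loop window starting at strand-local ``pos`` can fold."""
    L = len(genome)
    if not 0 <= pos < L:
        raise ValueError(f"pos must be in [0, {L})")
    seq = genome.strand_sequence(strand)
    tl = rules.terminator_len
    idx = (pos + np.arange(tl)) % L
    win = seq[idx]
    return all(win[i] != win[tl - 1 - i] for i in range(rules.stem_len))


def _transcript_arrays(scan: _StrandScan, rules: DecodingRules, L: int):
    """Vectorised transcripts of one strand.

    Returns (promoter pos, promoter d, transcript first, transcript length)
    arrays for every promoter whose first downstream terminator keeps the
    transcript under one full turn.
    """
    P, D, T = scan.prom_pos, scan.prom_d, scan.term_pos
    if P.size == 0 or T.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z
    first = (P + rules.promoter_len) % L
    i = np.searchsorted(T, first)
    wrap = i == T.size
    q = T[np.where(wrap, 0, i)]
    off = np.where(wrap, q + L - first, q - first)
    length = off + rules.terminator_len
    keep = length < L  # a transcript may not cover a full turn
    return P[keep], D[keep], first[keep], length[keep]


def find_transcripts(genome: Genome, rules: DecodingRules,
                     _scans: Optional[Dict[Strand, _StrandScan]] = None,
                     attach_cds: bool = False) -> List[Rna]:
    """RNAs from every promoter extended to its first downstream terminator.

    The transcript starts at the first position after the promoter window
    and runs through the last symbol of the terminator window.  A promoter
    whose first downstream terminator would make the transcript cover a
    full turn or more yields no RNA.  Several promoters may share one
    terminator (overlapping transcripts).
    """
    L = len(genome)
    scans = _scans if _scans is not None else _scan(genome, rules)
    rnas: List[Rna] = []
    inv_dmax1 = 1.0 / (rules.d_max + 1)
    for strand in Strand:
        scan = scans[strand]
        P, D, first, length = _transcript_arrays(scan, rules, L)
        for pos, d, f, ln in zip(P.tolist(), D.tolist(), first.tolist(),
                                 length.tolist()):
            e = 1.0 - d * inv_dmax1
            rna = Rna(strand, Promoter(strand, pos, d, e), f,
                      (f + ln - 1) % L, ln, e)
            if attach_cds:
                rna.cds_list = _cds_in_rna(scan, rna, rules, L, {})
            rnas.append(rna)
    return rnas


_MISSING = object()


def _translate_global(scan: _StrandScan, init: int, rules: DecodingRules,
                      L: int, strand: Strand):
    """First in-frame stop downstream of an initiation signal, circular.

    The first stop is a property of the genome alone; whether the CDS is
    valid inside a given transcript is the caller's bounds check.  Returns
    (cds, delta, params) where ``delta`` is the downstream distance from
    the initiation signal to the stop codon, or None when no stop exists
    within the longest possible transcript.  The in-frame scan walks the
    tiled stop mask with strided slices, in growing chunks, so typical
    genes touch only a few hundred positions.
    """
    sig = rules.init_signal_len
    clen = rules.codon_len
    n_total = (L - 1 - sig) // clen
    if n_total <= 0:
        return None
    q0 = (init % L) + sig  # < L + sig, inside the tiled arrays
    stop_i = -1
    done = 0
    chunk = 128
    is_stop = scan.is_stop
    while done < n_total:
        n = min(chunk, n_total - done)
        base = q0 + clen * done
        nz = np.flatnonzero(is_stop[base: base + clen * n: clen])
        if nz.size:
            stop_i = done + int(nz[0])
            break
        done += n
        chunk *= 4
    if stop_i < 0:
        return None
    body = scan.codon_val[q0: q0 + clen * stop_i: clen]
    cds = CodingSequence(
        strand=strand,
        init_pos=init % L,
        start_codon_pos=(init + sig - clen) % L,
        stop_codon_pos=(q0 + clen * stop_i) % L,
        codon_values=np.ascontiguousarray(body).tobytes(),
    )
    delta = sig + clen * stop_i  # init -> stop downstream distance
    return cds, delta, _decode_params(cds, rules)


def _cds_in_rna(scan: _StrandScan, rna: Rna, rules: DecodingRules, L: int,
                cache: dict) -> List[CodingSequence]:
    """Coding sequences wholly inside one transcript (may overlap)."""
    sig = rules.init_signal_len
    clen = rules.codon_len
    min_cds = sig + clen  # initiation signal + stop codon
    if rna.length < min_cds or scan.init_pos.size == 0:
        return []
    offsets = (scan.init_pos - rna.first) % L
    sel = offsets <= rna.length - min_cds
    out: List[CodingSequence] = []
    for init, off in zip(scan.init_pos[sel].tolist(), offsets[sel].tolist()):
        entry = cache.get(init, _MISSING)
        if entry is _MISSING:
            entry = _translate_global(scan, init, rules, L, rna.strand)
            cache[init] = entry
        if entry is None:
            continue
        cds, delta, _ = entry
        if off + delta + clen <= rna.length:  # stop codon fits the RNA
            out.append(cds)
    return out


def find_coding_sequences(genome: Genome, rna: Rna,
                          rules: DecodingRules) -> List[CodingSequence]:
    """Public wrapper: all CDSs inside one RNA of this genome."""
    scan = _StrandScan(genome.strand_sequence(rna.strand), rules)
    return _cds_in_rna(scan, rna, rules, len(genome), {})


# -- translation of a CDS into protein parameters ---------------------------

_GRAY_ROLE_BITS = {M0: ("m", 0), M1: ("m", 1), W0: ("w", 0), W1: ("w", 1),
                   H0: ("h", 0), H1: ("h", 1)}


_PARAM_CACHE_MAX_ENTRIES = 100_000
_PARAM_CACHE_MAX_CODONS = 256  # don't cache rare giant junk ORFs


def _decode_params(cds: CodingSequence, rules: DecodingRules
                   ) -> Tuple[float, float, float, int, int, int]:
    key = cds.codon_bytes
    cacheable = len(key) <= _PARAM_CACHE_MAX_CODONS
    if cacheable:
        cached = rules._param_cache.get(key)
        if cached is not None:
            return cached
    bits = {"m": [], "w": [], "h": []}
    roles = rules.role_of_codon
    for v in key:
        entry = _GRAY_ROLE_BITS.get(roles[v])
        if entry is not None:  # START codons in the body contribute nothing
            bits[entry[0]].append(entry[1])

    def norm(key: str) -> float:
        b = bits[key]
        if not b:
            return 0.0
        return gray_to_int(b) / (2 ** len(b) - 1)

    m = norm("m")
    w = rules.w_max * norm("w")
    h = 2.0 * norm("h") - 1.0 if bits["h"] else 0.0
    out = (m, w, h, len(bits["m"]), len(bits["w"]), len(bits["h"]))
    if cacheable:
        cache = rules._param_cache
        if len(cache) >= _PARAM_CACHE_MAX_ENTRIES:
            cache.clear()
        cache[key] = out
    return out


def decode_protein(cds: CodingSequence, e: float,
                   rules: DecodingRules) -> Protein:
    """Decode a CDS expressed at level ``e`` into a protein.

    The Gray bits of each parameter are the subscripts of its codons in
    reading order; raw integers are normalised to m in [0,1],
    w in [0, w_max], h in [-1,1].  A parameter with no codon is 0 (which
    makes the protein non-functional through w or H).
    """
    m, w, h, n_m, n_w, n_h = _decode_params(cds, rules)
    H = e * abs(h)
    return Protein(m=m, w=w, h=h, e=e, H=H,
                   functional=(w > 0 and H > 0),
                   n_m=n_m, n_w=n_w, n_h=n_h, cds=cds)


def decode_genome(genome: Genome,
                  rules: DecodingRules) -> List[Tuple[Rna, Protein]]:
    """Full decode: every (RNA, protein) pair of the genome.

    A CDS hosted by several RNAs is reported once per hosting RNA, with
    that RNA's expression level (gene copies expressed from each
    promoter add their phenotypic contributions).
    """
    L = len(genome)
    out: List[Tuple[Rna, Protein]] = []
    min_cds = rules.init_signal_len + rules.codon_len
    clen = rules.codon_len
    inv_dmax1 = 1.0 / (rules.d_max + 1)
    for strand in Strand:
        scan = _StrandScan(genome.strand_sequence(strand), rules)
        P, D, first, length = _transcript_arrays(scan, rules, L)
        if P.size == 0:
            continue
        rlist = []
        for pos, d, f, ln in zip(P.tolist(), D.tolist(), first.tolist(),
                                 length.tolist()):
            e = 1.0 - d * inv_dmax1
            rlist.append(Rna(strand, Promoter(strand, pos, d, e), f,
                             (f + ln - 1) % L, ln, e))
        I = scan.init_pos
        if I.size == 0:
            continue
        # initiation signals inside each transcript, via interval queries on
        # the sorted signal positions (a dense RNA x signal matrix would be
        # quadratic in L for signal-rich genomes)
        end = first + (length - min_cds)  # last admissible signal start
        lo = np.searchsorted(I, first)
        hi = np.maximum(np.searchsorted(I, np.minimum(end, L - 1),
                                        side="right"), lo)
        wrap_hi = np.where(end >= L,
                           np.searchsorted(I, end - L, side="right"), 0)
        r_parts, i_parts = [], []
        for r in range(first.size):
            if wrap_hi[r]:
                i_parts.append(np.arange(wrap_hi[r]))
                r_parts.append(np.full(int(wrap_hi[r]), r))
            if hi[r] > lo[r]:
                i_parts.append(np.arange(lo[r], hi[r]))
                r_parts.append(np.full(int(hi[r] - lo[r]), r))
        if not i_parts:
            continue
        r_idx = np.concatenate(r_parts)
        i_idx = np.concatenate(i_parts)
        cache: dict = {}
        protein_cache: dict = {}  # e takes only d_max+1 values
        pair_offs = (I[i_idx] - first[r_idx]) % L
        for r, k, off in zip(r_idx.tolist(), i_idx.tolist(),
                             pair_offs.tolist()):
            init = int(I[k])
            entry = cache.get(init, _MISSING)
            if entry is _MISSING:
                entry = _translate_global(scan, init, rules, L, strand)
                cache[init] = entry
            if entry is None:
                continue
            cds, delta, params = entry
            rna = rlist[r]
            if off + delta + clen > rna.length:
                continue
            pkey = (init, rna.e)
            prot = protein_cache.get(pkey)
            if prot is None:
                m, w, h, n_m, n_w, n_h = params
                H = rna.e * abs(h)
                prot = Protein(m, w, h, rna.e, H, (w > 0 and H > 0),
                               n_m, n_w, n_h, cds)
                protein_cache[pkey] = prot
            rna.cds_list.append(cds)
            out.append((rna, prot))
    return out


def annotation_table(genome: Genome, rules: DecodingRules):
    """Tab-friendly feature table (promoters, RNAs, CDSs) as a DataFrame.

    Positions are 0-based inclusive in stored-strand coordinates.
    """
    import pandas as pd

    L = len(genome)
    rows = []

    def stored_span(strand: Strand, first: int, last: int):
        a = strand_local_to_stored(strand, first, L)
        b = strand_local_to_stored(strand, last, L)
        return (a, b) if strand is Strand.LEADING else (b, a)

    for p in find_promoters(genome, rules):
        a, b = stored_span(p.strand, p.pos, (p.pos + rules.promoter_len - 1) % L)
        rows.append(dict(feature="promoter", strand=p.strand.name, start=a,
                         end=b, d=p.d, e=p.e, m=None, w=None, h=None, H=None,
                         functional=None))
    proteome = decode_genome(genome, rules)
    seen_rna = set()
    for rna, prot in proteome:
        rkey = (rna.strand, rna.promoter.pos)
        if rkey not in seen_rna:
            seen_rna.add(rkey)
            a, b = stored_span(rna.strand, rna.first, rna.last)
            rows.append(dict(feature="RNA", strand=rna.strand.name, start=a,
                             end=b, d=rna.promoter.d, e=rna.e, m=None, w=None,
                             h=None, H=None, functional=None))
        cds = prot.cds
        a, b = stored_span(cds.strand, cds.start_codon_pos,
                           (cds.stop_codon_pos + rules.codon_len - 1) % L)
        rows.append(dict(feature="CDS", strand=cds.strand.name, start=a,
                         end=b, d=None, e=prot.e, m=prot.m, w=prot.w,
                         h=prot.h, H=prot.H, functional=prot.functional))
    return pd.DataFrame(rows, columns=["feature", "strand", "start", "end",
                                       "d", "e", "m", "w", "h", "H",
                                       "functional"])
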