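"""Naive reference implementations used as independent oracles in tests.

Everything here works on plain Python strings with explicit loops; no code
is shared with the package's vectorised scanners.
"""

from digevol.genome import Strand


def revcomp(s: str) -> str:
    return "".join("1" if c == "0" else "0" for c in reversed(s))


def _ext(seq: str, need: int) -> str:
    """Sequence tiled so that windows of length <= need+1 never run out."""
    reps = (len(seq) + need) // len(seq) + 1
    return seq * reps


def bf_promoters(genome_str: str, rules):
    """All (strand, pos, d) promoter windows, by explicit comparison."""
    out = []
    L = len(genome_str)
    for strand in (Strand.LEADING, Strand.LAGGING):
        seq = genome_str if strand is Strand.LEADING else revcomp(genome_str)
        ext = _ext(seq, len(rules.consensus))
        for p in range(L):
            win = ext[p: p + len(rules.consensus)]
            d = sum(a != b for a, b in zip(win, rules.consensus))
            if d <= rules.d_max:
                out.append((strand, p, d))
    return out


def bf_is_terminator(seq_ext: str, p: int, rules) -> bool:
    tl = 2 * rules.stem_len + rules.loop_len
    win = seq_ext[p: p + tl]
    return all(win[i] != win[tl - 1 - i] for i in range(rules.stem_len))


def bf_terminators(genome_str: str, rules):
    out = []
    L = len(genome_str)
    tl = 2 * rules.stem_len + rules.loop_len
    for strand in (Strand.LEADING, Strand.LAGGING):
        seq = genome_str if strand is Strand.LEADING else revcomp(genome_str)
        ext = _ext(seq, tl)
        for p in range(L):
            if bf_is_terminator(ext, p, rules):
                out.append((strand, p))
    return out


def bf_rnas(genome_str: str, rules):
    """All (strand, prom_pos, d, first, last, length) transcripts.

    The transcript starts right after the promoter window and ends with the
    first downstream terminator window; transcripts of a full turn or more
    are rejected.
    """
    L = len(genome_str)
    tl = 2 * rules.stem_len + rules.loop_len
    plen = len(rules.consensus)
    out = []
    for strand, p, d in bf_promoters(genome_str, rules):
        seq = genome_str if strand is Strand.LEADING else revcomp(genome_str)
        ext = _ext(seq, max(tl, plen))
        first = (p + plen) % L
        for off in range(L):
            q = (first + off) % L
            if bf_is_terminator(ext, q, rules):
                length = off + tl
                if length < L:
                    out.append((strand, p, d, first, (first + length - 1) % L,
                                length))
                break
    return out


def bf_gray_to_int(bits: str) -> int:
    binary = []
    acc = 0
    for b in bits:
        acc ^= int(b)
        binary.append(str(acc))
    return int("".join(binary), 2)


def bf_cds_and_proteins(genome_str: str, rules):
    """All CDSs with decoded parameters, transcript by transcript.

    Returns two sets: cds entries (strand, init_pos, stop_pos, codon string)
    and protein entries (strand, init_pos, e, m, w, h).
    """
    L = len(genome_str)
    code = dict(rules.genetic_code)
    sd = rules.shine_dalgarno
    sig_len = len(sd) + rules.spacer_len + rules.codon_len
    cds_set = set()
    prot_set = set()
    for strand, p, d, first, last, length in bf_rnas(genome_str, rules):
        seq = genome_str if strand is Strand.LEADING else revcomp(genome_str)
        ext = _ext(seq, length + sig_len)
        transcript = "".join(ext[(first + j) % L] for j in range(length))
        for off in range(length - sig_len - rules.codon_len + 1):
            if transcript[off: off + len(sd)] != sd:
                continue
            if transcript[off + len(sd) + rules.spacer_len:
                          off + sig_len] != rules.start_codon:
                continue
            # translate codon by codon until the in-frame stop
            body = []
            j = off + sig_len
            stop_off = None
            while j + rules.codon_len <= length:
                codon = transcript[j: j + rules.codon_len]
                if codon == rules.stop_codon:
                    stop_off = j
                    break
                body.append(codon)
                j += rules.codon_len
            if stop_off is None:
                continue
            init_pos = (first + off) % L
            stop_pos = (first + stop_off) % L
            cds_set.add((strand, init_pos, stop_pos, "".join(body)))
            bits = {"M": "", "W": "", "H": ""}
            for codon in body:
                role = code[codon]
                if role in ("START", "STOP"):
                    continue
                bits[role[0]] += role[1]
            m = (bf_gray_to_int(bits["M"]) / (2 ** len(bits["M"]) - 1)
                 if bits["M"] else 0.0)
            w = (rules.w_max * (bf_gray_to_int(bits["W"])
                                / (2 ** len(bits["W"]) - 1))
                 if bits["W"] else 0.0)
            h = (2.0 * (bf_gray_to_int(bits["H"]) / (2 ** len(bits["H"]) - 1))
                 - 1.0 if bits["H"] else 0.0)
            e = 1.0 - d / (rules.d_max + 1)
            prot_set.add((strand, init_pos, e, m, w, h))
    return cds_set, prot_set


def grid_phenotype(activators, inhibitors, xs):
    """Dense-grid Lukasiewicz combination of (m, w, H) triangles."""
    import numpy as np

    def tri_sum(tris):
        total = np.zeros_like(xs)
        for (m, w, H) in tris:
            if w > 0 and H > 0:
                total += H * np.maximum(0.0, 1.0 - np.abs(xs - m) / w)
        return np.minimum(total, 1.0)

    return np.minimum(1.0, np.maximum(0.0, tri_sum(activators)
                                      - tri_sum(inhibitors)))
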