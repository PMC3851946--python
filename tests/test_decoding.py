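import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digevol import (
    DecodingRules,
    Genome,
    Strand,
    decode_genome,
    decode_protein,
    expression_level,
    find_coding_sequences,
    find_promoters,
    find_transcripts,
    gray_to_int,
    is_terminator,
    random_genome,
)
from digevol.decoding import CodingSequence, annotation_table, int_to_gray

from _reference import (
    bf_cds_and_proteins,
    bf_promoters,
    bf_rnas,
    bf_terminators,
    revcomp,
)

TERMINATOR = "01011110101"  # stem 0101 / loop 111 / stem 0101 (arms pair)

# The exact consensus contains stem-loop windows in its own interior, so a
# planted perfect promoter always drags terminators along.  This d=1
# variant (mismatch at position 11) embeds fold-free in an all-zero
# background on both strands, giving full control over terminator placement.
PROM_D1 = "0101011001100010010110"


def plant(background_len, *placements):
    """All-zero genome with (pos, bits) strings written in."""
    bits = ["0"] * background_len
    for pos, s in placements:
        for i, c in enumerate(s):
            bits[(pos + i) % background_len] = c
    return Genome("".join(bits))


def first_fold(genome_str, start):
    """Independent circular scan for the first stem-loop window >= start."""
    L = len(genome_str)
    ext = genome_str * 3
    for off in range(L):
        p = start + off
        win = ext[p: p + 11]
        if all(win[i] != win[10 - i] for i in range(4)):
            return (p % L, off)
    return None


class TestExpressionLevel:
    @pytest.mark.parametrize("d,d_max,expected",
                             [(0, 4, 1.0), (4, 4, 0.2), (2, 4, 0.6),
                              (1, 4, 0.8)])
    def test_printed_formula(self, d, d_max, expected):
        assert expression_level(d, d_max) == pytest.approx(expected)

    def test_rejects_non_promoter_distance(self):
        with pytest.raises(ValueError):
            expression_level(5, 4)


class TestGrayCode:
    @pytest.mark.parametrize("bits,value",
                             [("1", 1), ("0", 0), ("10", 3), ("11", 2),
                              ("110", 4), ("01", 1), ("111", 5)])
    def test_reflected_binary_decode(self, bits, value):
        assert gray_to_int(bits) == value

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            gray_to_int("")

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(1, 20), v=st.integers(0, 2 ** 20 - 1))
    def test_roundtrip_and_single_bit_steps(self, n, v):
        v %= 2 ** n
        assert gray_to_int(int_to_gray(v, n)) == v
        if v + 1 < 2 ** n:
            a, b = int_to_gray(v, n), int_to_gray(v + 1, n)
            assert sum(x != y for x, y in zip(a, b)) == 1


class TestTerminator:
    def test_valid_stem_loop(self, rules):
        assert is_terminator(Genome(TERMINATOR), Strand.LEADING, 0, rules)

    def test_broken_far_arm(self, rules):
        assert not is_terminator(Genome("01011110000"), Strand.LEADING, 0,
                                 rules)

    def test_outermost_pair_must_differ(self, rules, rng):
        # any window with symbol(pos) == symbol(pos+10) cannot fold
        for _ in range(20):
            win = rng.integers(0, 2, 11)
            win[10] = win[0]
            assert not is_terminator(Genome(win), Strand.LEADING, 0, rules)


class TestFindPromoters:
    def test_planted_exact_match(self, rules):
        g = plant(100, (7, rules.consensus))
        found = {(p.strand, p.pos, p.d, p.e) for p in find_promoters(g, rules)}
        assert (Strand.LEADING, 7, 0, 1.0) in {f[:4] for f in found} or \
               (Strand.LEADING, 7, 0, 1.0) in found

    def test_all_zero_genome_has_no_promoters(self, rules):
        # the consensus has 11 ones: d = 11 > 4 on both strands everywhere
        assert find_promoters(Genome("0" * 80), rules) == []
        assert rules.consensus.count("1") == 11

    def test_match_spanning_origin(self, rules):
        L = 100
        g = plant(L, (L - 10, rules.consensus))
        pos = {p.pos for p in find_promoters(g, rules)
               if p.strand is Strand.LEADING}
        assert L - 10 in pos

    def test_matches_brute_force_on_random_genomes(self, rules, rng):
        for _ in range(10):
            g = random_genome(int(rng.integers(30, 400)), rng)
            ours = {(p.strand, p.pos, p.d) for p in find_promoters(g, rules)}
            assert ours == set(bf_promoters(g.to_string(), rules))


class TestFindTranscripts:
    def test_single_transcript_extent(self, rules):
        g = plant(200, (10, PROM_D1), (60, TERMINATOR))
        q, off = first_fold(g.to_string(), 32)
        rnas = [r for r in find_transcripts(g, rules)
                if r.strand is Strand.LEADING and r.promoter.pos == 10]
        assert len(rnas) == 1
        rna = rnas[0]
        assert rna.first == 32
        assert rna.last == (q + 10) % 200
        assert rna.length == off + 11
        assert rna.e == 0.8  # one mismatch: e = 1 - 1/5

    def test_two_promoters_share_one_terminator(self, rules):
        g = plant(300, (10, PROM_D1), (50, PROM_D1), (120, TERMINATOR))
        q, _ = first_fold(g.to_string(), 32)
        assert q >= 72  # no fold before the second transcript start
        lead = [r for r in find_transcripts(g, rules)
                if r.strand is Strand.LEADING]
        assert len(lead) == 2
        assert {r.first for r in lead} == {32, 72}
        assert {r.last for r in lead} == {(q + 10) % 300}
        assert lead[0].length - lead[1].length == 40

    def test_promoter_without_terminator_yields_nothing(self, rules):
        g = plant(150, (10, PROM_D1))
        assert first_fold(g.to_string(), 0) is None
        assert find_transcripts(g, rules) == []

    def test_matches_brute_force_on_random_genomes(self, rules, rng):
        for _ in range(10):
            g = random_genome(int(rng.integers(50, 400)), rng)
            ours = {(r.strand, r.promoter.pos, r.promoter.d, r.first, r.last,
                     r.length) for r in find_transcripts(g, rules)}
            assert ours == set(bf_rnas(g.to_string(), rules))


def gene_block(spacer, codons):
    """Initiation signal + body codons + stop, as a bit string."""
    return "011011" + spacer + "000" + codons + "001"


class TestFindCodingSequences:
    def _decode_planted(self, codons, rules, spacer="1010"):
        g = plant(250, (10, rules.consensus),
                  (40, gene_block(spacer, codons)), (150, TERMINATOR))
        rnas = [r for r in find_transcripts(g, rules)
                if r.strand is Strand.LEADING]
        assert len(rnas) == 1
        return g, rnas[0]

    def test_w0_w1_gene(self, rules):
        g, rna = self._decode_planted("010" + "011", rules)
        cds = find_coding_sequences(g, rna, rules)
        assert len(cds) == 1
        assert cds[0].codons(rules) == ("W0", "W1")
        assert cds[0].init_pos == 40
        assert cds[0].start_codon_pos == 50
        assert cds[0].stop_codon_pos == 59

    def test_zero_codon_gene(self, rules):
        g, rna = self._decode_planted("", rules, spacer="0000")
        cds = find_coding_sequences(g, rna, rules)
        assert len(cds) == 1
        assert cds[0].codon_values == ()

    def test_no_in_frame_stop_means_no_protein(self, rules):
        # body codons 010... run straight into the terminator; neither the
        # body nor the in-frame terminator codons contain 001
        g = plant(250, (10, rules.consensus),
                  (40, "011011" + "0000" + "000" + "010" * 5),
                  (40 + 13 + 15, TERMINATOR))
        rnas = [r for r in find_transcripts(g, rules)
                if r.strand is Strand.LEADING]
        assert len(rnas) == 1
        assert find_coding_sequences(g, rnas[0], rules) == []

    def test_matches_brute_force_on_random_genomes(self, rules, rng):
        for _ in range(8):
            g = random_genome(int(rng.integers(100, 600)), rng)
            bf_cds, bf_prot = bf_cds_and_proteins(g.to_string(), rules)
            ours_cds = set()
            ours_prot = set()
            for rna, prot in decode_genome(g, rules):
                c = prot.cds
                codons = "".join(format(v, "03b") for v in c.codon_values)
                ours_cds.add((c.strand, c.init_pos, c.stop_codon_pos, codons))
                ours_prot.add((c.strand, c.init_pos, prot.e, prot.m, prot.w,
                               prot.h))
            assert ours_cds == bf_cds
            assert ours_prot == bf_prot


class TestDecodeProtein:
    def _cds(self, codon_values):
        return CodingSequence(Strand.LEADING, 0, 10, 16,
                              tuple(codon_values))

    def test_w_normalisation(self, rules):
        # W0 W1 -> Gray "01" -> raw 1 -> w = w_max * 1/3
        p = decode_protein(self._cds([0b010, 0b011]), 1.0, rules)
        assert p.w == rules.w_max * (1 / 3)
        assert p.n_w == 2 and p.n_m == 0 and p.n_h == 0

    def test_h_normalisation_and_height(self, rules):
        p = decode_protein(self._cds([0b111]), 0.5, rules)
        assert p.h == 1.0
        assert p.H == 0.5
        assert p.is_activator

    def test_degenerate_empty_gene(self, rules):
        p = decode_protein(self._cds([]), 1.0, rules)
        assert (p.m, p.w, p.h, p.H) == (0.0, 0.0, 0.0, 0.0)
        assert not p.functional

    def test_start_codons_in_body_are_silent(self, rules):
        a = decode_protein(self._cds([0b010, 0b000, 0b011]), 1.0, rules)
        b = decode_protein(self._cds([0b010, 0b011]), 1.0, rules)
        assert (a.m, a.w, a.h) == (b.m, b.w, b.h)

    def test_height_identity_everywhere(self, rules, rng):
        for _ in range(50):
            vals = rng.integers(0, 8, size=int(rng.integers(0, 12))).tolist()
            e = float(rng.uniform(0.2, 1.0))
            p = decode_protein(self._cds(vals), e, rules)
            assert p.H == e * abs(p.h)
            assert 0.0 <= p.m <= 1.0
            assert 0.0 <= p.w <= rules.w_max
            assert -1.0 <= p.h <= 1.0
            assert p.functional == (p.w > 0 and p.H > 0)


class TestDecodeGenome:
    def test_deterministic(self, rules, rng):
        g = random_genome(5000, rng)
        a = decode_genome(g, rules)
        b = decode_genome(g, rules)
        assert [(r.strand, r.first, p.m, p.w, p.h, p.e) for r, p in a] == \
               [(r.strand, r.first, p.m, p.w, p.h, p.e) for r, p in b]

    def test_all_zero_genome_is_silent(self, rules):
        assert decode_genome(Genome("0" * 500), rules) == []

    def test_strand_symmetry(self, rules, rng):
        for _ in range(5):
            g = random_genome(int(rng.integers(200, 800)), rng)
            fwd = decode_genome(g, rules)
            rev = decode_genome(g.reverse_complement(), rules)
            flip = {Strand.LEADING: Strand.LAGGING,
                    Strand.LAGGING: Strand.LEADING}

            def key(pairs, flipper):
                return sorted((flipper[p.cds.strand] if flipper else
                               p.cds.strand, p.e, p.m, p.w, p.h)
                              for _, p in pairs)

            assert key(fwd, None) == key(rev, flip)

    def test_rotation_covariance(self, rules, rng):
        g = random_genome(600, rng)
        L = len(g)
        r = 137
        rot = g.rotated(r)
        base = decode_genome(g, rules)
        moved = decode_genome(rot, rules)

        def positions(pairs):
            out = []
            for rna, p in pairs:
                # map strand-local positions back to the original frame
                if p.cds.strand is Strand.LEADING:
                    out.append((p.cds.strand, (p.cds.init_pos + r) % L,
                                p.m, p.w, p.h, p.e))
                else:
                    out.append((p.cds.strand, (p.cds.init_pos - r) % L,
                                p.m, p.w, p.h, p.e))
            return sorted(out)

        assert positions(moved) == sorted(
            (p.cds.strand, p.cds.init_pos, p.m, p.w, p.h, p.e)
            for _, p in base)

    def test_terminator_positions_match_brute_force(self, rules, rng):
        g = random_genome(300, rng)
        bf = set(bf_terminators(g.to_string(), rules))
        ours = {(s, p) for s in Strand for p in range(len(g))
                if is_terminator(g, s, p, rules)}
        assert ours == bf


class TestAnnotationTable:
    def test_feature_table_shape(self, rules):
        g = plant(250, (10, rules.consensus),
                  (40, gene_block("1010", "010011")), (150, TERMINATOR))
        table = annotation_table(g, rules)
        assert set(table["feature"]) == {"promoter", "RNA", "CDS"}
        cds_rows = table[table.feature == "CDS"]
        assert len(cds_rows) == 1
        assert bool(cds_rows.iloc[0]["functional"]) is False  # no H codon


class TestRulesValidation:
    def test_code_must_be_bijective(self):
        code = list(DecodingRules().genetic_code)
        code[2] = ("010", "W1")  # duplicate role, missing W0
        with pytest.raises(ValueError):
            DecodingRules(genetic_code=tuple(code))

    def test_d_max_bounds(self):
        with pytest.raises(ValueError):
            DecodingRules(d_max=22)
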