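"""Decode a hand-built genome and print its annotation.

Builds a small circular binary genome carrying one planted transcription
unit (promoter, one gene, stem-loop terminator), decodes it, and prints
the feature table plus the decoded protein parameters.
"""

import numpy as np

from digevol import DecodingRules, decode_genome
from digevol.decoding import annotation_table
from digevol.fixtures import CdsSpec, FixtureSpec, TranscriptSpec, compile_fixture

rules = DecodingRules()
rng = np.random.default_rng(42)

spec = FixtureSpec(transcripts=(TranscriptSpec(
    cds=(CdsSpec(m=0.52, w=0.004, h=0.9),),
    promoter_mismatches=1),))
genome, planted = compile_fixture(spec, 600, rng, rules)

print(f"genome: {len(genome)} bp (circular, binary)")
print(annotation_table(genome, rules).to_string(index=False))

for rna, protein in decode_genome(genome, rules):
    print(f"\ndecoded protein from RNA at {rna.promoter.pos} "
          f"({rna.strand.name}, e={protein.e}):")
    print(f"  m = {protein.m:.4f}   main cellular process (position in [0,1])")
    print(f"  w = {protein.w:.5f}  pleiotropy half-width (<= w_max = "
          f"{rules.w_max})")
    print(f"  h = {protein.h:+.4f}  efficiency; sign: activator if > 0")
    print(f"  H = e*|h| = {protein.H:.4f}  triangle height")
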