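# Methods

`digevol` is a forward-time simulator of bacterial genome evolution with
an explicit, sequence-level genotype-phenotype map. This note records the
model, the conventions the implementation fixes where the model leaves
freedom, the numerical choices, and what the desk-scale experiments do and
do not show.

## The organism

Each organism owns a single circular, double-stranded chromosome stored as
a string of binary nucleotides, 0 complementary to 1. Only one strand is
stored; reading the lagging strand returns complemented symbols in
reverse order. Positions are 0-based and all arithmetic is modulo the
genome length L. A segment `{p1, ..., p2}` is the inclusive clockwise run
from `p1` to `p2`, wrapping through the origin when `p1 > p2`; the origin
itself is a bookkeeping anchor with no biological meaning (decoding is
covariant under rotation of the stored origin, and tests check this).

### Transcription

Both strands are scanned for promoters: 22-bp windows within
`d_max = 4` mismatches of the consensus `0101011001110010010110`. A
promoter drives a transcript with expression level `e = 1 - d/(d_max+1)`,
so a perfect promoter gives e = 1.0 and the weakest one e = 0.2.
Terminators are 11-bp windows that could fold into a stem-loop: the outer
4 bases must pair (i.e. differ, in a binary alphabet) with the last 4 in
reverse; the 3 loop bases are free. A transcript runs from the first base
after the promoter window through the last base of the first downstream
terminator window. Two conventions are fixed here:

* the terminator search starts at the first post-promoter position, so a
  terminator may overlap the promoter's own window as long as it starts
  after it;
* a transcript must be shorter than one full turn of the chromosome; a
  promoter whose first terminator lies beyond that yields no RNA. (At
  realistic genome sizes terminators occur every ~16 bp on random
  sequence, so this cap is never reached in practice.)

Several promoters may share a terminator, giving overlapping transcripts;
each carries its own expression level.

### Translation and the genetic code

Inside a transcript, every occurrence of the initiation signal — the
Shine-Dalgarno-like motif `011011`, four free bases, then the start codon
`000` — opens a reading frame. Codons (3 bp) are read in frame until the
stop codon `001`; a frame with no in-frame stop inside the transcript
yields no protein. Operons and overlapping genes follow naturally.

A coding sequence interlaces the Gray codes of three protein parameters.
The genetic code used here assigns two codons per parameter, the last bit
being the next Gray bit:

| codon | role  | codon | role |
|-------|-------|-------|------|
| `000` | START | `100` | M0   |
| `001` | STOP  | `101` | M1   |
| `010` | W0    | `110` | H0   |
| `011` | W1    | `111` | H1   |

The W codons are the standard published pair; the M/H assignment above is
this implementation's choice (the full table is configurable in
`DecodingRules`). A START codon inside a gene body decodes to nothing.
Raw Gray integers are normalised to `m in [0, 1]` (the protein's main
cellular process), `w in [0, w_max]` with `w_max = 5e-3` (pleiotropy
half-width) and `h in [-1, 1]` (efficiency; the sign separates activators
from inhibitors). A parameter with zero codons of its role is 0, which
makes the protein non-functional through `w` or `H` without any 0/0
special case. A gene expressed from several promoters is decoded once per
hosting RNA, each copy contributing with that RNA's expression level —
the concentration effect of gene dosage.

## Phenotype, environment and selection

A protein is a triangular possibility distribution on the space
Omega = [0, 1] of abstract cellular processes: apex `m`, half-width `w`,
height `H = e*|h|`. Activators and inhibitors combine with the
Lukasiewicz bounded operators

    f_P(x) = min(1, max(0, min(sum_i f_i(x), 1) - min(sum_j f_j(x), 1))).

The implementation is exact: sums, clippings and differences are done on
piecewise-linear representations with crossing points inserted
analytically, and tests require agreement with a dense-grid evaluation to
1e-9.

The environmental target f_E is the clipped piecewise-linear sampling, at
`resolution = 1000` uniform intervals, of a sum of three Gaussians
(defaults: heights 1.2, -1.4, 0.3; means 0.52, 0.5, 0.8; widths 0.12,
0.07, 0.03 — chosen to give a plausible two-peaked target; all
configurable). The resolution is finer than the `w_max = 5e-3` triangle
support, so target and phenotype are resolved at comparable scales. Each
Gaussian mean fluctuates around its anchor by an AR(1) process

    dx(t+1) = dx(t) * (1 - 1/tau) + (sigma/tau) * sqrt(2*tau - 1) * eps(t)

with independent standard-normal innovations, `tau = 2500` generations
and `sigma = 5e-3`. The innovation scale makes the stationary standard
deviation exactly `sigma`, which is what "sigma controls the amplitude of
the fluctuations" requires; tests verify the stationary sd and the lag-1
autocorrelation `1 - 1/tau` against long simulated series.

Adaptation is the gap `g = integral over [0,1] of |f_E - f_P|`, computed
exactly on the merged breakpoint set. Reproduction weights are
`exp(-k*g)`; `k` sets the strength of selection (750 in the control
condition, 250 in the relaxed one). Offspring counts are one multinomial
draw with N trials over the normalised weights, so population size is
exactly constant and a fit individual can have several offspring. Within
a generation the order is fixed for reproducibility: the environment
steps first, everyone is re-evaluated against the new target, then
selection and reproduction happen.

## Replication and mutation

Seven event classes, each with a per-bp, per-replication rate (defaults:
point mutation, small insertion, small deletion at 5e-6; large deletion,
duplication, inversion, translocation at 5e-5). The four rearrangement
counts are drawn from Binomial(L, u) against the parental length,
shuffled and applied; then the three local counts are drawn against the
post-rearrangement length, shuffled and applied. Breakpoints are drawn
against the length current at each application. Conventions fixed here:

* small indel lengths are uniform on {1..6}; insertions are fresh uniform
  random bases;
* segments are clockwise-inclusive; inversion replaces a segment by its
  reverse complement (double-stranded inversion), so inverted genes stay
  readable on the other strand;
* a translocation excises the segment, re-ligates the remainder and
  re-inserts the segment in original orientation at a point drawn
  uniformly on the remainder (so every re-entry point is equally likely);
* events that would empty the genome (whole-genome deletion or
  translocation, oversized small deletion) are skipped and logged as
  skipped rather than redrawn — at the default rates such events are
  vanishingly rare, and skipping keeps per-event probabilities simple.

Every event records its positions and inserted sequence, so an event log
replays deterministically (`apply_event`); the lineage of the final best
individual replays from the founder genome to the final genome exactly,
and an acceptance test enforces this bit-for-bit over a 600-generation
population run.

## Initialisation

A run starts from a clonal population of N copies of a random founder.
Candidate founders are uniform random genomes of 5,000 bp, accepted when
they (a) decode to at least one functional protein (w > 0 and H > 0) and
(b) beat the empty phenotype against the initial target. Condition (b) —
the "one good gene" criterion — matters: a merely functional founder gene
can be an inhibitor with nothing to inhibit, leaving selection without a
foothold, in which case the population drifts and the genome decays.

## Randomness, backups, replay

One master seed spawns four named PCG64 streams (founder search,
environment, selection, mutation), consumed in a documented order. Runs
are bit-reproducible from (config, seed), independent of how often stats
or backups are written. Backups serialise the whole population plus
environment deviations and all stream states as JSON; resuming a backup
continues the original run exactly. A replay re-seeds the streams and may
override evolutionary parameters only (selection strength, mutation
rates, environment dynamics, run length); structural constants such as
the signal definitions are rejected because they would change the meaning
of the stored genomes.

## Architecture metrics

* A functional gene has w > 0 and H > 0; gene identity is (strand, start
  codon, stop codon), so multi-promoter expression does not inflate gene
  counts.
* Noncoding bases are stored positions covered by no transcription unit
  carrying a functional gene; a unit's span includes its promoter and
  terminator (configurable via `include_promoter`).
* Coding bases are the union of gene spans from the first base of the
  start codon through the last base of the stop codon; the initiation
  motif and spacer are regulatory, not coding. Under this convention a
  20-codon gene spans 66 bp, the same order as evolved average gene
  lengths.
* The mean functional CDS per RNA averages over RNAs with at least one
  functional CDS (the operon-size statistic); RNAs with none would dilute
  it toward 0.
* Equilibrium summaries average best-individual metrics over a trailing
  window of generations, then mean +/- sd across repetitions.
* The neutral-offspring fraction F_nu is estimated by Monte Carlo:
  replicate the individual n times through the full mutation pipeline and
  count offspring whose gap equals the parent's exactly. With a
  population context the expected offspring number W = N * p_i is
  reported alongside, enabling the F_nu * W diagnostic.

## Fixture compiler

`digevol.fixtures.compile_fixture` inverse-encodes requested (m, w, h)
values into codon sequences and plants whole transcription units on an
all-zero background (which contains no promoter or terminator windows).
Binary sequences fold easily — about one 11-bp window in 16 satisfies the
stem condition — so naively assembled genes almost always truncate their
own transcript. The compiler therefore repairs each unit until the
planted terminator is the first stem-loop after the promoter and no
spurious initiation signal hides in the transcript: a bad window
overlapping a gene body is cut by inserting a silent START codon, and one
overlapping free bits (the 4 spacer bases, the 3-bp inter-signal gaps) is
broken by re-drawing them. The compiled genome is then decoded and
compared against the recipe; compilation only returns genomes whose
decode matches the planted features exactly. Requested parameter values
are quantised to the Gray lattice of the requested codon counts;
unrepresentable requests (e.g. w > 0 with zero W codons) raise an error
naming the nearest representable value.

## Desk-scale experiments and their limits

The headline experiment relaxes selection mid-run: evolve at k = 750,
then continue the same backup at k = 750 (control) and k = 250 (relaxed)
with fresh random streams, and compare equilibrium genome architecture.
The package's test suite and acceptance script run this protocol at desk
scale — N = 100 instead of 1,000, phases of 400-500 generations instead
of 150,000, equilibrium windows of 120-150 generations — with everything
else at the reference parameter values. At this scale the directional effects
are clear and repeatable (relaxed selection loses genome size and
noncoding DNA and sheds weakly-contributing genes), and these directions
are what the tests assert. Phases much shorter than ~500 generations sit
mid-transient and the direction becomes seed-noisy, which is why the
window sizes are what they are. The quantitative equilibrium values are
NOT expected to match the full-scale study: populations of 100 drift
more, 500 generations is far from mutation-selection equilibrium, and
per-run variance across seeds is large. In particular, at N = 100 the
indirect selection for replication robustness is weak and some seeds
transiently bloat to hundreds of kilobases of mostly noncoding DNA
before shrinking again; the implementation is hardened (memory and time)
for exactly this regime. Scaling N or run lengths up recovers the full
protocol; nothing in the implementation is desk-scale-specific.

The synthetic-data side (random founders, compiled fixtures) emulates the
model's own universe, not real genome sequence: fixtures prove the
decoder and metrics correct by construction, and random genomes exercise
signal statistics, but neither says anything about real bacterial
sequence composition. Comparisons with real reduced genomes are outside
the package's scope.

## Known limitations

* The decoder re-scans a genome from scratch after each replication
  (no incremental update); cost is linear in L, which dominates run time
  for bloated genomes.
* The environmental target is a sampled piecewise-linear approximation of
  the Gaussian sum, not the exact curve; `resolution` controls the error.
* Backups are portable JSON but bit-exact continuation is guaranteed only
  on the same numpy/PCG64 build.
* No spatial structure, no plasmids, no regulation of expression by
  proteins, no sequence-similarity-guided breakpoints, no sexual
  recombination.
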