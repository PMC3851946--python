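"""Genome-architecture and phenotype metrics.

Conventions
-----------
* A *functional* gene is a decoded CDS with w > 0 and H > 0; gene identity
  is the triple (strand, start-codon position, stop-codon position), so a
  CDS expressed from several promoters counts once.
* The *coding* span of a gene runs from the first base of its start codon
  through the last base of its stop codon (the Shine-Dalgarno-like signal
  and spacer are regulatory, not coding).
* A base is *noncoding* iff it belongs to no transcription unit carrying at
  least one functional gene; by default a unit's span includes its 22-bp
  promoter and terminator window (configurable).
* The mean number of functional CDS per RNA averages over RNAs that carry
  at least one functional CDS (the operon-size statistic).

All metrics are pure functions of the decoded individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .mutation import mutate_genome
from .phenotype import compute_gap, phenotype_from_proteome

__all__ = [
    "count_functional_cds",
    "count_noncoding_bases",
    "coding_stats",
    "mean_cds_per_rna",
    "triangle_area_histogram",
    "equilibrium_estimates",
    "estimate_neutral_fraction",
    "generation_stats",
    "individual_metrics",
]


def _functional_genes(individual) -> Dict[Tuple, Tuple]:
    """Distinct functional genes keyed by (strand, start, stop)."""
    genes = {}
    for _, prot in individual.proteome:
        if prot.functional:
            cds = prot.cds
            genes[(cds.strand, cds.start_codon_pos, cds.stop_codon_pos)] = prot
    return genes


def count_functional_cds(individual) -> int:
    """Number of distinct genes with w > 0 and H > 0."""
    return len(_functional_genes(individual))


def _mark_span(mask: np.ndarray, strand, first: int, length: int) -> None:
    L = mask.size
    locs = (first + np.arange(length)) % L
    if strand.name == "LAGGING":
        locs = (L - 1 - locs) % L
    mask[locs] = True


def count_noncoding_bases(individual, include_promoter: bool = True,
                          rules=None) -> int:
    """Bases outside every RNA that carries at least one functional gene.

    Each stored position counts once however many functional transcription
    units cover it.  With ``include_promoter`` (default) a unit's span is
    the whole locus, promoter through terminator.
    """
    L = len(individual.genome)
    mask = np.zeros(L, dtype=bool)
    seen_rna = set()
    prom_len = rules.promoter_len if rules is not None else 22
    for rna, prot in individual.proteome:
        if not prot.functional:
            continue
        key = (rna.strand, rna.promoter.pos, rna.last)
        if key in seen_rna:
            continue
        seen_rna.add(key)
        if include_promoter:
            first = rna.promoter.pos
            length = min(prom_len + rna.length, L)
        else:
            first, length = rna.first, rna.length
        _mark_span(mask, rna.strand, first, length)
    return int(L - mask.sum())


def coding_stats(individual, rules=None
                 ) -> Tuple[int, float, float]:
    """(coding bases, coding fraction, mean gene length).

    Coding bases are the union of functional-gene spans projected onto the
    stored strand; the mean gene length averages span lengths over distinct
    functional genes (0 if there are none).
    """
    L = len(individual.genome)
    codon_len = rules.codon_len if rules is not None else 3
    genes = _functional_genes(individual)
    if not genes:
        return 0, 0.0, 0.0
    mask = np.zeros(L, dtype=bool)
    lengths = []
    for (strand, start, stop) in genes:
        length = (stop - start) % L + codon_len
        lengths.append(length)
        _mark_span(mask, strand, start, length)
    coding = int(mask.sum())
    return coding, coding / L, float(np.mean(lengths))


def mean_cds_per_rna(individual) -> float:
    """Mean functional-CDS count over RNAs carrying >= 1 functional CDS."""
    per_rna: Dict[Tuple, set] = {}
    for rna, prot in individual.proteome:
        if not prot.functional:
            continue
        key = (rna.strand, rna.promoter.pos, rna.last)
        cds = prot.cds
        per_rna.setdefault(key, set()).add(
            (cds.strand, cds.start_codon_pos, cds.stop_codon_pos))
    if not per_rna:
        return 0.0
    return float(np.mean([len(s) for s in per_rna.values()]))


def count_rnas(individual, rules=None) -> int:
    """Number of transcripts of the genome.

    With ``rules`` the genome is re-scanned so that RNAs carrying no CDS
    are counted too; without, only protein-bearing RNAs are visible.
    """
    if rules is not None:
        from .decoding import find_transcripts
        return len(find_transcripts(individual.genome, rules))
    return len({(rna.strand, rna.promoter.pos, rna.last)
                for rna, _ in individual.proteome})


def triangle_area_histogram(individuals, bin_edges: Optional[Sequence[float]] = None
                            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of functional-gene triangle areas H*w.

    The area of a gene's triangle (``0.5 * 2w * H``) is a proxy for its
    phenotypic impact.  Returns (bin edges, per-individual count matrix,
    mean counts across individuals).  Default bins are geometric on
    [1e-6, 1e-2].
    """
    if not isinstance(individuals, (list, tuple)):
        individuals = [individuals]
    if bin_edges is None:
        bin_edges = np.geomspace(1e-6, 1e-2, 21)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts = []
    for ind in individuals:
        areas = [p.H * p.w for p in _functional_genes(ind).values()]
        c, _ = np.histogram(areas, bins=bin_edges)
        counts.append(c)
    counts = np.asarray(counts)
    return bin_edges, counts, counts.mean(axis=0)


def individual_metrics(individual, rules=None) -> Dict[str, float]:
    """All per-individual architecture metrics as one flat record."""
    L = len(individual.genome)
    coding, coding_frac, mean_len = coding_stats(individual, rules)
    return {
        "gap": individual.gap,
        "genome_size": L,
        "rna_count": count_rnas(individual, rules),
        "total_cds": len({(p.cds.strand, p.cds.start_codon_pos,
                           p.cds.stop_codon_pos)
                          for _, p in individual.proteome}),
        "functional_cds": count_functional_cds(individual),
        "noncoding_bases": count_noncoding_bases(individual, rules=rules),
        "coding_bases": coding,
        "coding_fraction": coding_frac,
        "mean_gene_length": mean_len,
        "mean_cds_per_rna": mean_cds_per_rna(individual),
    }


def generation_stats(pop) -> Dict[str, float]:
    """One stats row: generation index, best and population-mean metrics."""
    best = pop.best()
    rules = pop.config.rules
    m = individual_metrics(best, rules)
    gaps = pop.gaps()
    sizes = np.array([len(ind.genome) for ind in pop.individuals])
    return {
        "t": pop.t,
        "best_gap": m["gap"],
        "mean_gap": float(gaps.mean()),
        "best_genome_size": m["genome_size"],
        "mean_genome_size": float(sizes.mean()),
        "best_functional_cds": m["functional_cds"],
        "best_rna_count": m["rna_count"],
        "best_noncoding_bases": m["noncoding_bases"],
        "best_coding_bases": m["coding_bases"],
        "best_coding_fraction": m["coding_fraction"],
        "best_mean_cds_per_rna": m["mean_cds_per_rna"],
    }


def equilibrium_estimates(stats_frames, window: int,
                          columns: Optional[Sequence[str]] = None):
    """Time-averaged best-individual metrics over each run's final window.

    ``stats_frames`` is one stats DataFrame or a list of them (one per
    repetition); ``window`` is in generations.  Returns a DataFrame with
    one row per run plus, as attrs, the cross-run mean and sd.
    """
    import pandas as pd

    if not isinstance(stats_frames, (list, tuple)):
        stats_frames = [stats_frames]
    rows = []
    for i, df in enumerate(stats_frames):
        t_max = df["t"].max()
        span = t_max - df["t"].min()
        if span < window - 1 and len(df) > 1:
            raise ValueError(
                f"run {i}: series covers {span + 1} generations "
                f"< window {window}")
        sel = df[df["t"] > t_max - window]
        cols = columns or [c for c in df.columns if c != "t"]
        rows.append({c: float(sel[c].mean()) for c in cols})
    per_run = pd.DataFrame(rows)
    per_run.attrs["mean"] = per_run.mean(axis=0)
    per_run.attrs["sd"] = per_run.std(axis=0, ddof=1)
    return per_run


@dataclass(frozen=True)
class NeutralFractionEstimate:
    """Monte-Carlo estimate of the neutral-offspring fraction F_nu."""

    estimate: float
    stderr: float
    n_replicates: int
    expected_offspring: Optional[float] = None  # W, when a population is given

    @property
    def f_nu_times_w(self) -> Optional[float]:
        if self.expected_offspring is None:
            return None
        return self.estimate * self.expected_offspring


def estimate_neutral_fraction(individual, config, rng,
                              n_replicates: int = 1000,
                              population=None) -> NeutralFractionEstimate:
    """Fraction of offspring with no mutation or only neutral ones.

    ``n_replicates`` mutated copies of the individual are generated; an
    offspring is neutral when its gap against the current target equals the
    parent's exactly (either no event applied, or the events left the
    phenotype unchanged).  When ``population`` is supplied, the expected
    offspring number W = N * exp(-k*g) / sum_i exp(-k*g_i) is reported too,
    enabling the F_nu * W ~= 1 diagnostic.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .decoding import decode_genome
    from .evolution import reproduction_probabilities

    target = (population.env_state.target if population is not None
              else None)
    if target is None:
        from .phenotype import initial_environment
        target = initial_environment(config.env).target
    parent_gap = compute_gap(individual.phenotype, target)
    neutral = 0
    for _ in range(n_replicates):
        child_genome, events = mutate_genome(individual.genome, config.rates,
                                             rng)
        if child_genome is individual.genome:
            neutral += 1
            continue
        proteome = decode_genome(child_genome, config.rules)
        child_gap = compute_gap(phenotype_from_proteome(proteome), target)
        if child_gap == parent_gap:
            neutral += 1
    f = neutral / n_replicates
    stderr = math.sqrt(f * (1.0 - f) / n_replicates)
    w = None
    if population is not None:
        probs = reproduction_probabilities(population.gaps(),
                                           config.selection_k)
        w = float(population.size * probs[individual.index])
    return NeutralFractionEstimate(estimate=f, stderr=stderr,
                                   n_replicates=n_replicates,
                                   expected_offspring=w)
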