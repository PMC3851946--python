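import numpy as np
import pandas as pd
import pytest

from digevol import SimulationConfig, Genome
from digevol.evolution import Individual, make_initial_population
from digevol.fixtures import CdsSpec, FixtureSpec, TranscriptSpec, compile_fixture
from digevol.mutation import MutationRates
from digevol.stats import (
    coding_stats,
    count_functional_cds,
    count_noncoding_bases,
    count_rnas,
    equilibrium_estimates,
    estimate_neutral_fraction,
    generation_stats,
    individual_metrics,
    mean_cds_per_rna,
    triangle_area_histogram,
)


def make_individual(genome, rules):
    return Individual.from_genome(genome, rules, index=0)


@pytest.fixture
def two_gene_individual(rules, rng):
    spec = FixtureSpec(transcripts=(
        TranscriptSpec(cds=(CdsSpec(m=0.3, w=0.004, h=0.8),)),
        TranscriptSpec(cds=(CdsSpec(m=0.7, w=0.002, h=0.6),)),
    ))
    genome, _ = compile_fixture(spec, 1000, rng, rules)
    return make_individual(genome, rules)


@pytest.fixture
def operon_individual(rules, rng):
    spec = FixtureSpec(transcripts=(TranscriptSpec(cds=(
        CdsSpec(m=0.2, w=0.003, h=0.5),
        CdsSpec(m=0.6, w=0.004, h=-0.7))),))
    genome, _ = compile_fixture(spec, 900, rng, rules)
    return make_individual(genome, rules)


class TestFunctionalCdsCount:
    def test_two_planted_genes(self, two_gene_individual):
        assert count_functional_cds(two_gene_individual) == 2

    def test_silent_genome(self, rules):
        ind = make_individual(Genome("0" * 400), rules)
        assert count_functional_cds(ind) == 0

    def test_founder_has_at_least_one(self):
        pop = make_initial_population(SimulationConfig(population_size=2,
                                                       seed=11))
        assert count_functional_cds(pop.individuals[0]) >= 1


class TestNoncodingBases:
    def test_silent_genome_is_all_noncoding(self, rules):
        ind = make_individual(Genome("0" * 400), rules)
        assert count_noncoding_bases(ind, rules=rules) == 400

    def test_functional_locus_spans_promoter_through_terminator(
            self, rules, rng):
        spec = FixtureSpec(transcripts=(TranscriptSpec(
            cds=(CdsSpec(m=0.5, w=0.004, h=1.0),)),))
        genome, planted = compile_fixture(spec, 1000, rng, rules)
        ind = make_individual(genome, rules)
        (strand, first, last), = planted.rnas
        rna_len = last - first + 1
        expected = 1000 - (22 + rna_len)  # promoter included in the locus
        assert count_noncoding_bases(ind, rules=rules) == expected
        assert count_noncoding_bases(ind, include_promoter=False,
                                     rules=rules) == 1000 - rna_len

    def test_noncoding_plus_functional_cover_is_genome(self, rules,
                                                       two_gene_individual):
        ind = two_gene_individual
        L = len(ind.genome)
        nc = count_noncoding_bases(ind, rules=rules)
        covered = set()
        for rna, prot in ind.proteome:
            if prot.functional:
                start = rna.promoter.pos
                for j in range(22 + rna.length):
                    p = (start + j) % L
                    covered.add(p if rna.strand.name == "LEADING"
                                else (L - 1 - p) % L)
        assert nc == L - len(covered)


class TestCodingStats:
    def test_gene_span_start_through_stop(self, rules, rng):
        # 20 body codons -> 3 + 60 + 3 = 66 bp from start through stop codon
        spec = FixtureSpec(transcripts=(TranscriptSpec(
            cds=(CdsSpec(m=0.5, w=0.004, h=1.0, n_m=10, n_w=5, n_h=5),)),))
        genome, _ = compile_fixture(spec, 800, rng, rules)
        ind = make_individual(genome, rules)
        coding, frac, mean_len = coding_stats(ind, rules)
        n_body = len(ind.proteome[0][1].cds.codon_values)
        assert mean_len == 3 + 3 * n_body + 3
        assert coding == mean_len  # single gene: union equals the span
        assert frac == coding / 800

    def test_two_disjoint_genes_double_coding_bases(self, rules,
                                                    two_gene_individual):
        ind = two_gene_individual
        coding, _, mean_len = coding_stats(ind, rules)
        spans = [3 + 3 * len(p.cds.codon_values) + 3
                 for _, p in ind.proteome]
        assert coding == sum(spans)
        assert mean_len == pytest.approx(np.mean(spans))

    def test_no_genes_reports_zeros(self, rules):
        ind = make_individual(Genome("0" * 300), rules)
        assert coding_stats(ind, rules) == (0, 0.0, 0.0)


class TestMeanCdsPerRna:
    def test_operon_counts_two(self, operon_individual):
        assert mean_cds_per_rna(operon_individual) == 2.0

    def test_single_gene_transcripts_count_one(self, two_gene_individual):
        assert mean_cds_per_rna(two_gene_individual) == 1.0

    def test_empty_individual_reports_zero(self, rules):
        ind = make_individual(Genome("0" * 200), rules)
        assert mean_cds_per_rna(ind) == 0.0


class TestAreaHistogram:
    def test_counts_conserve_functional_genes(self, two_gene_individual):
        edges, counts, mean = triangle_area_histogram(two_gene_individual)
        assert counts.sum() == count_functional_cds(two_gene_individual)
        assert np.array_equal(mean, counts[0])

    def test_explicit_gene_area(self, rules, rng):
        spec = FixtureSpec(transcripts=(TranscriptSpec(
            cds=(CdsSpec(m=0.5, w=0.005, h=0.8, n_w=4, n_h=5),)),))
        genome, planted = compile_fixture(spec, 800, rng, rules)
        ind = make_individual(genome, rules)
        prot = ind.proteome[0][1]
        area = prot.H * prot.w
        edges, counts, _ = triangle_area_histogram(
            ind, bin_edges=[area * 0.9, area * 1.1])
        assert counts[0][0] == 1

    def test_across_individuals_mean(self, rules, two_gene_individual,
                                     operon_individual):
        edges, counts, mean = triangle_area_histogram(
            [two_gene_individual, operon_individual])
        assert counts.shape[0] == 2
        assert np.allclose(mean, counts.mean(axis=0))


class TestEquilibriumEstimates:
    def test_constant_series(self):
        df = pd.DataFrame({"t": range(100), "best_genome_size": [42] * 100})
        per_run = equilibrium_estimates(df, window=10)
        assert per_run.loc[0, "best_genome_size"] == 42

    def test_window_average(self):
        df = pd.DataFrame({"t": [0, 1], "best_genome_size": [10, 20]})
        per_run = equilibrium_estimates(df, window=2)
        assert per_run.loc[0, "best_genome_size"] == 15

    def test_cross_run_mean_and_sd(self):
        frames = [pd.DataFrame({"t": range(10), "x": [v] * 10})
                  for v in (1.0, 3.0)]
        per_run = equilibrium_estimates(frames, window=5)
        assert per_run.attrs["mean"]["x"] == 2.0
        assert per_run.attrs["sd"]["x"] == pytest.approx(np.sqrt(2.0))

    def test_window_longer_than_series_errors(self):
        df = pd.DataFrame({"t": range(5), "x": range(5)})
        with pytest.raises(ValueError):
            equilibrium_estimates(df, window=50)


class TestNeutralFraction:
    def test_no_mutation_is_fully_neutral(self, rng):
        cfg = SimulationConfig(population_size=2, seed=11,
                               rates=MutationRates.zero())
        pop = make_initial_population(cfg)
        est = estimate_neutral_fraction(pop.individuals[0], cfg, rng,
                                        n_replicates=50)
        assert est.estimate == 1.0
        assert est.stderr == 0.0

    def test_heavy_mutation_lowers_neutrality(self, rng):
        rates = MutationRates(point=5e-3, small_ins=5e-3, small_del=5e-3,
                              large_del=5e-4, duplication=5e-4,
                              inversion=5e-4, translocation=5e-4)
        cfg = SimulationConfig(population_size=2, seed=11, rates=rates)
        pop = make_initial_population(cfg)
        est = estimate_neutral_fraction(pop.individuals[0], cfg, rng,
                                        n_replicates=60)
        assert est.estimate < 1.0
        assert est.stderr == pytest.approx(
            np.sqrt(est.estimate * (1 - est.estimate) / 60))

    def test_population_context_reports_w(self, rng):
        cfg = SimulationConfig(population_size=5, seed=11,
                               rates=MutationRates.zero())
        pop = make_initial_population(cfg)
        est = estimate_neutral_fraction(pop.individuals[0], cfg, rng,
                                        n_replicates=10, population=pop)
        # clonal population: W = 1 for everyone, so F_nu * W = 1
        assert est.expected_offspring == pytest.approx(1.0)
        assert est.f_nu_times_w == pytest.approx(1.0)


class TestGenerationStats:
    def test_row_contents(self):
        pop = make_initial_population(SimulationConfig(population_size=4,
                                                       seed=11))
        row = generation_stats(pop)
        assert row["t"] == 0
        assert row["best_genome_size"] == 5000
        assert row["best_gap"] == pop.best().gap
        assert row["mean_genome_size"] == 5000.0
        assert row["best_functional_cds"] >= 1
        assert row["best_rna_count"] >= 1

    def test_metrics_are_pure(self, two_gene_individual, rules):
        a = individual_metrics(two_gene_individual, rules)
        b = individual_metrics(two_gene_individual, rules)
        assert a == b

    def test_rna_count_includes_cds_free_rnas(self, rules, rng):
        pop = make_initial_population(SimulationConfig(population_size=2,
                                                       seed=11))
        ind = pop.individuals[0]
        assert count_rnas(ind, rules) >= count_rnas(ind)
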