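"""Generational population loop, fossil-record backups and lineages.

Each generation: the environmental target takes one fluctuation step, all
individuals are (re-)evaluated against it, reproduction probabilities
``exp(-k*g_i) / sum_j exp(-k*g_j)`` are computed, offspring counts are
drawn from a multinomial with N trials, and each offspring is an
independently mutated copy of its parent.  The population size N is
constant and the parental generation dies entirely.

Randomness comes from one master seed spawning four named streams
(founder search, environment, selection, mutation), so a replay can renew
the streams without touching stored genome semantics.  Backups serialise
the whole population plus environment and RNG states as JSON; loading a
backup and continuing with the stored streams reproduces the original run
bit for bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import SimulationConfig, apply_overrides, config_from_dict, config_to_dict
from .decoding import decode_genome
from .genome import Genome, random_genome
from .mutation import MutationEvent, mutate_genome
from .phenotype import (
    EnvironmentState,
    PiecewiseLinearFunction,
    build_target,
    compute_gap,
    initial_environment,
    phenotype_from_proteome,
    step_environment,
)

__all__ = [
    "Individual",
    "Population",
    "Lineage",
    "RunResult",
    "make_initial_population",
    "reproduction_probabilities",
    "draw_offspring_counts",
    "advance_generation",
    "run_simulation",
    "continue_run",
    "save_backup",
    "load_backup",
    "replay_from_backup",
    "reconstruct_lineage",
    "replay_lineage",
]

BACKUP_FORMAT_VERSION = 1
_STREAM_NAMES = ("init", "env", "selection", "mutation")


class Individual:
    """One organism: genome, decoded proteome, phenotype and gap."""

    __slots__ = ("genome", "proteome", "phenotype", "gap", "index",
                 "parent_index")

    def __init__(self, genome: Genome, proteome, phenotype, index: int,
                 parent_index: Optional[int] = None):
        self.genome = genome
        self.proteome = proteome
        self.phenotype = phenotype
        self.gap: float = float("nan")
        self.index = index
        self.parent_index = parent_index

    @classmethod
    def from_genome(cls, genome: Genome, rules, index: int,
                    parent_index: Optional[int] = None) -> "Individual":
        proteome = decode_genome(genome, rules)
        return cls(genome, proteome, phenotype_from_proteome(proteome),
                   index, parent_index)


@dataclass
class Lineage:
    """Per-generation parent->child maps with every mutation event.

    ``records[t][child] = (parent_index, events)`` describes how child
    ``child`` of generation ``t+1`` arose from generation ``t``.
    """

    founder_genome: Optional[Genome]
    records: List[List[Tuple[int, Tuple[MutationEvent, ...]]]] = field(
        default_factory=list)

    def append_generation(self, entries) -> None:
        self.records.append(entries)


def _spawn_streams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.Generator(np.random.PCG64(ss))
            for name, ss in zip(_STREAM_NAMES, children)}


class Population:
    """The evolving population plus environment and RNG state."""

    def __init__(self, config: SimulationConfig,
                 individuals: List[Individual],
                 env_state: EnvironmentState,
                 rngs: Dict[str, np.random.Generator],
                 t: int = 0,
                 lineage: Optional[Lineage] = None):
        self.config = config
        self.individuals = individuals
        self.env_state = env_state
        self.rngs = rngs
        self.t = t
        self.lineage = lineage

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def target(self) -> PiecewiseLinearFunction:
        return self.env_state.target

    def gaps(self) -> np.ndarray:
        return np.array([ind.gap for ind in self.individuals])

    def best(self) -> Individual:
        """Minimum-gap individual; ties broken by lowest index."""
        return min(self.individuals, key=lambda ind: (ind.gap, ind.index))

    def evaluate(self) -> None:
        """Recompute every gap against the current target.

        Identical phenotype objects (clones) are evaluated once.
        """
        cache: Dict[int, float] = {}
        target = self.env_state.target
        for ind in self.individuals:
            key = id(ind.phenotype)
            g = cache.get(key)
            if g is None:
                g = compute_gap(ind.phenotype, target)
                cache[key] = g
            ind.gap = g


def make_initial_population(config: SimulationConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> Population:
    """Clonal population founded on a random genome with >= 1 good gene.

    Uniform random genomes of the configured initial length are drawn until
    one decodes to at least one functional protein AND its phenotype beats
    the empty phenotype against the initial target (the "one good gene"
    initialisation).  Requiring a strictly beneficial gene matters: a merely
    functional gene can be an inhibitor with nothing to inhibit, leaving the
    population with no selective foothold.  The population is N copies of
    the accepted founder.
    """
    rngs = _spawn_streams(config.seed)
    founder_rng = rng if rng is not None else rngs["init"]
    target0 = initial_environment(config.env).target
    empty_gap = target0.integral()  # gap of the zero phenotype
    founder = None
    proteome = None
    phenotype = None
    for _ in range(config.init_max_attempts):
        candidate = random_genome(config.initial_genome_length, founder_rng)
        prot = decode_genome(candidate, config.rules)
        if not any(p.functional for _, p in prot):
            continue
        phen = phenotype_from_proteome(prot)
        if compute_gap(phen, target0) < empty_gap:
            founder, proteome, phenotype = candidate, prot, phen
            break
    if founder is None:
        raise RuntimeError(
            f"no suitable founder found in {config.init_max_attempts} draws")
    individuals = [Individual(founder, proteome, phenotype, index=i,
                              parent_index=None)
                   for i in range(config.population_size)]
    env_state = initial_environment(config.env)
    lineage = Lineage(founder_genome=founder) if config.record_lineage else None
    pop = Population(config, individuals, env_state, rngs, t=0,
                     lineage=lineage)
    pop.evaluate()
    return pop


def reproduction_probabilities(gaps: Sequence[float], k: float) -> np.ndarray:
    """Normalised selection weights exp(-k*g_i) / sum_j exp(-k*g_j).

    Computed with a max-shift so that ratios stay exact for k*g up to 1e4.
    """
    g = np.asarray(gaps, dtype=np.float64)
    if g.size < 1:
        raise ValueError("need at least one individual")
    w = np.exp(-k * (g - g.min()))
    p = w / w.sum()
    return p / p.sum()  # renormalise to sum exactly 1 (one ulp guard)


def draw_offspring_counts(probabilities: np.ndarray, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Multinomial(N, p) offspring counts; always sums to N."""
    p = np.asarray(probabilities, dtype=np.float64)
    return rng.multinomial(n, p / p.sum())


def advance_generation(pop: Population) -> Population:
    """One full generation step, in place; returns the population.

    Order: environment fluctuates, everyone is re-evaluated, reproduction
    probabilities are drawn with the current k, offspring counts come from
    one multinomial draw, and each offspring replicates its parent's genome
    with independent mutations.  Offspring without applied mutations share
    the parent's decoded state (no re-decoding).
    """
    cfg = pop.config
    pop.env_state = step_environment(pop.env_state, cfg.env, pop.rngs["env"])
    pop.evaluate()
    probs = reproduction_probabilities(pop.gaps(), cfg.selection_k)
    counts = draw_offspring_counts(probs, pop.size, pop.rngs["selection"])

    mut_rng = pop.rngs["mutation"]
    children: List[Individual] = []
    lineage_entries = [] if pop.lineage is not None else None
    target = pop.env_state.target
    gap_cache: Dict[int, float] = {}
    idx = 0
    for parent, n_off in zip(pop.individuals, counts.tolist()):
        for _ in range(n_off):
            genome, events = mutate_genome(parent.genome, cfg.rates, mut_rng)
            if genome is parent.genome:  # no applied event: exact copy
                child = Individual(parent.genome, parent.proteome,
                                   parent.phenotype, idx, parent.index)
            else:
                child = Individual.from_genome(genome, cfg.rules, idx,
                                               parent.index)
            key = id(child.phenotype)
            g = gap_cache.get(key)
            if g is None:
                g = compute_gap(child.phenotype, target)
                gap_cache[key] = g
            child.gap = g
            if lineage_entries is not None:
                lineage_entries.append((parent.index, tuple(events)))
            children.append(child)
            idx += 1
    pop.individuals = children
    pop.t += 1
    if pop.lineage is not None:
        pop.lineage.append_generation(lineage_entries)
    return pop


# -- backups (fossil record) -------------------------------------------------


def save_backup(pop: Population, path) -> None:
    """Serialise population, environment and RNG states as JSON."""
    doc = {
        "format_version": BACKUP_FORMAT_VERSION,
        "t": pop.t,
        "config": config_to_dict(pop.config),
        "genomes": [ind.genome.to_string() for ind in pop.individuals],
        "parent_indices": [ind.parent_index for ind in pop.individuals],
        "env_deviations": pop.env_state.deviations.tolist(),
        "rng_states": {name: g.bit_generator.state
                       for name, g in pop.rngs.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_backup(path) -> Population:
    """Rebuild a population from a backup; decoded state is recomputed."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != BACKUP_FORMAT_VERSION:
        raise ValueError(f"unsupported backup format: "
                         f"{doc.get('format_version')!r}")
    cfg = config_from_dict(doc["config"])
    rngs = _spawn_streams(cfg.seed)
    for name, state in doc["rng_states"].items():
        rngs[name].bit_generator.state = state
    individuals = []
    cache: Dict[str, Individual] = {}
    for i, (s, pidx) in enumerate(zip(doc["genomes"],
                                      doc["parent_indices"])):
        proto = cache.get(s)
        if proto is None:
            proto = Individual.from_genome(Genome(s), cfg.rules, i, pidx)
            cache[s] = proto
            ind = proto
        else:
            ind = Individual(proto.genome, proto.proteome, proto.phenotype,
                             i, pidx)
        ind.index, ind.parent_index = i, pidx
        individuals.append(ind)
    dev = np.asarray(doc["env_deviations"], dtype=np.float64)
    base = np.array([g[1] for g in cfg.env.gaussians])
    env_state = EnvironmentState(deviations=dev,
                                 target=build_target(cfg.env, base + dev))
    pop = Population(cfg, individuals, env_state, rngs, t=doc["t"])
    pop.evaluate()
    return pop


def replay_from_backup(backup: Union[str, os.PathLike, Population],
                       overrides: Optional[Dict[str, str]] = None,
                       new_seed: Optional[int] = None) -> Population:
    """Population ready to continue evolution from a stored state.

    ``overrides`` may change evolutionary parameters only (selection
    strength, mutation rates, environment dynamics, run length); structural
    constants are rejected because they would invalidate the stored
    genomes' semantics.  With ``new_seed`` the RNG streams are re-spawned,
    giving an alternative history from the same starting point.
    """
    pop = backup if isinstance(backup, Population) else load_backup(backup)
    cfg = pop.config
    if overrides:
        cfg = apply_overrides(cfg, overrides, restrict_to_evolutionary=True)
    if new_seed is not None:
        from dataclasses import replace as _replace
        cfg = _replace(cfg, seed=new_seed)
        pop.rngs = _spawn_streams(new_seed)
    pop.config = cfg
    if pop.config.record_lineage and pop.lineage is None:
        # Lineage rooted mid-run: the "founder" of the recorded segment is
        # whichever backup individual the reconstructed path starts from.
        pop.lineage = Lineage(founder_genome=None)
    pop.evaluate()
    return pop


# -- run driver ---------------------------------------------------------------


@dataclass
class RunResult:
    population: Population
    stats: "object"  # pandas.DataFrame
    lineage: Optional[Lineage]


def continue_run(pop: Population, generations: int,
                 outdir: Optional[Union[str, os.PathLike]] = None,
                 progress: bool = False) -> RunResult:
    """Advance an existing population, recording stats/backups/lineage."""
    import pandas as pd

    from .stats import generation_stats

    cfg = pop.config
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "backups"), exist_ok=True)
        from .config import save_config
        save_config(cfg, os.path.join(outdir, "config.txt"))
    lineage_fh = None
    if outdir is not None and cfg.record_lineage:
        lineage_fh = open(os.path.join(outdir, "lineage.jsonl"), "a")
        if pop.t == 0 and pop.lineage is not None:
            lineage_fh.write(json.dumps(
                {"founder": pop.lineage.founder_genome.to_string()}) + "\n")
    rows = [generation_stats(pop)]
    try:
        for step in range(generations):
            advance_generation(pop)
            if pop.lineage is not None and lineage_fh is not None:
                entries = pop.lineage.records[-1]
                lineage_fh.write(json.dumps({
                    "t": pop.t,
                    "entries": [[p, [e.to_record() for e in evs]]
                                for p, evs in entries],
                }) + "\n")
            if pop.t % cfg.stats_period == 0:
                rows.append(generation_stats(pop))
            if (outdir is not None and cfg.backup_period
                    and pop.t % cfg.backup_period == 0):
                save_backup(pop, os.path.join(
                    outdir, "backups", f"backup_t{pop.t}.json"))
            if progress and (step + 1) % 200 == 0:
                print(f"generation {pop.t}: best gap "
                      f"{pop.best().gap:.4f}, best size "
                      f"{len(pop.best().genome)}")
    finally:
        if lineage_fh is not None:
            lineage_fh.close()
    stats = pd.DataFrame(rows)
    if outdir is not None:
        stats_path = os.path.join(outdir, "stats.tsv")
        header = not os.path.exists(stats_path)
        stats.iloc[1 if not header else 0:].to_csv(
            stats_path, sep="\t", index=False, mode="a", header=header)
    return RunResult(population=pop, stats=stats, lineage=pop.lineage)


def run_simulation(config: SimulationConfig,
                   outdir: Optional[Union[str, os.PathLike]] = None,
                   progress: bool = False) -> RunResult:
    """Create a founder population and evolve it for the configured length."""
    pop = make_initial_population(config)
    if outdir is not None and config.backup_period:
        os.makedirs(os.path.join(outdir, "backups"), exist_ok=True)
        save_backup(pop, os.path.join(outdir, "backups", "backup_t0.json"))
    return continue_run(pop, config.generations, outdir=outdir,
                        progress=progress)


# -- line of descent ----------------------------------------------------------


def _load_lineage_file(path) -> Lineage:
    founder = None
    records = []
    with open(path) as fh:
        for line in fh:
            doc = json.loads(line)
            if "founder" in doc:
                founder = Genome(doc["founder"])
            else:
                records.append([
                    (p, tuple(MutationEvent.from_record(r) for r in evs))
                    for p, evs in doc["entries"]])
    if founder is None:
        raise ValueError(f"{path}: missing founder record")
    return Lineage(founder_genome=founder, records=records)


def reconstruct_lineage(lineage: Union[Lineage, str, os.PathLike],
                        final_index: int
                        ) -> List[Tuple[int, Tuple[MutationEvent, ...]]]:
    """Ancestor path of one final individual, generation 0 upward.

    Returns one (ancestor index, events) entry per elapsed generation; the
    events are those that turned the ancestor into its child on the path.
    """
    if not isinstance(lineage, Lineage):
        lineage = _load_lineage_file(lineage)
    path: List[Tuple[int, Tuple[MutationEvent, ...]]] = []
    child = final_index
    for t in range(len(lineage.records) - 1, -1, -1):
        entries = lineage.records[t]
        if child >= len(entries):
            raise ValueError(f"lineage gap at generation {t + 1}: "
                             f"no record for individual {child}")
        parent, events = entries[child]
        path.append((parent, events))
        child = parent
    path.reverse()
    return path


def replay_lineage(founder: Genome,
                   path: List[Tuple[int, Tuple[MutationEvent, ...]]]
                   ) -> Genome:
    """Re-apply every recorded event along a line of descent."""
    from .mutation import apply_event

    genome = founder
    for _, events in path:
        for ev in events:
            genome = apply_event(genome, ev)
    return genome
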