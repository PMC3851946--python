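"""Two-phase experiment: relax selection mid-run and compare architectures.

Phase 1 evolves a population under strong selection (k = 750) and saves a
backup.  The backup is then continued twice with fresh random streams:
a control at k = 750 and a scenario at k = 250.  Relaxed selection
streamlines the genome, mostly by shedding noncoding DNA.  Desk-scale
sizes (N = 100, 500-generation phases); expect a few minutes.
"""

import tempfile
from pathlib import Path

from digevol import SimulationConfig
from digevol.evolution import (
    advance_generation,
    make_initial_population,
    replay_from_backup,
    save_backup,
)
from digevol.stats import individual_metrics

PHASE1, PHASE2 = 500, 500

cfg = SimulationConfig(population_size=100, seed=11)
pop = make_initial_population(cfg)
for _ in range(PHASE1):
    advance_generation(pop)
backup = Path(tempfile.mkdtemp()) / "backup.json"
save_backup(pop, backup)
print(f"phase 1 done: t={pop.t}, best genome {len(pop.best().genome)} bp")

for label, overrides in (("control  k=750", None),
                         ("scenario k=250", {"selection_k": "250"})):
    arm = replay_from_backup(backup, overrides=overrides, new_seed=99)
    for _ in range(PHASE2):
        advance_generation(arm)
    m = individual_metrics(arm.best(), arm.config.rules)
    print(f"{label}: best genome {m['genome_size']} bp, "
          f"{m['functional_cds']} functional genes, "
          f"{m['noncoding_bases']} noncoding bp, "
          f"coding {100 * m['coding_fraction']:.1f}%")
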