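"""Candidate discovery: consensus DARs -> marker genes -> scored report.

Simulates two differential-accessibility tables with a planted consensus,
keeps the regions confirmed with the same direction by both callers,
annotates the up-regulated ones to their nearest gene and retains those
whose gene belongs to the simulated endothelial marker list, then attaches
placeholder ensemble scores and prints the Table-style summary.
"""

import numpy as np

from ecre import (
    attach_scores,
    consensus_dars,
    map_to_markers,
    select_opened,
    summarize_candidates,
)
from ecre.simulate import (
    SimulationConfig,
    make_genome,
    simulate_annotation,
    simulate_dar_tables,
    simulate_enhancers,
)

sim = SimulationConfig(seed=13, n_chrom=1, chrom_length=8_000_000, n_pos=150,
                       n_dar=120, n_genes=400, marker_fraction=0.3)
genome = make_genome(sim)
enhancers = simulate_enhancers(sim, genome)
primary, confirming, truth_ids = simulate_dar_tables(sim, genome)
ann = simulate_annotation(sim, genome, enhancers)

consensus = consensus_dars(primary, confirming)
print(f"Primary DARs: {len(primary)}; confirmed by the second caller: "
      f"{len(consensus)} (planted truth: {len(truth_ids)})")

opened = select_opened(consensus, "up")
print(f"Opened (up) consensus DARs: {len(opened)}")

candidates = map_to_markers(opened, list(ann.genes), ann.markers, list(ann.degs))
print(f"Candidates whose nearest gene is a marker: {len(candidates)}")

# stand-in scores: a real run would use ensemble_predict on the candidates
rng = np.random.default_rng(13)
scores = {c.region.id: float(rng.beta(2, 2)) for c in candidates}
scored = attach_scores(candidates, scores)
summary = summarize_candidates(scored, tau=0.5)
print(f"Above 0.5: {summary['n_above']} of {summary['n_total']} "
      f"({summary['pct_above']}%)")
if scored:
    c = scored[0]
    print(f"Top candidate: {c.region.id} -> {c.gene} at {c.distance_to_tss} bp "
          f"({c.location}), score {c.score:.3f}")
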