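"""Train the lasso-logistic ensemble on a small synthetic world.

Plants 80 enhancers on a 4 Mb chromosome, simulates 4 informative and 2
noise peak tracks plus one coverage track, trains the ensemble with
freshly shuffled matched negatives in each repeat, and scores the planted
enhancers themselves.  With strong track signal the per-repeat test
accuracies approach 1 and every planted enhancer scores near 1.
"""

from ecre import RegionSet, TrackLibrary, TrainConfig, ensemble_predict
from ecre.simulate import (
    SimulationConfig,
    make_genome,
    simulate_coverage,
    simulate_enhancers,
    simulate_tracks,
)

sim = SimulationConfig(
    seed=7, n_chrom=1, chrom_length=4_000_000, n_pos=80,
    n_informative=4, n_noise=2, p_fg=0.9, p_bg=0.05,
)
genome = make_genome(sim)
enhancers = simulate_enhancers(sim, genome)
peaks, truths = simulate_tracks(sim, genome, enhancers)
library = TrackLibrary(peaks, {"cov": simulate_coverage(sim, genome, enhancers, "cov")})

cfg = TrainConfig(seed=7, repeats=5, cv_folds=5, n_lambda=50)
ens = ensemble_predict(
    pos=enhancers, tracks=library, genome=genome,
    excl=RegionSet(), queries=enhancers, cfg=cfg,
)

print("Per-repeat test accuracy:", [round(float(a), 3) for a in ens.test_accuracies])
print("Selected lambda per repeat:", [f"{l:.2e}" for l in ens.lambdas])
df = ens.to_frame()
print(f"\nEnhancer calls among planted queries: {int(df.is_enhancer.sum())} / {len(df)}")
print(df.head(5)[["region_id", "mean_score", "is_enhancer"]].to_string(index=False))
print("\n(mean_score is the average probability over the 5 repeats; a region")
print(" is called an enhancer when it exceeds the 0.5 threshold strictly)")
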