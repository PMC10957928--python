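"""Summarise the packaged candidate regulatory-element tables.

Loads the 101 scored candidate REs (opened chromatin regions mapped to
endothelial marker genes) and the 6 curated REs of major endothelial
genes, then applies the strict 0.5 ensemble-score threshold.
"""

from ecre import classify, load_table2_candidates, load_table3_scores, summarize_candidates

candidates = load_table2_candidates()
summary = summarize_candidates(candidates, tau=0.5)
print("Candidate REs:", summary["n_total"])
print("Scored > 0.5 (likely enhancers):", summary["n_above"])
print(
    f"Of those, literature-supported: {summary['n_above_with_ref']} "
    f"({summary['pct_ref_of_above']}%)"
)

top = candidates[0]
print(f"\nTop candidate: {top.region.id} near {top.gene} "
      f"(score {top.score:.3f}, {top.location}, gene log2FC {top.gene_log2fc})")

t3 = load_table3_scores()
calls = [classify(s, 0.5) for s in t3.prediction_score]
print(f"\nCurated REs called enhancers at 0.5: {sum(calls)} of {len(calls)}")
for gene, score, call in zip(t3.gene, t3.prediction_score, calls):
    print(f"  {gene:8s} score {score:.4f} -> {'enhancer' if call else 'below threshold'}")
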