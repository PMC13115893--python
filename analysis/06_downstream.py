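#!/usr/bin/env python
"""Stage 6: gene-level downstream analysis of the biomarker panel.

Maps panel CpGs to genes, classifies their effector status, runs
hypergeometric over-representation analysis, and ranks interaction-
network hubs by the composite degree/betweenness score.
"""

import argparse
from pathlib import Path

import numpy as np

from oamethyl.cohort import (
    generate_gene_sets,
    generate_interaction_network,
    write_edge_list,
)
from oamethyl.io import read_annotation
from oamethyl.network import (
    classify_effector_status,
    composite_node_score,
    hypergeometric_ora,
    load_edge_list,
    map_cpg_to_genes,
)
from oamethyl.pipeline import stage_seed

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-hubs", type=int, default=3)
args = parser.parse_args()
out = args.dir

annotation = read_annotation(out / "annotation.csv")
panel = (out / "panel.txt").read_text().split()
effectors = (out / "effector_genes.txt").read_text().split()
all_genes = sorted(set(annotation.links["gene"]))

genes, unmapped = map_cpg_to_genes(panel, annotation)
print(f"panel maps to {len(genes)} genes ({len(unmapped)} probes unmapped)")

rng = np.random.default_rng(stage_seed(args.seed, "effector-db"))
non_eff = [g for g in all_genes if g not in set(effectors)]
db_reported = list(rng.choice(non_eff, size=max(1, len(non_eff) // 5),
                              replace=False))
n_val, n_db, n_novel = classify_effector_status(genes, effectors, db_reported)
print(f"effector status: {n_val} validated, {n_db} database-reported, "
      f"{n_novel} novel candidates")

collection, enriched, _ = generate_gene_sets(
    all_genes, n_sets=40, enriched_fraction=0.1,
    seed=stage_seed(args.seed, "gene-sets"), query_genes=effectors)
collection.write_gmt(out / "gene_sets.gmt")
ora = hypergeometric_ora(genes, collection, all_genes)
ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
hits = [s for s in ora.head(len(enriched))["set_name"] if s in set(enriched)]
print(f"enrichment: min adj_p {ora['adj_p'].min():.3g}; "
      f"{len(hits)}/{len(enriched)} planted sets in the top {len(enriched)}")

net_genes = genes if len(genes) >= 4 * args.n_hubs + 3 else all_genes
net, hubs = generate_interaction_network(
    net_genes, args.n_hubs, seed=stage_seed(args.seed, "network"))
write_edge_list(net, out / "edge_list.tsv")
graph = load_edge_list(out / "edge_list.tsv", min_score=500)
scores = composite_node_score(graph)
scores.to_csv(out / "node_scores.tsv", sep="\t", index=False)
top = list(scores["node"].head(args.n_hubs))
print(f"network: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges (score >= 500)")
print(f"top-{args.n_hubs} composite hubs: {top}; planted hubs: {hubs}; "
      f"recovery {len(set(top) & set(hubs)) / len(hubs):.2f}")
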