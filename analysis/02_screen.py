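#!/usr/bin/env python
"""Stage 2: dual-strategy CpG screening.

Welch t-tests with BH adjustment build the statistical T-pool; TSS
windows around the effector genes build the annotation G-pool.
"""

import argparse
from pathlib import Path

from oamethyl.io import read_annotation, read_beta_matrix
from oamethyl.screening import (
    differential_methylation,
    select_g_pool,
    select_t_pool,
    significant_sites,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--t-pool-k", type=int, default=500)
parser.add_argument("--window-bp", type=int, default=2000)
args = parser.parse_args()
out = args.dir

matrix = read_beta_matrix(out / "beta_matrix.tsv", out / "sample_sheet.tsv")
annotation = read_annotation(out / "annotation.csv")
effectors = (out / "effector_genes.txt").read_text().split()

dm = differential_methylation(matrix)
dm.to_csv(out / "dm_table.tsv", sep="\t")
sig = significant_sites(dm)
print(f"{len(sig)} sites pass adj_p<0.05 and |delta_beta|>0.2")

t_pool = select_t_pool(dm, k=min(args.t_pool_k, len(dm)))
g_pool = select_g_pool(annotation, effectors, window_bp=args.window_bp)
g_ids = [c for c in g_pool.cpg_ids if c in set(matrix.cpg_ids)]
print(f"T-pool: {len(t_pool.cpg_ids)} probes; G-pool: {len(g_ids)} probes")

planted = set((out / "planted_dm_sites.txt").read_text().split())
recovered = len(set(t_pool.cpg_ids[:len(planted)]) & planted)
print(f"planted recovery in top-{len(planted)} of T-pool: "
      f"{recovered}/{len(planted)}")

(out / "t_pool.txt").write_text("\n".join(t_pool.cpg_ids) + "\n")
(out / "g_pool.txt").write_text("\n".join(g_ids) + "\n")
(out / "significant_sites.txt").write_text("\n".join(sorted(sig)) + "\n")
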