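#!/usr/bin/env python
"""Stage 1: simulate the synthetic cohort and harmonize its batches.

Writes the harmonized beta matrix, sample sheet, probe annotation, and
the planted ground truth under results/analysis/.
"""

import argparse
from pathlib import Path

from oamethyl.cohort import SimulationConfig, generate_cohort
from oamethyl.io import (
    BetaMatrix,
    harmonize_datasets,
    write_annotation,
    write_beta_matrix,
    write_sample_sheet,
)
from oamethyl.pipeline import stage_seed

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
out = args.out
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=stage_seed(args.seed, "simulate"))
raw, annotation, truth = generate_cohort(config)
print(f"simulated {raw.n_cpg} CpGs x {raw.n_samples} samples "
      f"({int(sum(raw.labels))} cases), {len(truth.dm_cpg_ids)} planted DM")

# split back into per-batch datasets, then harmonize as separate cohorts
datasets = []
for b in sorted(set(raw.batch)):
    cols = [i for i, bb in enumerate(raw.batch) if bb == b]
    datasets.append(BetaMatrix(
        cpg_ids=list(raw.cpg_ids),
        sample_ids=[raw.sample_ids[i] for i in cols],
        values=raw.values[:, cols],
        labels=raw.labels[cols],
        batch=[raw.batch[i] for i in cols],
        joint=[raw.joint[i] for i in cols] if raw.joint else None))
matrix = harmonize_datasets(datasets, annotation)
print(f"harmonized to {matrix.n_cpg} CpGs x {matrix.n_samples} samples")

write_beta_matrix(matrix, out / "beta_matrix.tsv")
write_sample_sheet(matrix, out / "sample_sheet.tsv")
write_annotation(annotation, out / "annotation.csv")
(out / "effector_genes.txt").write_text("\n".join(truth.effector_genes) + "\n")
(out / "planted_dm_sites.txt").write_text("\n".join(truth.dm_cpg_ids) + "\n")
print(f"artifacts written to {out}/")
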