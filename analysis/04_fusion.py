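#!/usr/bin/env python
"""Stage 4: train the gated Transformer-CNN fusion classifier.

Compares the three feature sets under identical splits and runs the
fusion-mode ablation (gated vs. concat vs. single branches).
"""

import argparse
from pathlib import Path

import pandas as pd

from oamethyl.fusion import FusionModelConfig, ablation_compare
from oamethyl.io import read_beta_matrix
from oamethyl.pipeline import compare_feature_sets, stage_seed

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()
out = args.dir

matrix = read_beta_matrix(out / "beta_matrix.tsv", out / "sample_sheet.tsv")
X, y = matrix.values.T, matrix.labels
sets = {tag: (out / f"{t}_sites.txt").read_text().split()
        for t, tag in (("t", "T-sites"), ("g", "G-sites"), ("u", "U-sites"))}

config = FusionModelConfig(
    d_model=32, cnn_out=32, fusion_dim=32, n_heads=4, n_layers=1,
    ff_dim=64, kernel_sizes=(7, 3), cnn_channels=(16,),
    max_epochs=40, patience=10, seed=stage_seed(args.seed, "fusion"))

comparison = compare_feature_sets(sets, X, y, matrix.cpg_ids, config)
comparison.to_csv(out / "feature_set_comparison.tsv", sep="\t", index=False)
print(comparison[["feature_set", "n_features", "test_acc", "test_auc",
                  "test_f1"]].to_string(index=False))

col = {c: i for i, c in enumerate(matrix.cpg_ids)}
Xu = X[:, [col[c] for c in sets["U-sites"]]]
ablation = ablation_compare(Xu, y, config)
rows = [{"mode": mode, "val_acc": m.acc, "val_auc": m.auc, "val_f1": m.f1}
        for mode, m in ablation.items()]
pd.DataFrame(rows).to_csv(out / "ablation.tsv", sep="\t", index=False)
for row in rows:
    print(f"{row['mode']:>12}: ACC {row['val_acc']:.3f}  "
          f"AUC {row['val_auc']:.3f}")
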