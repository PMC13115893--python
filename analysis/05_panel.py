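#!/usr/bin/env python
"""Stage 5: gradient-saliency biomarker panel selection.

Trains the fusion model on the U-sites, ranks features by gradient
importance, sweeps nested panel sizes, and reports the gate statistics
and panel provenance.
"""

import argparse
from pathlib import Path

from oamethyl.fusion import FusionModelConfig, gate_contribution, train_model
from oamethyl.io import read_beta_matrix
from oamethyl.panel import importance_ranking, panel_provenance, panel_sweep
from oamethyl.pipeline import stage_seed
from oamethyl.selection import FeatureSet

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--grid", type=int, nargs="+", default=[40, 60, 80, 100])
args = parser.parse_args()
out = args.dir

matrix = read_beta_matrix(out / "beta_matrix.tsv", out / "sample_sheet.tsv")
col = {c: i for i, c in enumerate(matrix.cpg_ids)}
u_ids = (out / "u_sites.txt").read_text().split()
t_sites = FeatureSet("T-sites", set((out / "t_sites.txt").read_text().split()))
g_sites = FeatureSet("G-sites", set((out / "g_sites.txt").read_text().split()))
Xu, y = matrix.values.T[:, [col[c] for c in u_ids]], matrix.labels

config = FusionModelConfig(
    d_model=32, cnn_out=32, fusion_dim=32, n_heads=4, n_layers=1,
    ff_dim=64, kernel_sizes=(7, 3), cnn_channels=(16,),
    max_epochs=40, patience=10, seed=stage_seed(args.seed, "fusion"))
model, _ = train_model(Xu, y, config)

gate = gate_contribution(model, Xu)
print(f"gate weights: transformer {gate.mean_transformer_weight:.3f}, "
      f"CNN {gate.mean_cnn_weight:.3f}")

ranked = importance_ranking(model, Xu, u_ids)
grid = [s for s in args.grid if s <= len(u_ids)] or [len(u_ids)]
sweep = panel_sweep(ranked, Xu, y, u_ids, config, size_grid=grid)
sweep.curve().to_csv(out / "panel_sweep.tsv", sep="\t", index=False)
print(sweep.curve().to_string(index=False))
print(f"best panel size: {sweep.best_size}")

prov = panel_provenance(sweep.panel_cpg_ids, t_sites, g_sites)
print(f"panel provenance: {prov.n_from_t} from T ({prov.pct_from_t}%), "
      f"{prov.n_from_g} from G ({prov.pct_from_g}%)")
(out / "panel.txt").write_text("\n".join(sweep.panel_cpg_ids) + "\n")
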