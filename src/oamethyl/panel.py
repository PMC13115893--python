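"""Biomarker panel selection by saliency ranking and subset-size sweep.

The integrated U-sites features are ranked by mean absolute gradient of
the trained fusion model's positive-class logit with respect to each
input beta value; nested prefix subsets over a size grid (default
100..320) are each retrained and validated, and the size with the best
mean validation accuracy (smaller on ties) becomes the biomarker panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import FusionModelConfig, TransCNN, evaluate, gradient_importance, train_model
from .selection import FeatureSet

DEFAULT_SIZE_GRID = (100, 120, 150, 180, 200, 220, 250, 280, 300, 320)


@dataclass
class PanelSweepResult:
    size_grid: list[int]
    mean_acc_per_size: list[float]
    best_size: int
    panel_cpg_ids: list[str]

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.size_grid,
                             "mean_val_acc": self.mean_acc_per_size})


@dataclass
class PanelProvenance:
    n_from_t: int
    n_from_g: int
    pct_from_t: float
    pct_from_g: float
    overlap_policy: str = "assign-to-G"


def importance_ranking(model: TransCNN, X: np.ndarray,
                       feature_ids) -> list[str]:
    """Features in descending mean-|gradient| order, id tie-break."""
    imp = gradient_importance(model, X)
    feature_ids = list(feature_ids)
    order = sorted(range(len(feature_ids)),
                   key=lambda i: (-imp[i], feature_ids[i]))
    return [feature_ids[i] for i in order]


def panel_sweep(ranked_ids, X, y, feature_ids,
                config: FusionModelConfig,
                size_grid=DEFAULT_SIZE_GRID,
                n_repeats: int = 1) -> PanelSweepResult:
    """Retrain the fusion model on each nested prefix subset and pick the
    size with the highest mean validation accuracy (ties -> smaller)."""
    size_grid = sorted(set(int(s) for s in size_grid))
    if max(size_grid) > len(ranked_ids):
        raise ValueError("size grid exceeds the ranking length")
    col = {f: i for i, f in enumerate(feature_ids)}
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    mean_accs = []
    for k in size_grid:
        cols = [col[f] for f in ranked_ids[:k]]
        accs = []
        for rep in range(n_repeats):
            cfg = FusionModelConfig(**{**config.__dict__,
                                       "seed": config.seed + rep})
            model, history = train_model(X[:, cols], y, cfg)
            accs.append(history["best_val_acc"])
        mean_accs.append(float(np.mean(accs)))
    best_idx = int(np.lexsort((size_grid, -np.asarray(mean_accs)))[0])
    best_size = size_grid[best_idx]
    return PanelSweepResult(
        size_grid=list(size_grid), mean_acc_per_size=mean_accs,
        best_size=best_size, panel_cpg_ids=list(ranked_ids[:best_size]),
    )


def panel_provenance(panel, t_sites: FeatureSet, g_sites: FeatureSet,
                     overlap_policy: str = "assign-to-G") -> PanelProvenance:
    """Attribute each panel probe to its originating selection strategy.

    Probes present in both consensus sets are credited to the
    annotation-driven side (assign-to-G); percentages are rounded to one
    decimal with the T share taken as the complement so the pair sums to
    100 exactly.
    """
    panel = list(panel)
    t, g = t_sites.cpg_ids, g_sites.cpg_ids
    outside = [p for p in panel if p not in t and p not in g]
    if outside:
        raise ValueError(f"panel probes outside both source sets: {outside[:5]}")
    if overlap_policy == "assign-to-G":
        n_g = sum(1 for p in panel if p in g)
    elif overlap_policy == "assign-to-T":
        n_g = sum(1 for p in panel if p in g and p not in t)
    else:
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    n_t = len(panel) - n_g
    pct_g = round(100.0 * n_g / len(panel), 1)
    pct_t = round(100.0 - pct_g, 1)
    return PanelProvenance(n_from_t=n_t, n_from_g=n_g,
                           pct_from_t=pct_t, pct_from_g=pct_g,
                           overlap_policy=overlap_policy)
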