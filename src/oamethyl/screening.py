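"""Dual-strategy preliminary CpG screening.

Two complementary pools of candidate CpGs feed the downstream feature
selection:

* **T-pool** — statistical: per-probe Welch t-test between cases and
  controls with Benjamini-Hochberg FDR adjustment and the group mean
  beta difference Δβ = mean(case) − mean(control); the top-k probes
  (default 5000) ranked by (adj. p ascending, |Δβ| descending).
* **G-pool** — annotation-driven: probes within ±``window_bp`` (default
  2000, closed interval) of the transcription start site of any listed
  effector gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, CpGAnnotation

DEFAULT_TOP_K = 5000
DEFAULT_WINDOW_BP = 2000
DEFAULT_P_THRESH = 0.05
DEFAULT_DELTA_THRESH = 0.2


@dataclass
class FeaturePool:
    pool_tag: str  # "T" or "G"
    cpg_ids: list[str]
    provenance: pd.DataFrame

    def __post_init__(self):
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("pool contains duplicate probes")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    adj_p(i) = min over j with p_(j) >= p_(i) of p_(j) * n / j, capped at
    1; the output preserves the input order and dominates the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def differential_methylation(matrix: BetaMatrix) -> pd.DataFrame:
    """Per-probe Welch t-test (two-sided), BH adjustment, and Δβ.

    Returns a DataFrame indexed by cpg_id with columns t_stat, p_value,
    adj_p, delta_beta, direction (hyper iff Δβ > 0).  Degenerate probes
    with zero variance in both groups and equal means get t = 0, p = 1.
    """
    labels = matrix.labels
    if np.sum(labels == 1) < 2 or np.sum(labels == 0) < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    cases = matrix.values[:, labels == 1]
    controls = matrix.values[:, labels == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(cases, controls, axis=1,
                                          equal_var=False)
    delta = cases.mean(axis=1) - controls.mean(axis=1)
    # zero-variance probes: identical distributions -> no evidence
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)
    adj_p = benjamini_hochberg(p_value)
    return pd.DataFrame({
        "t_stat": t_stat,
        "p_value": p_value,
        "adj_p": adj_p,
        "delta_beta": delta,
        "direction": np.where(delta > 0, "hyper", "hypo"),
    }, index=pd.Index(matrix.cpg_ids, name="cpg_id"))


def select_t_pool(dm: pd.DataFrame, k: int = DEFAULT_TOP_K) -> FeaturePool:
    """Top-k probes by (adj_p asc, |Δβ| desc, cpg_id asc)."""
    if k > len(dm):
        raise ValueError(f"k={k} exceeds the {len(dm)} tested probes")
    ranked = dm.assign(abs_delta=dm["delta_beta"].abs())
    ranked = ranked.sort_values(
        ["adj_p", "abs_delta", "cpg_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).head(k)
    prov = ranked[["adj_p", "abs_delta"]].reset_index()
    prov.insert(1, "rank", np.arange(1, k + 1))
    return FeaturePool("T", list(ranked.index), prov)


def significant_sites(dm: pd.DataFrame,
                      p_thresh: float = DEFAULT_P_THRESH,
                      delta_thresh: float = DEFAULT_DELTA_THRESH) -> set[str]:
    """Probes meeting both significance criteria, strict inequalities:
    adj_p < p_thresh and |Δβ| > delta_thresh."""
    if p_thresh <= 0 or delta_thresh <= 0:
        raise ValueError("thresholds must be positive")
    mask = (dm["adj_p"] < p_thresh) & (dm["delta_beta"].abs() > delta_thresh)
    return set(dm.index[mask])


def select_g_pool(annotation: CpGAnnotation, effector_genes,
                  window_bp: int = DEFAULT_WINDOW_BP) -> FeaturePool:
    """Probes within the closed ±window_bp interval of any effector TSS.

    Provenance records each qualifying (gene, signed distance) pair; a
    probe qualifying through several genes appears in the pool once.
    """
    if len(annotation.probes) == 0:
        raise ValueError("annotation is empty")
    effectors = set(effector_genes)
    if not effectors:
        warnings.warn("empty effector gene list: G-pool is empty")
        return FeaturePool("G", [], pd.DataFrame(
            columns=["cpg_id", "gene", "distance"]))
    links = annotation.links[annotation.links["gene"].isin(effectors)]
    pos = annotation.probes.set_index("cpg_id")["pos"]
    dist = pos.loc[links["cpg_id"]].to_numpy() - links["tss_pos"].to_numpy()
    hits = links.assign(distance=dist)
    hits = hits[np.abs(hits["distance"]) <= window_bp]
    prov = hits[["cpg_id", "gene", "distance"]].reset_index(drop=True)
    cpg_ids = list(dict.fromkeys(prov["cpg_id"]))  # first-hit order, unique
    return FeaturePool("G", cpg_ids, prov)
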