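"""End-to-end orchestration of the methylation gene-discovery framework.

``run_pipeline`` executes, on a self-contained synthetic cohort (or
user-supplied files), the full chain: simulate -> harmonize -> dual
screening -> consensus feature selection -> fusion-model training and
feature-set comparison -> saliency panel sweep -> gene mapping and
effector classification -> over-representation testing -> interaction
network hub scoring.  Every stage's seed derives deterministically from
the global seed, and the resulting ``RunReport`` carries the sizes,
metrics, and a fingerprint that is identical across repeat runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    SimulationConfig,
    generate_cohort,
    generate_gene_sets,
    generate_interaction_network,
    write_edge_list,
)
from .fusion import FusionModelConfig, evaluate, gate_contribution, train_model
from .io import BetaMatrix, harmonize_datasets, write_beta_matrix, write_sample_sheet, write_annotation
from .network import (
    classify_effector_status,
    composite_node_score,
    hypergeometric_ora,
    load_edge_list,
    map_cpg_to_genes,
)
from .panel import importance_ranking, panel_provenance, panel_sweep
from .screening import (
    differential_methylation,
    select_g_pool,
    select_t_pool,
    significant_sites,
)
from .selection import (
    consensus_sites,
    cv_subset_selection,
    rf_importance_ranking,
    svm_rfe_ranking,
    union_sites,
)

log = logging.getLogger("oamethyl.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """One document controlling every stage (JSON round-trippable)."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # desk-scale fusion model for the self-contained demo cohort; the
    # FusionModelConfig class defaults keep the full 64-dim architecture
    fusion: FusionModelConfig = field(default_factory=lambda: FusionModelConfig(
        d_model=32, cnn_out=32, fusion_dim=32, n_heads=4, n_layers=1,
        ff_dim=64, kernel_sizes=(7, 3), cnn_channels=(16,),
        max_epochs=40, patience=10))
    t_pool_k: int = 500
    window_bp: int = 2000
    p_thresh: float = 0.05
    delta_thresh: float = 0.2
    selection_grid: tuple[int, ...] = (60, 120, 200)
    cv_folds: int = 5
    rf_trees: int = 200
    elim_fraction: float = 0.2
    sweep_grid: tuple[int, ...] = (40, 60, 80, 100)
    compare_repeats: int = 2
    min_score: int = 500
    w_degree: float = 0.5
    w_between: float = 0.5
    top_k_nodes: int = 20
    n_hubs: int = 3
    n_gene_sets: int = 40
    enriched_fraction: float = 0.1
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["sim"] = SimulationConfig(**raw.get("sim", {}))
        fus = raw.get("fusion", {})
        for key in ("kernel_sizes", "cnn_channels"):
            if key in fus:
                fus[key] = tuple(fus[key])
        raw["fusion"] = FusionModelConfig(**fus)
        for key in ("selection_grid", "sweep_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _metrics_row(tag: str, n_features: int, val_stats: dict,
                 test_metrics) -> dict:
    return {
        "feature_set": tag, "n_features": n_features,
        **{f"val_{k}_mean": float(np.mean(v)) for k, v in val_stats.items()},
        **{f"val_{k}_std": float(np.std(v)) for k, v in val_stats.items()},
        "test_acc": test_metrics.acc, "test_f1": test_metrics.f1,
        "test_auc": test_metrics.auc,
    }


def compare_feature_sets(feature_sets: dict[str, list[str]],
                         X: np.ndarray, y: np.ndarray, feature_ids,
                         config: FusionModelConfig,
                         n_repeats: int = 2) -> pd.DataFrame:
    """Train the fusion model on each feature set under identical splits
    and seeds; mean +/- std of validation metrics over repeats plus a
    single held-out test evaluation per set."""
    from sklearn.model_selection import train_test_split

    col = {f: i for i, f in enumerate(feature_ids)}
    rows = []
    for tag, features in feature_sets.items():
        if not features:
            log.warning("feature set %s is empty; skipped", tag)
            continue
        cols = [col[f] for f in features]
        Xs = X[:, cols]
        X_tv, X_test, y_tv, y_test = train_test_split(
            Xs, y, test_size=0.2, stratify=y,
            random_state=config.seed % (2**32))
        val_stats: dict[str, list[float]] = {"acc": [], "f1": [], "auc": []}
        final_model = None
        for rep in range(n_repeats):
            cfg = FusionModelConfig(**{**config.__dict__,
                                       "seed": config.seed + rep,
                                       "val_fraction": 0.25})
            model, _ = train_model(X_tv, y_tv, cfg)
            from sklearn.model_selection import train_test_split as _tts
            _, X_val, _, y_val = _tts(X_tv, y_tv, test_size=0.25,
                                      stratify=y_tv,
                                      random_state=cfg.seed % (2**32))
            m = evaluate(model, X_val, y_val)
            val_stats["acc"].append(m.acc)
            val_stats["f1"].append(m.f1)
            val_stats["auc"].append(m.auc if m.auc is not None else np.nan)
            final_model = model
        test_metrics = evaluate(final_model, X_test, y_test)
        rows.append(_metrics_row(tag, len(features), val_stats, test_metrics))
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    config: dict
    stages: dict

    def fingerprint(self) -> str:
        blob = json.dumps({"config": self.config, "stages": self.stages},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def write(self, path) -> None:
        payload = {"config": self.config, "stages": self.stages,
                   "fingerprint": self.fingerprint()}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _select_pool(tag: str, pool_ids: list[str], matrix: BetaMatrix,
                 cfg: PipelineConfig) -> tuple:
    """Consensus selection on one pool: both rankers, CV size choice,
    intersection."""
    col = {c: i for i, c in enumerate(matrix.cpg_ids)}
    X = matrix.values.T[:, [col[c] for c in pool_ids]]
    y = matrix.labels
    grid = [s for s in cfg.selection_grid if s <= len(pool_ids)]
    if not grid:
        grid = [len(pool_ids)]
    seed = stage_seed(cfg.seed, f"select-{tag}")
    svm = svm_rfe_ranking(X, y, pool_ids, elim_fraction=cfg.elim_fraction,
                          seed=seed)
    rf = rf_importance_ranking(X, y, pool_ids, n_trees=cfg.rf_trees,
                               seed=seed)
    k_svm, svm_table = cv_subset_selection(svm, X, y, pool_ids, grid,
                                           n_folds=cfg.cv_folds, seed=seed,
                                           n_trees=cfg.rf_trees)
    k_rf, rf_table = cv_subset_selection(rf, X, y, pool_ids, grid,
                                         n_folds=cfg.cv_folds, seed=seed,
                                         n_trees=cfg.rf_trees)
    sites = consensus_sites(svm.top(k_svm), rf.top(k_rf),
                            set_tag=f"{tag}-sites")
    return sites, {"svm_optimal_size": k_svm, "rf_optimal_size": k_rf,
                   "svm_cv": svm_table.to_dict("records"),
                   "rf_cv": rf_table.to_dict("records"),
                   "consensus_size": len(sites.cpg_ids)}


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Execute the full framework on a self-contained synthetic cohort."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    t0 = time.time()

    def _log(stage: str, **info):
        log.info("stage=%s %s", stage,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    # 1. simulate ------------------------------------------------------------
    sim_cfg = SimulationConfig(**{**cfg.sim.__dict__,
                                  "seed": stage_seed(cfg.seed, "simulate")})
    raw, annotation, truth = generate_cohort(sim_cfg)
    write_annotation(annotation, out / "annotation.csv")
    (out / "effector_genes.txt").write_text(
        "\n".join(truth.effector_genes) + "\n")
    stages["simulate"] = {"n_cpg": raw.n_cpg, "n_samples": raw.n_samples,
                          "n_planted_dm": len(truth.dm_cpg_ids),
                          "n_effector_genes": len(truth.effector_genes)}
    _log("simulate", **stages["simulate"])

    # 2. harmonize (split the cohort back into its dataset batches) ----------
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
    write_beta_matrix(matrix, out / "beta_matrix.tsv")
    write_sample_sheet(matrix, out / "sample_sheet.tsv")
    stages["harmonize"] = {"n_cpg": matrix.n_cpg,
                           "n_samples": matrix.n_samples}
    _log("harmonize", **stages["harmonize"])

    # 3. screening -----------------------------------------------------------
    dm = differential_methylation(matrix)
    dm.to_csv(out / "dm_table.tsv", sep="\t")
    k = min(cfg.t_pool_k, len(dm))
    t_pool = select_t_pool(dm, k=k)
    g_pool = select_g_pool(annotation, truth.effector_genes,
                           window_bp=cfg.window_bp)
    g_pool_ids = [c for c in g_pool.cpg_ids if c in set(matrix.cpg_ids)]
    sig = significant_sites(dm, cfg.p_thresh, cfg.delta_thresh)
    planted = set(truth.dm_cpg_ids)
    stages["screening"] = {
        "t_pool_size": len(t_pool.cpg_ids),
        "g_pool_size": len(g_pool_ids),
        "n_significant": len(sig),
        "t_pool_planted_recovery": len(set(t_pool.cpg_ids[:len(planted)])
                                       & planted) / len(planted),
    }
    _log("screening", **stages["screening"])

    # 4. consensus feature selection -----------------------------------------
    t_sites, t_info = _select_pool("T", t_pool.cpg_ids, matrix, cfg)
    g_sites, g_info = _select_pool("G", g_pool_ids, matrix, cfg)
    u_sites = union_sites(t_sites, g_sites)
    order = {c: i for i, c in enumerate(matrix.cpg_ids)}
    sets_ordered = {
        "T-sites": sorted(t_sites.cpg_ids, key=order.get),
        "G-sites": sorted(g_sites.cpg_ids, key=order.get),
        "U-sites": sorted(u_sites.cpg_ids, key=order.get),
    }
    stages["selection"] = {
        "T": t_info, "G": g_info,
        "t_sites": len(t_sites.cpg_ids), "g_sites": len(g_sites.cpg_ids),
        "u_sites": len(u_sites.cpg_ids),
        "tg_overlap": len(t_sites.cpg_ids & g_sites.cpg_ids),
    }
    _log("selection", t_sites=len(t_sites.cpg_ids),
         g_sites=len(g_sites.cpg_ids), u_sites=len(u_sites.cpg_ids))

    # 5. fusion model: feature-set comparison --------------------------------
    X, y = matrix.values.T, matrix.labels
    fusion_cfg = FusionModelConfig(**{**cfg.fusion.__dict__,
                                      "seed": stage_seed(cfg.seed, "fusion")})
    comparison = compare_feature_sets(sets_ordered, X, y, matrix.cpg_ids,
                                      fusion_cfg,
                                      n_repeats=cfg.compare_repeats)
    comparison.to_csv(out / "feature_set_comparison.tsv", sep="\t",
                      index=False)
    stages["comparison"] = comparison.to_dict("records")
    _log("comparison", rows=len(comparison))

    # 6. panel sweep ---------------------------------------------------------
    u_ids = sets_ordered["U-sites"]
    cols = [order[c] for c in u_ids]
    Xu = X[:, cols]
    u_model, _ = train_model(Xu, y, fusion_cfg)
    ranked = importance_ranking(u_model, Xu, u_ids)
    sweep_grid = [s for s in cfg.sweep_grid if s <= len(u_ids)] or [len(u_ids)]
    sweep = panel_sweep(ranked, Xu, y, u_ids, fusion_cfg,
                        size_grid=sweep_grid)
    gate = gate_contribution(u_model, Xu)
    prov = panel_provenance(sweep.panel_cpg_ids, t_sites, g_sites)
    (out / "panel.txt").write_text("\n".join(sweep.panel_cpg_ids) + "\n")
    sweep.curve().to_csv(out / "panel_sweep.tsv", sep="\t", index=False)
    stages["panel"] = {
        "sweep": sweep.curve().to_dict("records"),
        "best_size": sweep.best_size,
        "provenance": prov.__dict__,
        "mean_transformer_weight": gate.mean_transformer_weight,
        "mean_cnn_weight": gate.mean_cnn_weight,
    }
    _log("panel", best_size=sweep.best_size,
         gate_t=round(gate.mean_transformer_weight, 3))

    # 7. gene mapping & effector classification ------------------------------
    genes, unmapped = map_cpg_to_genes(sweep.panel_cpg_ids, annotation)
    rng = np.random.default_rng(stage_seed(cfg.seed, "effector-db"))
    all_genes = sorted(set(annotation.links["gene"]))
    non_eff = [g for g in all_genes if g not in set(truth.effector_genes)]
    database_reported = list(rng.choice(
        non_eff, size=min(len(non_eff), max(1, len(non_eff) // 5)),
        replace=False)) if non_eff else []
    n_val, n_db, n_novel = classify_effector_status(
        genes, truth.effector_genes, database_reported)
    stages["gene_mapping"] = {
        "n_genes": len(genes), "n_unmapped_probes": len(unmapped),
        "n_validated": n_val, "n_database": n_db, "n_novel": n_novel,
    }
    _log("gene_mapping", **stages["gene_mapping"])

    # 8. over-representation --------------------------------------------------
    collection, enriched_names, _ = generate_gene_sets(
        all_genes, cfg.n_gene_sets, cfg.enriched_fraction,
        seed=stage_seed(cfg.seed, "gene-sets"),
        query_genes=truth.effector_genes)
    collection.write_gmt(out / "gene_sets.gmt")
    ora = hypergeometric_ora(genes, collection, all_genes)
    ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    top = ora.iloc[0]
    planted_top = [s for s in ora.head(len(enriched_names))["set_name"]
                   if s in set(enriched_names)]
    stages["enrichment"] = {
        "n_sets": len(ora), "min_adj_p": float(ora["adj_p"].min()),
        "top_set": str(top["set_name"]),
        "planted_in_top": len(planted_top),
        "n_planted": len(enriched_names),
    }
    _log("enrichment", **stages["enrichment"])

    # 9. interaction network --------------------------------------------------
    # hub planting needs non-hub nodes to outnumber hubs 3:1 with slack;
    # fall back to the full gene universe when the panel maps too few genes
    net_genes = genes if len(genes) >= 4 * cfg.n_hubs + 3 else all_genes
    net, hubs = generate_interaction_network(
        net_genes, cfg.n_hubs,
        combined_score_range=(cfg.min_score - 100, 999),
        seed=stage_seed(cfg.seed, "network"))
    write_edge_list(net, out / "edge_list.tsv")
    loaded = load_edge_list(out / "edge_list.tsv", min_score=cfg.min_score)
    scores = composite_node_score(loaded, cfg.w_degree, cfg.w_between,
                                  top_k=cfg.top_k_nodes)
    scores.to_csv(out / "node_scores.tsv", sep="\t", index=False)
    top_nodes = list(scores["node"].head(cfg.n_hubs))
    stages["network"] = {
        "n_nodes": loaded.number_of_nodes(),
        "n_edges": loaded.number_of_edges(),
        "top_nodes": list(scores["node"]),
        "hub_recovery": len(set(top_nodes) & set(hubs)) / len(hubs),
    }
    _log("network", n_nodes=loaded.number_of_nodes(),
         hub_recovery=stages["network"]["hub_recovery"])

    report = RunReport(config=json.loads(cfg.to_json()), stages=stages)
    report.write(out / "run_report.json")
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report
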