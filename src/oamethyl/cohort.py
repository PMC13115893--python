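"""Synthetic 450K-like methylation cohorts with planted ground truth.

The generator emulates the structure every downstream stage consumes:
Beta-distributed beta values in [0, 1] with per-CpG random means,
planted case-control mean differences (Δβ) at known sites split
~50/50 hyper/hypo, additive per-(batch, CpG) location shifts across a
configurable number of dataset batches, class imbalance, and a
manifest-like CpG-to-gene/TSS annotation in which a controllable
fraction of the planted differential sites falls inside the TSS windows
of a planted effector-gene list.  Everything is drawn from a single
seeded generator, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import BetaMatrix, CpGAnnotation
from .network import GeneSetCollection

_SAFE_LOW, _SAFE_HIGH = 0.15, 0.75  # mean band keeping planted shifts unclipped


@dataclass
class SimulationConfig:
    """Cohort shape and effect-size settings.

    Sample-size defaults mirror the study cohort (94 cases, 31 controls,
    three dataset batches); the probe count is a desk-scale default and
    is the knob to turn for larger simulations.
    """

    n_cases: int = 94
    n_controls: int = 31
    n_cpg: int = 2000
    n_dm: int = 100
    delta_beta: float = 0.25
    base_alpha: float = 0.8
    base_beta: float = 0.8
    concentration: float = 60.0  # Beta precision: sd ~ sqrt(mu(1-mu)/(c+1))
    n_batches: int = 3
    batch_shift_sd: float = 0.02
    n_genes: int = 300
    n_effector_genes: int = 30
    dm_in_effector_fraction: float = 0.5
    window_bp: int = 2000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_cpg", "n_dm", "n_batches",
                     "n_genes", "n_effector_genes", "window_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_dm > self.n_cpg:
            raise ValueError("n_dm cannot exceed n_cpg")
        if not 0.0 < self.delta_beta < 1.0:
            raise ValueError("delta_beta must lie in (0, 1)")
        if not 0.0 <= self.dm_in_effector_fraction <= 1.0:
            raise ValueError("dm_in_effector_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted structure for recovery tests."""

    dm_cpg_ids: list[str] = field(default_factory=list)
    effector_genes: list[str] = field(default_factory=list)
    hub_nodes: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)


def _gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    idx = np.arange(cfg.n_genes)
    chroms = [f"chr{1 + (i % 22)}" for i in idx]
    tss = 50_000 + (idx // 22) * 200_000 + rng.integers(0, 20_000, cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    return pd.DataFrame({
        "gene": [f"GENE{i + 1:04d}" for i in idx],
        "chrom": chroms, "tss": tss.astype(int), "strand": strands,
    })


def generate_cohort(config: SimulationConfig
                    ) -> tuple[BetaMatrix, CpGAnnotation, SyntheticTruth]:
    """Simulate a labeled cohort, its annotation, and the planted truth.

    Exactly ``n_dm`` probes carry a case-control mean difference of
    ``delta_beta`` (half hypermethylated in cases, half hypo); a
    ``dm_in_effector_fraction`` share of them sits inside an effector
    TSS window.  Batch labels are assigned round-robin over samples.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg, rng)
    effector_idx = rng.choice(cfg.n_genes, size=min(cfg.n_effector_genes,
                                                    cfg.n_genes),
                              replace=False)
    effector_idx.sort()
    effectors = list(genes["gene"].iloc[effector_idx])
    non_effector_idx = np.setdiff1d(np.arange(cfg.n_genes), effector_idx)

    # --- probe placement ---------------------------------------------------
    cpg_ids = [f"cg{i + 1:07d}" for i in range(cfg.n_cpg)]
    dm_idx = rng.choice(cfg.n_cpg, size=cfg.n_dm, replace=False)
    dm_idx.sort()
    dm_set = set(dm_idx.tolist())
    n_dm_eff = int(round(cfg.dm_in_effector_fraction * cfg.n_dm))
    dm_in_windows = set(rng.choice(dm_idx, size=n_dm_eff,
                                   replace=False).tolist())

    chrom = np.empty(cfg.n_cpg, dtype=object)
    pos = np.empty(cfg.n_cpg, dtype=int)
    link_rows: list[dict] = []

    def _place_near(i: int, gene_row: pd.Series, max_offset: int) -> None:
        offset = int(rng.integers(-max_offset, max_offset + 1))
        chrom[i] = gene_row["chrom"]
        pos[i] = max(1, int(gene_row["tss"]) + offset)
        link_rows.append({"cpg_id": cpg_ids[i], "gene": gene_row["gene"],
                          "tss_pos": int(gene_row["tss"]),
                          "strand": gene_row["strand"]})
        # occasional second gene link (shared locus in the manifest)
        if rng.random() < 0.08:
            other = genes.iloc[int(rng.integers(0, cfg.n_genes))]
            if other["gene"] != gene_row["gene"]:
                link_rows.append({
                    "cpg_id": cpg_ids[i], "gene": other["gene"],
                    "tss_pos": int(other["tss"]), "strand": other["strand"]})

    for i in range(cfg.n_cpg):
        if i in dm_in_windows:
            g = genes.iloc[int(rng.choice(effector_idx))]
            _place_near(i, g, cfg.window_bp)  # inside the window, closed
        elif i in dm_set:
            # planted but deliberately outside any effector window
            if non_effector_idx.size and rng.random() < 0.5:
                g = genes.iloc[int(rng.choice(non_effector_idx))]
                _place_near(i, g, cfg.window_bp)
            else:
                chrom[i] = f"chr{int(rng.integers(1, 23))}"
                pos[i] = int(rng.integers(1, 3_000_000))
        elif rng.random() < 0.6:
            g = genes.iloc[int(rng.integers(0, cfg.n_genes))]
            _place_near(i, g, 3 * cfg.window_bp)
        else:
            chrom[i] = f"chr{int(rng.integers(1, 23))}"
            pos[i] = int(rng.integers(1, 3_000_000))

    annotation = CpGAnnotation(
        probes=pd.DataFrame({"cpg_id": cpg_ids, "chrom": chrom, "pos": pos}),
        links=pd.DataFrame(link_rows,
                           columns=["cpg_id", "gene", "tss_pos", "strand"]),
    )

    # --- beta values --------------------------------------------------------
    n_samples = cfg.n_cases + cfg.n_controls
    labels = np.concatenate([np.ones(cfg.n_cases, dtype=int),
                             np.zeros(cfg.n_controls, dtype=int)])
    mu_control = np.clip(rng.beta(cfg.base_alpha, cfg.base_beta, cfg.n_cpg),
                         0.02, 0.98)
    # planted sites: means drawn from a band that keeps the shifted group
    # mean inside [0, 1] without truncation bias
    hyper = rng.random(cfg.n_dm) < 0.5
    lo = np.where(hyper, _SAFE_LOW, _SAFE_LOW + cfg.delta_beta)
    hi = np.where(hyper, _SAFE_HIGH - cfg.delta_beta, _SAFE_HIGH)
    safe = np.clip(rng.uniform(np.minimum(lo, hi - 1e-3), hi), 0.02, 0.98)
    mu_control[dm_idx] = safe
    mu_case = mu_control.copy()
    mu_case[dm_idx] = np.clip(
        mu_control[dm_idx] + np.where(hyper, cfg.delta_beta, -cfg.delta_beta),
        0.0, 1.0)

    c = cfg.concentration
    values = np.empty((cfg.n_cpg, n_samples))
    for group_mu, cols in ((mu_case, labels == 1), (mu_control, labels == 0)):
        a = group_mu * c
        b = (1.0 - group_mu) * c
        values[:, cols] = rng.beta(a[:, None], b[:, None],
                                   size=(cfg.n_cpg, int(cols.sum())))

    batches = [f"batch{(s % cfg.n_batches) + 1}" for s in range(n_samples)]
    if cfg.batch_shift_sd > 0:
        shifts = rng.normal(0.0, cfg.batch_shift_sd,
                            size=(cfg.n_batches, cfg.n_cpg))
        for s in range(n_samples):
            values[:, s] += shifts[s % cfg.n_batches]
    values = np.clip(values, 0.0, 1.0)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    sample_ids = ([f"OA{i + 1:03d}" for i in range(cfg.n_cases)]
                  + [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)])
    joint = list(rng.choice(["knee", "hip"], size=n_samples, p=[0.6, 0.4]))
    matrix = BetaMatrix(cpg_ids=cpg_ids, sample_ids=sample_ids, values=values,
                        labels=labels, batch=batches, joint=joint)
    truth = SyntheticTruth(dm_cpg_ids=[cpg_ids[i] for i in dm_idx],
                           effector_genes=effectors)
    return matrix, annotation, truth


def generate_interaction_network(genes, n_hubs: int,
                                 combined_score_range: tuple[int, int] = (400, 999),
                                 seed: int = 0) -> tuple[nx.Graph, list[str]]:
    """Build a scored interaction network with planted high-centrality hubs.

    Non-hub nodes form a sparse path backbone (median degree 2); each hub
    is wired to at least max(6, half the non-hubs) distinct non-hub
    nodes, guaranteeing hub degree >= 3x the median non-hub degree.
    Returns the graph and the planted hub ids.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    if n_hubs > len(genes):
        raise ValueError("n_hubs cannot exceed the number of genes")
    lo, hi = combined_score_range
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(genes))
    hubs, non_hubs = order[:n_hubs], order[n_hubs:]

    graph = nx.Graph()
    graph.add_nodes_from(genes)

    def _score() -> int:
        return int(rng.integers(lo, hi + 1))

    # sparse backbone among non-hubs: disjoint pairs keep the median low
    for i in range(0, len(non_hubs) - 1, 2):
        graph.add_edge(non_hubs[i], non_hubs[i + 1], combined_score=_score())
    if non_hubs:
        k = min(len(non_hubs), max(6, (len(non_hubs) + 1) // 2))
        for hub in hubs:
            targets = rng.choice(len(non_hubs), size=k, replace=False)
            for t in targets:
                graph.add_edge(hub, non_hubs[t], combined_score=_score())
        # top up hub degrees until every hub clears 3x the median
        # non-hub degree (attachments themselves raise the median, so
        # iterate; infeasible when hubs are too numerous)
        for _ in range(3 * len(non_hubs)):
            med = float(np.median([graph.degree(n) for n in non_hubs]))
            lagging = [h for h in hubs if graph.degree(h) < 3 * med]
            if not lagging:
                break
            progressed = False
            for hub in lagging:
                candidates = sorted(
                    (n for n in non_hubs if not graph.has_edge(hub, n)),
                    key=lambda n: (graph.degree(n), n))
                need = int(np.ceil(3 * med)) - graph.degree(hub)
                for n in candidates[:need]:
                    graph.add_edge(hub, n, combined_score=_score())
                    progressed = True
            if not progressed:
                raise ValueError(
                    "cannot plant hubs with degree >= 3x the median "
                    "non-hub degree; reduce n_hubs relative to the gene "
                    "list")
        med = float(np.median([graph.degree(n) for n in non_hubs]))
        if any(graph.degree(h) < 3 * med for h in hubs):
            raise ValueError(
                "cannot plant hubs with degree >= 3x the median non-hub "
                "degree; reduce n_hubs relative to the gene list")
    return graph, hubs


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['combined_score']}\n")


def generate_gene_sets(genes, n_sets: int, enriched_fraction: float,
                       seed: int = 0, query_genes=None,
                       set_size_range: tuple[int, int] = (10, 30),
                       query_share: float = 0.8
                       ) -> tuple[GeneSetCollection, list[str], list[str]]:
    """Gene sets with a planted over-representation signal.

    A ``enriched_fraction`` share of the sets draws ``query_share`` of
    its members from the designated query list (default: a random 10%
    of the genes) and the rest from the background; the remaining sets
    sample uniformly.  Returns (collection, enriched names, query list).
    """
    genes = list(genes)
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if query_genes is None:
        n_query = max(1, len(genes) // 10)
        query_genes = list(rng.choice(genes, size=n_query, replace=False))
    query = list(query_genes)
    background = [g for g in genes if g not in set(query)]

    n_enriched = int(round(n_sets * enriched_fraction))
    sets, descriptions = {}, {}
    enriched_names = []
    for i in range(n_sets):
        name = f"SET{i + 1:03d}"
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        if i < n_enriched:
            n_q = min(len(query), max(1, int(round(query_share * size))))
            members = list(rng.choice(query, size=n_q, replace=False))
            n_bg = min(len(background), size - n_q)
            if n_bg > 0:
                members += list(rng.choice(background, size=n_bg,
                                           replace=False))
            enriched_names.append(name)
            descriptions[name] = "planted enriched set"
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)),
                                      replace=False))
            descriptions[name] = "background set"
        sets[name] = set(members)
    return (GeneSetCollection(sets=sets, descriptions=descriptions),
            enriched_names, query)
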