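"""Reading, validation, harmonization, and writing of beta-value matrices
and CpG annotations.

Matrices are TSV with probes as rows (first column ``cpg_id``) and samples
as columns; a companion sample sheet (TSV: sample_id, label, batch, joint)
carries the class label (1 = osteoarthritis, 0 = control), the dataset /
batch identifier, and the joint site.  Annotations follow the 450K
manifest layout: ``IlmnID, CHR, MAPINFO, UCSC_RefGene_Name, TSS_Coordinate,
Strand`` with semicolon-separated multi-gene fields and 1-based
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PRECISION = 4


@dataclass
class BetaMatrix:
    """A CpG x sample matrix of methylation beta values in [0, 1]."""

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_cpg, n_samples)
    labels: np.ndarray  # per-sample, 1 = OA, 0 = control
    batch: list[str]
    joint: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        n_cpg, n_samp = len(self.cpg_ids), len(self.sample_ids)
        if self.values.shape != (n_cpg, n_samp):
            raise ValueError(
                f"values shape {self.values.shape} != ({n_cpg}, {n_samp})"
            )
        if len(set(self.cpg_ids)) != n_cpg:
            dupes = pd.Index(self.cpg_ids)
            raise ValueError(
                "duplicate probe ids: "
                f"{sorted(dupes[dupes.duplicated()].unique())[:5]}"
            )
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere(
                np.isfinite(self.values)
                & ((self.values < 0) | (self.values > 1))
            )[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.cpg_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        if self.labels.size != n_samp or not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1, one per sample")
        if len(self.batch) != n_samp:
            raise ValueError("batch must have one entry per sample")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids,
                            columns=self.sample_ids)

    def subset_probes(self, cpg_ids: list[str]) -> "BetaMatrix":
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        rows = [index[c] for c in cpg_ids]
        return BetaMatrix(list(cpg_ids), list(self.sample_ids),
                          self.values[rows], self.labels.copy(),
                          list(self.batch),
                          None if self.joint is None else list(self.joint))


@dataclass
class CpGAnnotation:
    """Probe genomic coordinates and gene/TSS links.

    ``probes``: DataFrame with columns cpg_id, chrom, pos (1-based).
    ``links``: DataFrame with columns cpg_id, gene, tss_pos, strand —
    one row per (probe, gene) link; probes may have zero links.
    """

    probes: pd.DataFrame
    links: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cpg_id", "gene", "tss_pos", "strand"]))

    def __post_init__(self):
        if self.probes["cpg_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        if (self.probes["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    def covers(self, cpg_ids) -> bool:
        return set(cpg_ids) <= set(self.probes["cpg_id"])


# -- chromosome ordering -----------------------------------------------------

_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y)$", re.IGNORECASE)


def chromosome_sort_key(chrom: str) -> tuple[int, object]:
    """chr1..chr22 numerically, then chrX, chrY, then others lexicographic."""
    m = _CHROM_RE.match(str(chrom))
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body))
        return (1, {"X": 0, "Y": 1}[body])
    return (2, str(chrom))


def genomic_order(annotation: CpGAnnotation, cpg_ids: list[str]) -> list[str]:
    """Deterministic total order: (chromosome, position, probe id)."""
    probes = annotation.probes.set_index("cpg_id").loc[cpg_ids]
    keys = sorted(
        zip(cpg_ids, probes["chrom"], probes["pos"]),
        key=lambda t: (chromosome_sort_key(t[1]), int(t[2]), t[0]),
    )
    return [k[0] for k in keys]


# -- reading / writing -------------------------------------------------------

def read_beta_matrix(matrix_path, sample_sheet_path) -> BetaMatrix:
    """Load a probe x sample TSV plus its sample sheet, validating values,
    ids, and sheet coverage."""
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    sheet = sheet.set_index("sample_id")
    missing = [s for s in frame.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    sheet = sheet.loc[list(frame.columns)]
    joint = (list(sheet["joint"].astype(str))
             if "joint" in sheet.columns else None)
    return BetaMatrix(
        cpg_ids=list(frame.index.astype(str)),
        sample_ids=list(frame.columns.astype(str)),
        values=frame.to_numpy(dtype=float),
        labels=sheet["label"].to_numpy(dtype=int),
        batch=list(sheet["batch"].astype(str)),
        joint=joint,
    )


def write_beta_matrix(matrix: BetaMatrix, out_path,
                      precision: int = DEFAULT_PRECISION) -> None:
    if matrix.n_cpg == 0 or matrix.n_samples == 0:
        raise ValueError("refusing to write an empty beta matrix")
    frame = matrix.to_frame().round(precision)
    frame.index.name = "cpg_id"
    frame.to_csv(out_path, sep="\t")


def write_sample_sheet(matrix: BetaMatrix, out_path) -> None:
    sheet = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "label": matrix.labels,
        "batch": matrix.batch,
        "joint": matrix.joint if matrix.joint is not None
        else ["NA"] * matrix.n_samples,
    })
    sheet.to_csv(out_path, sep="\t", index=False)


def read_annotation(path) -> CpGAnnotation:
    """Parse a 450K-manifest-like CSV into probe and link tables."""
    raw = pd.read_csv(path, dtype=str)
    probes = pd.DataFrame({
        "cpg_id": raw["IlmnID"],
        "chrom": raw["CHR"],
        "pos": raw["MAPINFO"].astype(int),
    })
    rows = []
    for _, rec in raw.iterrows():
        genes = str(rec.get("UCSC_RefGene_Name", "") or "")
        if not genes or genes == "nan":
            continue
        tss = str(rec.get("TSS_Coordinate", "") or "").split(";")
        strands = str(rec.get("Strand", "") or "").split(";")
        for i, gene in enumerate(genes.split(";")):
            rows.append({
                "cpg_id": rec["IlmnID"],
                "gene": gene,
                "tss_pos": int(tss[i]),
                "strand": strands[i] if i < len(strands) else "+",
            })
    links = pd.DataFrame(rows, columns=["cpg_id", "gene", "tss_pos", "strand"])
    return CpGAnnotation(probes=probes, links=links)


def write_annotation(annotation: CpGAnnotation, path) -> None:
    link_map: dict[str, list] = {}
    for _, rec in annotation.links.iterrows():
        link_map.setdefault(rec["cpg_id"], []).append(rec)
    rows = []
    for _, probe in annotation.probes.iterrows():
        recs = link_map.get(probe["cpg_id"], [])
        rows.append({
            "IlmnID": probe["cpg_id"],
            "CHR": probe["chrom"],
            "MAPINFO": int(probe["pos"]),
            "UCSC_RefGene_Name": ";".join(r["gene"] for r in recs),
            "TSS_Coordinate": ";".join(str(int(r["tss_pos"])) for r in recs),
            "Strand": ";".join(r["strand"] for r in recs),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# -- harmonization -----------------------------------------------------------

def batch_center(values: np.ndarray, batches: list[str]) -> np.ndarray:
    """Per-(batch, probe) mean-centering re-anchored to the probe's global
    mean, clipped back to [0, 1]."""
    out = values.astype(float).copy()
    global_mean = out.mean(axis=1, keepdims=True)
    batches = np.asarray(batches)
    for b in np.unique(batches):
        cols = batches == b
        out[:, cols] += global_mean - out[:, cols].mean(axis=1, keepdims=True)
    return np.clip(out, 0.0, 1.0)


def harmonize_datasets(datasets: list[BetaMatrix],
                       annotation: CpGAnnotation,
                       precision: int = DEFAULT_PRECISION,
                       correct_batch: bool = True) -> BetaMatrix:
    """Merge cohorts into one analysis-ready matrix.

    Keeps probes common to all datasets that have no missing values,
    applies per-batch location adjustment, rounds to a fixed decimal
    precision (half-to-even), and orders rows genomically.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    common = set(datasets[0].cpg_ids)
    for d in datasets[1:]:
        common &= set(d.cpg_ids)
    if not common:
        raise ValueError("no probes shared by all datasets")

    frames, labels, batches, joints, samples = [], [], [], [], []
    for d in datasets:
        sub = d.subset_probes(sorted(common))
        frames.append(sub.to_frame())
        labels.append(sub.labels)
        batches.extend(sub.batch)
        joints.extend(sub.joint if sub.joint is not None
                      else ["NA"] * sub.n_samples)
        samples.extend(sub.sample_ids)
    merged = pd.concat(frames, axis=1)
    keep = merged.index[merged.notna().all(axis=1)]
    if keep.empty:
        raise ValueError("every shared probe has missing values")
    merged = merged.loc[keep]

    values = merged.to_numpy(dtype=float)
    if correct_batch:
        values = batch_center(values, batches)
    values = np.round(values, precision)

    result = BetaMatrix(
        cpg_ids=list(merged.index), sample_ids=samples, values=values,
        labels=np.concatenate(labels), batch=batches, joint=joints,
    )
    order = genomic_order(annotation, result.cpg_ids)
    return result.subset_probes(order)
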