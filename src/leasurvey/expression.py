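"""Tissue expression and qPCR analysis.

RPKM matrices are log2(x+1)-transformed and clustered by average-linkage
agglomeration on 1 - Pearson correlation across tissues.  qPCR relative
expression follows the delta-delta-Cq method with an assumed amplification
efficiency of 2: the target's (mean control Cq - mean treated Cq) shift is
normalized by the mean shift of the reference genes, giving a log2 fold
change directly.  The differential call uses the inclusive |log2FC| >= 1
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import LeaSurveyError

DE_LOG2FC_CUTOFF = 1.0


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(RPKM + 1); zeros stay zero."""
    if (m.to_numpy() < 0).any():
        raise LeaSurveyError("negative RPKM values")
    return np.log2(m + 1.0)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    genes: list[str]  # input order, parallel to the linkage's leaf indices
    gene_order: list[str]  # dendrogram leaf order
    zero_variance_genes: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Partition genes into k clusters (gene -> cluster label)."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.genes, (int(x) for x in labels)))


def hcluster(m: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of genes on 1 - Pearson correlation.

    Genes with zero variance across tissues have undefined correlation;
    their distances are set to the maximum (1.0) and they are reported in
    ``zero_variance_genes``.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise LeaSurveyError("need >= 2 genes and >= 2 tissues to cluster")
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    dist[flat, :] = 1.0
    dist[:, flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(z)
    genes = list(m.index)
    return ClusterResult(
        linkage=z,
        genes=genes,
        gene_order=[genes[i] for i in order],
        zero_variance_genes=[g for g, f in zip(genes, flat) if f],
    )


def tissue_preference(m: pd.DataFrame, fold: float = 2.0) -> dict[str, str | None]:
    """Preferred tissue per gene: max RPKM >= fold x second-highest and > 0."""
    out: dict[str, str | None] = {}
    for gene, row in m.iterrows():
        vals = row.sort_values(ascending=False)
        top, second = vals.iloc[0], vals.iloc[1] if len(vals) > 1 else 0.0
        out[gene] = vals.index[0] if top > 0 and top >= fold * second else None
    return out


@dataclass(frozen=True)
class QPCRRecord:
    gene_id: str
    treatment: str
    tissue: str
    cq_control: tuple[float, ...]
    cq_treated: tuple[float, ...]

    def __post_init__(self):
        for vals in (self.cq_control, self.cq_treated):
            if len(vals) < 2:
                raise LeaSurveyError(
                    f"{self.gene_id}/{self.treatment}/{self.tissue}: "
                    "need >= 2 Cq replicates per condition"
                )
            if any(not (0 < v < 45) for v in vals):
                raise LeaSurveyError(
                    f"{self.gene_id}: Cq values must lie in (0, 45)"
                )

    @property
    def delta_cq(self) -> float:
        """Mean control Cq minus mean treated Cq (positive = induced)."""
        return float(np.mean(self.cq_control) - np.mean(self.cq_treated))


def qpcr_log2fc(rec: QPCRRecord, refs: Sequence[QPCRRecord]) -> float:
    """Delta-delta-Cq log2 fold change, efficiency assumed exactly 2."""
    refs = [
        r for r in refs if r.treatment == rec.treatment and r.tissue == rec.tissue
    ]
    if not refs:
        raise LeaSurveyError(
            f"no reference record for {rec.treatment}/{rec.tissue}"
        )
    return rec.delta_cq - float(np.mean([r.delta_cq for r in refs]))


def de_call(log2fc: float, cutoff: float = DE_LOG2FC_CUTOFF) -> str:
    """'up' if log2FC >= cutoff, 'down' if <= -cutoff, else 'unchanged'."""
    if log2fc >= cutoff:
        return "up"
    if log2fc <= -cutoff:
        return "down"
    return "unchanged"


def read_cq_table(path: str) -> list[QPCRRecord]:
    """Read a long-format Cq TSV: gene, treatment, tissue, condition,
    replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "treatment", "tissue", "condition", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise LeaSurveyError(f"Cq table missing columns: {sorted(missing)}")
    records = []
    for (gene, trt, tis), grp in df.groupby(
        ["gene", "treatment", "tissue"], sort=True
    ):
        ctrl = tuple(grp.loc[grp.condition == "control", "cq"])
        trtd = tuple(grp.loc[grp.condition == "treated", "cq"])
        records.append(QPCRRecord(gene, trt, tis, ctrl, trtd))
    return records


def qpcr_panel(
    records: Iterable[QPCRRecord],
    reference_genes: Sequence[str] = ("GAPC2", "UPL7"),
) -> pd.DataFrame:
    """Fold-change table with DE calls for all non-reference records."""
    records = list(records)
    refs = [r for r in records if r.gene_id in reference_genes]
    if not refs:
        raise LeaSurveyError(f"no records for reference genes {reference_genes}")
    rows = []
    for rec in records:
        if rec.gene_id in reference_genes:
            continue
        fc = qpcr_log2fc(rec, refs)
        rows.append((rec.gene_id, rec.treatment, rec.tissue, fc, de_call(fc)))
    return pd.DataFrame(
        rows, columns=["gene", "treatment", "tissue", "log2fc", "call"]
    ).sort_values(["gene", "treatment", "tissue"], ignore_index=True)
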