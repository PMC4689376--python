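"""Gene models from GFF3 and exon/intron structure summaries."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .errors import ParseError


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its primary transcript's exon chain."""

    gene_id: str
    chromosome: str
    strand: str
    span: tuple[int, int]  # 1-based inclusive
    exons: tuple[tuple[int, int], ...]  # sorted, disjoint, 1-based inclusive
    cds_span: tuple[int, int]
    protein_id: str

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(
            self.exons[i + 1][0] - self.exons[i][1] - 1
            for i in range(len(self.exons) - 1)
        )

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)


def _validate_parents(path: str) -> None:
    ids: set[str] = set()
    deferred: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 tab-delimited columns, got {len(cols)}", lineno)
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                ids.add(attrs["ID"])
            for parent in attrs.get("Parent", "").split(","):
                if parent:
                    deferred.append((lineno, parent))
    for lineno, parent in deferred:
        if parent not in ids:
            raise ParseError(f"Parent={parent!r} refers to an unknown ID", lineno)


def parse_gff3(path: str, fasta_path: str) -> list[GeneModel]:
    """Load gene models, one per gene, from a GFF3 and its genome FASTA.

    The primary transcript of each gene is the mRNA with the longest total
    CDS (ties broken by lexicographically smallest transcript ID).  Exon
    coordinates are validated against contig lengths.  Genes with no mRNA
    child are skipped with a warning.
    """
    _validate_parents(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    contig_len = {name: len(rec) for name, rec in Fasta(fasta_path).items()}
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            warnings.warn(f"gene {gene.id} has no mRNA child; skipped")
            continue

        def cds_len(m):
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        primary = min(mrnas, key=lambda m: (-cds_len(m), m.id))
        exons = sorted(
            (e.start, e.end)
            for e in db.children(primary, featuretype="exon")
        )
        if not exons:
            warnings.warn(f"transcript {primary.id} has no exons; gene skipped")
            continue
        if gene.seqid not in contig_len:
            raise ParseError(f"gene {gene.id} on unknown contig {gene.seqid!r}")
        clen = contig_len[gene.seqid]
        for s, e in exons:
            if not (1 <= s <= e <= clen):
                raise ParseError(
                    f"exon {s}-{e} of gene {gene.id} outside contig "
                    f"{gene.seqid} (length {clen})"
                )
        cds = [(c.start, c.end) for c in db.children(primary, featuretype="CDS")]
        cds_span = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else exons[0]
        protein_id = primary.attributes.get("protein_id", [primary.id])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                span=(gene.start, gene.end),
                exons=tuple(exons),
                cds_span=cds_span,
                protein_id=protein_id,
            )
        )
    return models


def _round_half_up_pct(x: float) -> int:
    return int(math.floor(x * 100 + 0.5))


def intron_stats(models: list[GeneModel]) -> tuple[pd.DataFrame, dict]:
    """Per-gene intron counts plus the headline distribution summary.

    Returns ``(per_gene, summary)`` where ``summary`` holds the percentage
    of genes with no intron, the percentage with one or two, and the raw
    count of genes with three or more (percentages rounded half-up to
    whole percent).
    """
    per_gene = pd.DataFrame(
        [
            (
                m.gene_id,
                m.n_introns,
                ",".join(map(str, m.exon_lengths)),
                ",".join(map(str, m.intron_lengths)),
            )
            for m in models
        ],
        columns=["gene_id", "n_introns", "exon_lengths", "intron_lengths"],
    )
    if not models:
        return per_gene, {}
    n = len(models)
    n0 = int((per_gene.n_introns == 0).sum())
    n12 = int(per_gene.n_introns.isin([1, 2]).sum())
    n3p = int((per_gene.n_introns >= 3).sum())
    summary = {
        "n_genes": n,
        "pct_intronless": _round_half_up_pct(n0 / n),
        "pct_one_or_two": _round_half_up_pct(n12 / n),
        "n_three_or_more": n3p,
    }
    return per_gene, summary
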