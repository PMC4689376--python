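"""Promoter extraction and cis-element scanning.

The promoter is the 1 kb of genomic sequence immediately upstream of the
translation start site, on the coding strand.  Registered cis-elements
(IUPAC degenerate strings) are counted on both strands; overlapping and
nested occurrences are all counted independently — in particular every
DRE/CRT occurrence (RCCGAC) also contains an LTRE occurrence (CCGAC) and
increments both counters.  ``N`` in the promoter never matches.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import LeaSurveyError
from .registry import DEFAULT_REGISTRY, IUPAC_DNA, MotifRegistry, reverse_complement
from .structure import GeneModel

PROMOTER_LENGTH = 1000


def iupac_regex(pattern: str) -> re.Pattern:
    """Overlap-tolerant regex for an IUPAC DNA pattern (lookahead trick)."""
    body = "".join(
        c if len(IUPAC_DNA[c]) == 1 else f"[{IUPAC_DNA[c]}]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


def extract_promoter(
    model: GeneModel,
    genome: Mapping[str, str],
    length: int = PROMOTER_LENGTH,
) -> str:
    """Upstream ``length`` bases of the translation start, coding strand.

    Minus-strand promoters are reverse-complemented.  A promoter running
    off the contig edge is truncated with a warning.
    """
    if model.cds_span is None:
        raise LeaSurveyError(f"gene {model.gene_id} has no CDS")
    contig = str(genome[model.chromosome])
    if model.strand == "+":
        end = model.cds_span[0] - 1  # last base before the ATG, 1-based
        start = max(0, end - length)
        seq = contig[start:end]
    else:
        start = model.cds_span[1]  # 0-based index of first base past cds end
        seq = contig[start:start + length]
        seq = reverse_complement(seq)
    if len(seq) < length:
        warnings.warn(
            f"promoter of {model.gene_id} truncated to {len(seq)} bp at contig edge"
        )
    return seq.upper()


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    strand: str  # "+" | "-"
    offset: int  # 0-based position in the promoter string


def scan(
    promoter: str,
    registry: MotifRegistry = DEFAULT_REGISTRY,
    gene_id: str = "",
    forward_only: bool = False,
) -> tuple[dict[str, int], list[MotifHit]]:
    """Count every occurrence of each registered motif, both strands.

    Minus-strand occurrences are matches of the motif's reverse complement
    in the promoter string; their offset is the match position in the
    promoter (forward coordinates).
    """
    counts: dict[str, int] = {}
    hits: list[MotifHit] = []
    for name, pattern in registry:
        fwd = iupac_regex(pattern)
        n = 0
        for m in fwd.finditer(promoter):
            hits.append(MotifHit(gene_id, name, "+", m.start()))
            n += 1
        if not forward_only:
            rev = iupac_regex(reverse_complement(pattern))
            for m in rev.finditer(promoter):
                hits.append(MotifHit(gene_id, name, "-", m.start()))
                n += 1
        counts[name] = n
    return counts, hits


def scan_genes(
    models: list[GeneModel],
    genome: Mapping[str, str],
    registry: MotifRegistry = DEFAULT_REGISTRY,
    length: int = PROMOTER_LENGTH,
    forward_only: bool = False,
) -> tuple[pd.DataFrame, list[MotifHit]]:
    """Per-gene motif counts over extracted promoters.

    Returns (counts table indexed by gene_id, flat hit records).
    """
    rows, all_hits = {}, []
    for model in models:
        promoter = extract_promoter(model, genome, length)
        counts, hits = scan(promoter, registry, model.gene_id, forward_only)
        rows[model.gene_id] = counts
        all_hits.extend(hits)
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table.index.name = "gene_id"
    return table.sort_index(), all_hits


def group_averages(table: pd.DataFrame, group_of: Mapping[str, str]) -> pd.DataFrame:
    """Mean motif count per group, rounded to 2 decimals."""
    missing = [g for g in table.index if g not in group_of]
    if missing:
        raise LeaSurveyError(f"unassigned gene(s) in motif table: {missing[:5]}")
    grouped = table.groupby([group_of[g] for g in table.index]).mean().round(2)
    grouped.index.name = "group"
    return grouped


def candidate_filter(
    table: pd.DataFrame, motif: str = "ABRE", min_count: int = 10
) -> list[str]:
    """Genes whose promoter carries >= ``min_count`` occurrences of ``motif``,
    sorted by count descending then gene id."""
    if motif not in table.columns:
        raise LeaSurveyError(f"motif {motif!r} not in table")
    sel = table[table[motif] >= min_count]
    return sorted(sel.index, key=lambda g: (-int(sel.loc[g, motif]), g))


def hits_bed(hits: list[MotifHit], registry: MotifRegistry = DEFAULT_REGISTRY) -> str:
    """Promoter-relative BED (0-based half-open) of motif hits."""
    lines = []
    motif_len = dict(registry.entries)
    for h in sorted(hits, key=lambda h: (h.gene_id, h.offset, h.motif, h.strand)):
        L = len(motif_len[h.motif])
        lines.append(
            f"{h.gene_id}\t{h.offset}\t{h.offset + L}\t{h.motif}\t0\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
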