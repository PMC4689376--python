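"""Paralog detection and tandem/segmental duplication classification.

Candidate paralog pairs come from the family phylogeny (same-group sister
leaves) and from a same-group percent-identity screen.  Each candidate is
then classified:

* tandem — same group, same chromosome, nearest gene boundaries within
  100 kb, and at most 10 non-family ("nonhomologous") spacer genes lying
  wholly between the pair;
* segmental — the global protein alignment covers more than 80% of the
  longer protein at more than 70% similarity, and the pair does not
  qualify as tandem (tandem takes precedence);
* none — everything else.

"Similarity" is percent identity over non-terminal-gap alignment columns
of a Needleman-Wunsch global alignment (BLOSUM62, gap open -10,
extend -0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import LeaSurveyError
from .structure import GeneModel

TANDEM_MAX_DISTANCE_BP = 100_000
TANDEM_MAX_SPACERS = 10
SEGMENTAL_MIN_COVERAGE = 0.8
SEGMENTAL_MIN_SIMILARITY_PCT = 70.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentResult:
    a_aligned: str
    b_aligned: str
    score: float
    identities: int
    aligned_len: int  # columns excluding terminal-gap columns
    coverage: float  # longer-protein residues in the aligned region / its length
    similarity_pct: float


def global_align(a: str, b: str) -> AlignmentResult:
    """Global Needleman-Wunsch alignment of two protein sequences.

    The first alignment in Biopython's deterministic traceback order is
    used.  Identity, coverage and similarity are computed over the columns
    remaining after trimming leading/trailing columns that contain a gap.
    """
    if not a or not b:
        raise LeaSurveyError("cannot align empty sequences")
    aln = _ALIGNER.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    # trim terminal gap runs
    start, end = 0, len(ra)
    while start < end and (ra[start] == "-" or rb[start] == "-"):
        start += 1
    while end > start and (ra[end - 1] == "-" or rb[end - 1] == "-"):
        end -= 1
    core_a, core_b = ra[start:end], rb[start:end]
    aligned_len = len(core_a)
    identities = sum(x == y and x != "-" for x, y in zip(core_a, core_b))
    longer = max(len(a), len(b))
    if len(a) >= len(b):
        covered = sum(c != "-" for c in core_a)
    else:
        covered = sum(c != "-" for c in core_b)
    coverage = covered / longer
    similarity = 100.0 * identities / aligned_len if aligned_len else 0.0
    return AlignmentResult(
        ra, rb, float(aln.score), identities, aligned_len, coverage, similarity
    )


@dataclass(frozen=True)
class PairMetrics:
    pair: tuple[str, str]
    aligned_len: int
    coverage: float
    similarity_pct: float
    same_chromosome: bool
    genomic_distance_bp: int | None
    spacer_genes: int | None


@dataclass(frozen=True)
class DuplicationCall:
    pair: tuple[str, str]
    klass: str  # "tandem" | "segmental" | "none"
    metrics: PairMetrics


def _sister_pairs(tree: dendropy.Tree) -> set[tuple[str, str]]:
    out = set()
    for node in tree.preorder_internal_node_iter():
        leaf_children = [c for c in node.child_nodes() if c.is_leaf()]
        if len(leaf_children) == 2 and len(node.child_nodes()) == 2:
            names = sorted(c.taxon.label for c in leaf_children)
            out.add(tuple(names))
    return out


def candidate_pairs(
    group_of: Mapping[str, str],
    tree: dendropy.Tree | None,
    proteins: Mapping[str, str],
    similarity_screen_pct: float = 60.0,
) -> list[tuple[str, str]]:
    """Union of same-group sister-leaf pairs and same-group pairs passing
    the percent-identity screen, sorted lexicographically."""
    pairs: set[tuple[str, str]] = set()
    if tree is not None:
        for a, b in _sister_pairs(tree):
            if a in group_of and b in group_of and group_of[a] == group_of[b]:
                pairs.add((a, b))
    by_group: dict[str, list[str]] = {}
    for gid, grp in group_of.items():
        if gid in proteins:
            by_group.setdefault(grp, []).append(gid)
    for members in by_group.values():
        members.sort()
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if (a, b) in pairs:
                    continue
                res = global_align(proteins[a], proteins[b])
                if res.similarity_pct >= similarity_screen_pct:
                    pairs.add((a, b))
    return sorted(pairs)


def pair_metrics(
    pair: tuple[str, str],
    proteins: Mapping[str, str],
    models: Mapping[str, GeneModel],
    family_ids: set[str],
) -> PairMetrics:
    a, b = sorted(pair)
    for g in (a, b):
        if g not in models:
            raise LeaSurveyError(f"gene {g!r} missing from annotation")
        if g not in proteins:
            raise LeaSurveyError(f"gene {g!r} missing from proteome")
    res = global_align(proteins[a], proteins[b])
    ma, mb = models[a], models[b]
    same_chrom = ma.chromosome == mb.chromosome
    distance = spacers = None
    if same_chrom:
        up, dn = (ma, mb) if ma.span[0] <= mb.span[0] else (mb, ma)
        distance = max(0, dn.span[0] - up.span[1] - 1)
        spacers = sum(
            1
            for m in models.values()
            if m.chromosome == ma.chromosome
            and m.gene_id not in family_ids
            and m.span[0] > up.span[1]
            and m.span[1] < dn.span[0]
        )
    return PairMetrics(
        (a, b), res.aligned_len, res.coverage, res.similarity_pct,
        same_chrom, distance, spacers,
    )


def classify(
    pairs: Sequence[tuple[str, str]],
    group_of: Mapping[str, str],
    proteins: Mapping[str, str],
    models: Mapping[str, GeneModel],
    family_ids: set[str] | None = None,
) -> list[DuplicationCall]:
    """Classify candidate pairs as tandem, segmental or none."""
    if family_ids is None:
        family_ids = set(group_of)
    calls = []
    for pair in pairs:
        a, b = sorted(pair)
        m = pair_metrics((a, b), proteins, models, family_ids)
        same_group = group_of.get(a) is not None and group_of.get(a) == group_of.get(b)
        if (
            same_group
            and m.same_chromosome
            and m.genomic_distance_bp is not None
            and m.genomic_distance_bp <= TANDEM_MAX_DISTANCE_BP
            and m.spacer_genes is not None
            and m.spacer_genes <= TANDEM_MAX_SPACERS
        ):
            klass = "tandem"
        elif (
            m.coverage > SEGMENTAL_MIN_COVERAGE
            and m.similarity_pct > SEGMENTAL_MIN_SIMILARITY_PCT
        ):
            klass = "segmental"
        else:
            klass = "none"
        calls.append(DuplicationCall((a, b), klass, m))
    return calls


def tandem_clusters(calls: Sequence[DuplicationCall]) -> list[tuple[str, ...]]:
    """Connected components of the tandem-call graph, as sorted tuples."""
    adj: dict[str, set[str]] = {}
    for c in calls:
        if c.klass != "tandem":
            continue
        a, b = c.pair
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    clusters = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            g = stack.pop()
            if g in comp:
                continue
            comp.add(g)
            stack.extend(adj[g] - comp)
        seen |= comp
        clusters.append(tuple(sorted(comp)))
    return clusters


def duplicated_fraction(calls: Sequence[DuplicationCall], total_genes: int) -> int:
    """Percentage of genes involved in any tandem/segmental call (whole %)."""
    if total_genes < 1:
        raise LeaSurveyError("total_genes must be >= 1")
    genes = {
        g for c in calls if c.klass in ("tandem", "segmental") for g in c.pair
    }
    return int(math.floor(100.0 * len(genes) / total_genes + 0.5))


def calls_frame(calls: Sequence[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.pair[0],
                c.pair[1],
                c.klass,
                round(c.metrics.coverage, 4),
                round(c.metrics.similarity_pct, 2),
                c.metrics.genomic_distance_bp,
                c.metrics.spacer_genes,
            )
            for c in calls
        ],
        columns=[
            "gene_a", "gene_b", "class", "coverage",
            "similarity_pct", "distance_bp", "spacers",
        ],
    )
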