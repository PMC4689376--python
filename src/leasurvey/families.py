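"""Assignment of proteins to the seven LEA groups.

Primary evidence is a significant Pfam domain hit (lowest e-value wins).
Proteins with no significant hit ("orphans") are rescued by placement in
the family phylogeny: they take the majority group of their nearest
domain-assigned neighbours by patristic distance.  When tree placement
contradicts domain evidence, the domain wins and the protein is only
flagged as tree-discordant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import dendropy

from .errors import LeaSurveyError, ParseError
from .phylo import patristic_distances
from .registry import PROFILE_TO_GROUP

DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class DomainHit:
    """One row of a domain-hit table (hmmscan domtblout dialect)."""

    protein_id: str
    profile_id: str
    e_value: float
    bit_score: float
    ali_start: int
    ali_end: int

    @property
    def known_profile(self) -> bool:
        return self.profile_id in PROFILE_TO_GROUP

    @property
    def group(self) -> str | None:
        return PROFILE_TO_GROUP.get(self.profile_id)


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    group: str | None
    evidence: str  # "domain" | "tree" | "none"
    supporting_hit: DomainHit | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def with_flag(self, flag: str) -> "GroupAssignment":
        return replace(self, flags=self.flags | {flag})


def parse_domain_hits(path: str) -> list[DomainHit]:
    """Parse an hmmscan-style domtblout table.

    Whitespace-delimited; ``#`` lines are comments.  Column layout follows
    hmmscan: profile name / accession in columns 1-2, protein id in column
    4, full-sequence e-value and bit score in columns 7-8, alignment
    coordinates in columns 18-19 (1-based inclusive).  Profile accession
    versions (``PF00257.19``) are stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 19:
                raise ParseError(
                    f"expected >= 19 whitespace-delimited fields, got {len(fields)}",
                    line=lineno,
                )
            try:
                hit = DomainHit(
                    protein_id=fields[3],
                    profile_id=fields[1].split(".")[0],
                    e_value=float(fields[6]),
                    bit_score=float(fields[7]),
                    ali_start=int(fields[17]),
                    ali_end=int(fields[18]),
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if hit.e_value <= 0:
                raise ParseError("e-value must be positive", line=lineno)
            if not (1 <= hit.ali_start <= hit.ali_end):
                raise ParseError("invalid alignment coordinates", line=lineno)
            hits.append(hit)
    return hits


def assign_by_domain(
    hits: list[DomainHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    all_proteins: list[str] | None = None,
) -> tuple[list[GroupAssignment], list[str]]:
    """Assign each protein to the group of its best significant hit.

    Returns (assignments, orphans).  Orphans are proteins with no
    significant known-profile hit; ``all_proteins`` extends the orphan
    search to proteins absent from the hit table entirely.  A protein
    whose two best hits tie exactly on both e-value and bit score while
    naming different groups is flagged ``ambiguous`` and left ungrouped.
    """
    if evalue_cutoff <= 0:
        raise LeaSurveyError("e-value cutoff must be positive")
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    assignments: list[GroupAssignment] = []
    orphans: list[str] = []
    universe = list(by_protein)
    if all_proteins is not None:
        universe += [p for p in all_proteins if p not in by_protein]
    for pid in universe:
        sig = [
            h
            for h in by_protein.get(pid, [])
            if h.known_profile and h.e_value <= evalue_cutoff
        ]
        if not sig:
            orphans.append(pid)
            continue
        sig.sort(key=lambda h: (h.e_value, -h.bit_score, h.profile_id))
        best = sig[0]
        rivals = [
            h
            for h in sig[1:]
            if h.e_value == best.e_value
            and h.bit_score == best.bit_score
            and h.group != best.group
        ]
        if rivals:
            assignments.append(
                GroupAssignment(pid, None, "none", None, frozenset({"ambiguous"}))
            )
        else:
            assignments.append(GroupAssignment(pid, best.group, "domain", best))
    return assignments, orphans


def _nearest_assigned(
    pid: str,
    dists: dict[tuple[str, str], float],
    group_of: dict[str, str],
    k: int,
) -> list[tuple[float, str, str]]:
    """(distance, leaf, group) for the k nearest domain-assigned leaves."""
    cand = []
    for other, grp in group_of.items():
        if other == pid:
            continue
        key = tuple(sorted((pid, other)))
        if key in dists:
            cand.append((dists[key], other, grp))
    cand.sort()
    return cand[:k]


def assign_orphans_by_tree(
    orphans: list[str],
    tree: dendropy.Tree,
    assignments: list[GroupAssignment],
    k: int = 3,
) -> list[GroupAssignment]:
    """Rescue orphans by majority group among k nearest assigned leaves.

    An exact majority tie falls back to the single nearest leaf's group; if
    that too is tied (equidistant leaves of different groups) the orphan is
    returned unassigned with an ``unassigned`` flag.
    """
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [o for o in orphans if o not in leaf_names]
    if missing:
        raise LeaSurveyError(f"orphan(s) absent from tree: {', '.join(missing)}")
    group_of = {
        a.protein_id: a.group
        for a in assignments
        if a.group is not None and a.evidence == "domain"
    }
    if not group_of:
        raise LeaSurveyError("no domain-assigned proteins in the tree")
    dists = patristic_distances(tree)
    out: list[GroupAssignment] = []
    for pid in orphans:
        nearest = _nearest_assigned(pid, dists, group_of, k)
        counts = Counter(grp for _, _, grp in nearest)
        ranked = counts.most_common()
        if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
            out.append(GroupAssignment(pid, ranked[0][0], "tree"))
            continue
        # majority tie: nearest single leaf decides, unless equidistant
        # leaves disagree
        d0 = nearest[0][0]
        front = {grp for d, _, grp in nearest if d == d0}
        if len(front) == 1:
            out.append(GroupAssignment(pid, front.pop(), "tree"))
        else:
            out.append(
                GroupAssignment(pid, None, "none", None, frozenset({"unassigned"}))
            )
    return out


def reconcile(
    assignments: list[GroupAssignment],
    tree: dendropy.Tree,
    k: int = 3,
) -> list[GroupAssignment]:
    """Flag domain-assigned proteins whose tree neighbourhood disagrees.

    Domain evidence always keeps the group; a protein whose k nearest
    domain-assigned neighbours are majority another group gets a
    ``tree_discordant`` flag.  Tree-rescued proteins are never flagged.
    """
    group_of = {
        a.protein_id: a.group
        for a in assignments
        if a.group is not None and a.evidence == "domain"
    }
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    dists = patristic_distances(tree)
    out: list[GroupAssignment] = []
    for a in assignments:
        if a.evidence != "domain" or a.protein_id not in leaf_names:
            out.append(a)
            continue
        nearest = _nearest_assigned(a.protein_id, dists, group_of, k)
        if not nearest:
            out.append(a)
            continue
        counts = Counter(grp for _, _, grp in nearest)
        top_group, top_n = counts.most_common(1)[0]
        majority = top_n > len(nearest) / 2
        if majority and top_group != a.group:
            out.append(a.with_flag("tree_discordant"))
        else:
            out.append(a)
    return out


def assignments_table(assignments: list[GroupAssignment]) -> str:
    """Render assignments as a TSV string (protein_id, group, evidence, flags)."""
    lines = ["protein_id\tgroup\tevidence\tflags"]
    for a in sorted(assignments, key=lambda x: x.protein_id):
        flags = ",".join(sorted(a.flags))
        lines.append(f"{a.protein_id}\t{a.group or '.'}\t{a.evidence}\t{flags or '.'}")
    return "\n".join(lines) + "\n"
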