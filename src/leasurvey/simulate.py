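"""Ground-truthed synthetic dataset generator.

Builds a toy multi-chromosome genome carrying a 72-gene LEA family in
seven groups, with every feature the survey pipeline measures planted by
construction and recorded in a :class:`SimTruth` object:

* group membership (each group descends from its own random ancestor
  protein, carries a fixed group signature, and is strongly divergent from
  the other groups, so planted clades are monophyletic);
* hydropathy (LEA_2 proteins are composition-biased hydrophobic, all other
  groups hydrophilic; dehydrins carry the 15-residue K-segment verbatim);
* the intron-count distribution (default 40 / 31 / 1 of 72 genes with
  zero / one-or-two / three introns);
* tandem clusters (compact same-group runs with a few non-family spacer
  genes) and cross-chromosome segmental pairs mutated to a target percent
  identity;
* exact promoter cis-element counts (background DNA is rejection-sampled
  so that no registered motif occurs outside planted positions, and each
  finished promoter is re-verified with an independent brute-force scan);
* tissue RPKM values with five planted correlation clades;
* qPCR Cq shifts realizing planted log2 fold changes, with two stable
  reference genes.

All randomness flows from ``SimConfig.seed``; equal seeds give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ConfigurationError
from .registry import (
    DEFAULT_REGISTRY,
    GROUP_TO_PROFILE,
    IUPAC_DNA,
    K_SEGMENT,
    MotifRegistry,
    reverse_complement,
)

TISSUES = ("callus", "flower", "leaf", "fruit")
TREATMENTS = ("drought", "PEG", "NaCl")
QPCR_TISSUES = ("leaf", "root")
REFERENCE_GENES = ("GAPC2", "UPL7")

# residues with positive / negative Kyte-Doolittle hydropathy
_HYDROPHOBIC = "AVILMFC"
_HYDROPHILIC = "RNDQEGHKPSTWY"

_GROUP_LENGTHS = {
    "LEA_1": 100,
    "LEA_2": 150,
    "LEA_3": 77,
    "LEA_4": 120,
    "LEA_5": 90,
    "DEHYDRIN": 77,
    "SMP": 130,
}

# fixed 12-mer group signatures (never mutated); DEHYDRIN uses the
# 15-residue K-segment instead
_GROUP_SIGNATURES = {
    "LEA_1": "DKEQGRTNSHPE",
    "LEA_2": "VLIAVFMLAVIF",
    "LEA_3": "QTSGHRNDEKPW",
    "LEA_4": "NHETKQDGRSPY",
    "LEA_5": "GPDSETRKQHNW",
    "DEHYDRIN": K_SEGMENT,
    "SMP": "RQHNGTPKDSEW",
}
_SIGNATURE_OFFSET = 10

DEFAULT_GROUP_SIZES = {
    "LEA_1": 4,
    "LEA_2": 43,
    "LEA_3": 5,
    "LEA_4": 7,
    "LEA_5": 3,
    "DEHYDRIN": 6,
    "SMP": 4,
}

DEFAULT_INTRON_DISTRIBUTION = {"0": 40, "1-2": 31, "3": 1}

#: fraction of positions mutated from the group ancestor per ordinary
#: member; keeps unplanted same-group identity well below the 70%
#: segmental threshold while leaving clades monophyletic
_BASELINE_MUTATION_FRACTION = 0.30
#: mutation fraction for tandem-cluster members relative to the cluster seed
_TANDEM_MUTATION_FRACTION = 0.05
#: hard ceiling on unplanted same-group percent identity (position-wise)
_MAX_UNPLANNED_IDENTITY = 67.0

_BIG_GAP = 102_000  # separates non-cluster family genes: rules out tandem calls
_CLUSTER_GAP = 800  # filler inside tandem clusters


@dataclass(frozen=True)
class TandemClusterSpec:
    group: str
    size: int
    chromosome: int  # 1-based
    max_gap_bp: int = 20_000
    spacer_genes: int = 2


@dataclass(frozen=True)
class SegmentalPairSpec:
    group: str
    similarity_pct: float
    coverage_pct: float = 100.0
    chromosome_a: int = 0  # 0 = auto
    chromosome_b: int = 0


def _default_tandem_clusters() -> list[TandemClusterSpec]:
    return [
        TandemClusterSpec("LEA_3", 2, 1),
        TandemClusterSpec("LEA_2", 4, 2),
        TandemClusterSpec("LEA_2", 3, 5),
        TandemClusterSpec("LEA_2", 2, 6),
        TandemClusterSpec("LEA_2", 2, 6),
        TandemClusterSpec("LEA_2", 3, 6),
        TandemClusterSpec("SMP", 2, 9),
    ]


def _default_segmental_pairs() -> list[SegmentalPairSpec]:
    return [
        SegmentalPairSpec("LEA_2", 80.4, chromosome_a=3, chromosome_b=7),
        SegmentalPairSpec("LEA_2", 74.6, chromosome_a=4, chromosome_b=8),
        SegmentalPairSpec("SMP", 71.3, chromosome_a=1, chromosome_b=5),
    ]


def gene_ids(group_sizes: dict[str, int]) -> dict[str, list[str]]:
    """Deterministic gene identifiers, assigned in group blocks."""
    out: dict[str, list[str]] = {}
    n = 0
    for group, size in group_sizes.items():
        out[group] = [f"LEA{n + i + 1:03d}" for i in range(size)]
        n += size
    return out


def _default_qpcr_effects(ids: dict[str, list[str]]) -> list[tuple[str, str, str, float]]:
    g = {grp: lst for grp, lst in ids.items()}
    return [
        (g["LEA_1"][1], "drought", "leaf", 1.5),
        (g["LEA_4"][2], "drought", "root", 1.8),
        (g["LEA_5"][0], "drought", "root", 1.4),
        (g["DEHYDRIN"][0], "PEG", "leaf", 1.6),
        (g["LEA_1"][1], "PEG", "root", 1.3),
        (g["LEA_2"][6], "PEG", "leaf", -1.5),
        (g["LEA_4"][1], "PEG", "leaf", -1.3),
        (g["LEA_4"][5], "PEG", "leaf", -1.7),
        (g["LEA_5"][2], "PEG", "leaf", -1.2),
        (g["DEHYDRIN"][4], "PEG", "leaf", -1.4),
        (g["LEA_2"][6], "NaCl", "root", -1.3),
        (g["LEA_5"][2], "NaCl", "root", -1.6),
    ]


def _default_candidate_genes(ids: dict[str, list[str]]) -> list[str]:
    """17 genes planted with >= 10 ABREs: the 9 DE genes plus 8 extras."""
    de = sorted({g for g, _, _, _ in _default_qpcr_effects(ids)})
    extras = [
        ids["LEA_1"][0],
        ids["LEA_2"][0],
        ids["LEA_2"][7],
        ids["LEA_2"][22],
        ids["LEA_3"][0],
        ids["LEA_4"][0],
        ids["LEA_5"][1],
        ids["SMP"][1],
    ]
    out = sorted(set(de) | set(extras))
    assert len(out) == 17
    return out


def _default_promoter_plants(ids: dict[str, list[str]]) -> dict[str, dict[str, int]]:
    all_genes = [g for lst in ids.values() for g in lst]
    candidates = set(_default_candidate_genes(ids))
    plants = {}
    for k, gene in enumerate(all_genes):
        abre = 10 + (k % 6) if gene in candidates else (3 * k) % 9
        dre = k % 3
        plants[gene] = {
            "ABRE": abre,
            "DRE_CRT": dre,
            "MYBS": k % 4,
            "LTRE": dre + (k % 2),  # scanner convention: every DRE/CRT nests an LTRE
        }
    return plants


def _default_expression_patterns() -> dict[int, tuple[float, ...]]:
    return {
        1: (10.0, 7.0, 2.0, 0.2),
        2: (0.2, 10.0, 7.0, 2.0),
        3: (2.0, 0.2, 10.0, 7.0),
        4: (7.0, 2.0, 0.2, 10.0),
        5: (12.0, 0.3, 0.3, 0.3),
    }


@dataclass
class SimConfig:
    seed: int = 1
    n_chromosomes: int = 9
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    intron_distribution: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_DISTRIBUTION)
    )
    tandem_clusters: list[TandemClusterSpec] = field(default_factory=_default_tandem_clusters)
    segmental_pairs: list[SegmentalPairSpec] = field(default_factory=_default_segmental_pairs)
    promoter_plants: dict[str, dict[str, int]] | None = None  # None = defaults
    expression_patterns: dict[int, tuple[float, ...]] = field(
        default_factory=_default_expression_patterns
    )
    qpcr_effects: list[tuple[str, str, str, float]] | None = None  # None = defaults
    orphan_fraction: float = 0.0
    registry: MotifRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)
    cq_replicate_sd: float = 0.05
    chromosome_capacity_bp: int = 3_000_000

    def validate(self) -> None:
        total = sum(self.group_sizes.values())
        if sum(self.intron_distribution.values()) != total:
            raise ConfigurationError(
                "intron_distribution totals "
                f"{sum(self.intron_distribution.values())}, expected {total}"
            )
        if not 0 <= self.orphan_fraction < 1:
            raise ConfigurationError("orphan_fraction must lie in [0, 1)")
        used: dict[str, int] = {g: 0 for g in self.group_sizes}
        for p in self.segmental_pairs:
            used[p.group] = used.get(p.group, 0) + 2
        for i, c in enumerate(self.tandem_clusters):
            if c.group not in self.group_sizes:
                raise ConfigurationError(f"tandem cluster {i}: unknown group {c.group!r}")
            if c.size < 2:
                raise ConfigurationError(f"tandem cluster {i}: size must be >= 2")
            if c.spacer_genes > 10:
                raise ConfigurationError(
                    f"tandem cluster {i}: {c.spacer_genes} spacer genes would "
                    "break the planted tandem criteria (max 10)"
                )
            if not 1 <= c.chromosome <= self.n_chromosomes:
                raise ConfigurationError(
                    f"tandem cluster {i}: chromosome {c.chromosome} out of range"
                )
            used[c.group] = used.get(c.group, 0) + c.size
        for group, n in used.items():
            if n > self.group_sizes.get(group, 0):
                raise ConfigurationError(
                    f"group {group}: planted duplications need {n} genes, "
                    f"only {self.group_sizes.get(group, 0)} available"
                )


@dataclass
class SimTruth:
    group_of: dict[str, str]
    duplication_class_of: dict[tuple[str, str], str]
    planted_motif_counts: dict[tuple[str, str], int]
    planted_fold_changes: dict[tuple[str, str, str], float]
    intron_count_of: dict[str, int]
    expression_clade_of: dict[str, int]
    orphans: list[str]


@dataclass
class SimBundle:
    out_dir: Path
    genome_fasta: Path
    gff3: Path
    proteome_fasta: Path
    domain_hits: Path
    alignment_fasta: Path
    group_alignments: dict[str, Path]
    rpkm_tsv: Path
    qpcr_cq_tsv: Path
    truth_tsv: Path
    truth: SimTruth


# ---------------------------------------------------------------------------
# sequence helpers

_CODONS = {
    aa: sorted(c for c, a in unambiguous_dna_by_id[1].forward_table.items() if a == aa)
    for aa in set(unambiguous_dna_by_id[1].forward_table.values())
}


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _expand_iupac(pattern: str) -> list[str]:
    outs = [""]
    for c in pattern:
        outs = [o + b for o in outs for b in IUPAC_DNA[c]]
    return outs


def _forbidden_strings(registry: MotifRegistry) -> list[str]:
    out: list[str] = []
    for _, pattern in registry:
        for p in (pattern, reverse_complement(pattern)):
            for s in _expand_iupac(p):
                if s not in out:
                    out.append(s)
    return out


def bruteforce_motif_counts(seq: str, registry: MotifRegistry = DEFAULT_REGISTRY) -> dict[str, int]:
    """Independent both-strand occurrence counter (position-by-position).

    Used by the generator to verify planted promoters; intentionally
    avoids the regex machinery of :mod:`leasurvey.promoters`.
    """
    counts = {}
    for name, pattern in registry:
        total = 0
        for pat in (pattern, reverse_complement(pattern)):
            sets = [IUPAC_DNA[c] for c in pat]
            for i in range(len(seq) - len(pat) + 1):
                if all(seq[i + j] in sets[j] for j in range(len(pat))):
                    total += 1
        counts[name] = total
    return counts


def _motif_free_dna(rng: np.random.Generator, length: int, forbidden: list[str]) -> str:
    maxlen = max(len(f) for f in forbidden)
    seq: list[str] = []
    guard = 0
    while len(seq) < length:
        placed = False
        for b in rng.permutation(4):
            seq.append("ACGT"[b])
            tail = "".join(seq[-maxlen:])
            if any(tail.endswith(f) for f in forbidden):
                seq.pop()
            else:
                placed = True
                break
        if not placed:
            del seq[-min(3, len(seq)):]
            guard += 1
            if guard > 10 * length:
                raise ConfigurationError("motif-free background generation stalled")
    return "".join(seq)


def _guard(concrete: str, registry: MotifRegistry) -> str:
    """Flank a concrete planted string with bases that cannot complete any
    registered motif across the junction (e.g. a C before ACGTG would add a
    reverse-strand ABRE)."""
    want = bruteforce_motif_counts(concrete, registry)
    for lead in "TAGC":
        for tail in "TAGC":
            s = lead + concrete + tail
            if bruteforce_motif_counts(s, registry) == want:
                return s
    raise ConfigurationError(f"no safe flanking bases for planted motif {concrete!r}")


def _build_promoter(
    rng: np.random.Generator,
    plants: dict[str, int],
    registry: MotifRegistry,
    forbidden: list[str],
    length: int = 1000,
    max_attempts: int = 80,
) -> str:
    """A promoter whose both-strand scan counts exactly equal ``plants``."""
    n_dre = plants.get("DRE_CRT", 0)
    n_ltre = plants.get("LTRE", 0)
    if n_ltre < n_dre:
        raise ConfigurationError(
            "LTRE count must be >= DRE_CRT count (every DRE/CRT nests an LTRE)"
        )
    # concrete strings to write into the promoter; standalone LTREs get a
    # T/C lead-in base so they do not complete a DRE/CRT
    items: list[str] = []
    for _ in range(plants.get("ABRE", 0)):
        items.append("ACGTG")
    for _ in range(n_dre):
        items.append(("A" if rng.integers(0, 2) else "G") + "CCGAC")
    for _ in range(n_ltre - n_dre):
        items.append(("T" if rng.integers(0, 2) else "C") + "CCGAC")
    for _ in range(plants.get("MYBS", 0)):
        items.append("TAACTG")
    unknown = set(plants) - {"ABRE", "DRE_CRT", "LTRE", "MYBS"}
    if unknown:
        raise ConfigurationError(f"cannot plant unregistered motifs: {sorted(unknown)}")
    stride = 10
    n_cells = (length - stride) // stride
    if len(items) > n_cells:
        raise ConfigurationError("too many planted motifs for promoter length")
    for _ in range(max_attempts):
        seq = list(_motif_free_dna(rng, length, forbidden))
        cells = rng.choice(n_cells, size=len(items), replace=False)
        for item, cell in zip(items, cells):
            concrete = item if rng.integers(0, 3) else reverse_complement(item)
            concrete = _guard(concrete, registry)
            pos = int(cell) * stride
            seq[pos:pos + len(concrete)] = concrete
        out = "".join(seq)
        if bruteforce_motif_counts(out, registry) == {
            name: plants.get(name, 0) for name, _ in registry
        }:
            return out
    raise ConfigurationError("could not realize exact planted motif counts")


def _mutate(
    seq: str,
    n_mut: int,
    rng: np.random.Generator,
    pool: str,
    protected: range,
) -> str:
    """Substitute ``n_mut`` distinct unprotected positions with different
    residues drawn from ``pool``."""
    positions = [i for i in range(len(seq)) if i not in protected]
    if n_mut > len(positions):
        raise ConfigurationError("more mutations requested than mutable positions")
    chosen = rng.choice(len(positions), size=n_mut, replace=False)
    out = list(seq)
    for idx in chosen:
        p = positions[int(idx)]
        options = [c for c in pool if c != out[p]]
        out[p] = options[rng.integers(0, len(options))]
    return "".join(out)


def _identity_pct(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# generation stages


def _make_proteins(
    config: SimConfig,
    ids: dict[str, list[str]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[tuple[str, str], str], dict[str, list[list[str]]]]:
    """Protein sequences honouring planted duplication structure.

    Returns (protein_of_gene, duplication_truth, cluster_genes_by_group).
    """
    proteins: dict[str, str] = {}
    dup_truth: dict[tuple[str, str], str] = {}
    clusters_of: dict[str, list[list[str]]] = {g: [] for g in config.group_sizes}
    seg_genes: dict[str, list[tuple[str, str, SegmentalPairSpec]]] = {}

    for group, members in ids.items():
        L = _GROUP_LENGTHS.get(group, 110)
        sig = _GROUP_SIGNATURES.get(group, "DKEQGRTNSHPE")
        pool = _HYDROPHOBIC if group == "LEA_2" else _HYDROPHILIC
        protected = range(_SIGNATURE_OFFSET, _SIGNATURE_OFFSET + len(sig))
        ancestor = [pool[rng.integers(0, len(pool))] for _ in range(L)]
        ancestor[_SIGNATURE_OFFSET:_SIGNATURE_OFFSET + len(sig)] = sig
        ancestor = "".join(ancestor)
        m_base = round(_BASELINE_MUTATION_FRACTION * L)

        # allocate members: segmental pairs first, then tandem clusters
        cursor = 0
        pair_specs = [p for p in config.segmental_pairs if p.group == group]
        my_seg = []
        for spec in pair_specs:
            a, b = members[cursor], members[cursor + 1]
            cursor += 2
            my_seg.append((a, b, spec))
        my_clusters = []
        for spec in [c for c in config.tandem_clusters if c.group == group]:
            my_clusters.append(members[cursor:cursor + spec.size])
            cursor += spec.size
        free = members[cursor:]
        seg_genes[group] = my_seg
        clusters_of[group] = my_clusters

        planted_pairs: set[tuple[str, str]] = set()

        # baseline members: seg sources, cluster seeds, free genes
        for a, b, spec in my_seg:
            proteins[a] = _mutate(ancestor, m_base, rng, pool, protected)
            m_seg = round(L * (1.0 - spec.similarity_pct / 100.0))
            proteins[b] = _mutate(proteins[a], m_seg, rng, pool, protected)
            pair = tuple(sorted((a, b)))
            dup_truth[pair] = "segmental"
            planted_pairs.add(pair)
        for cluster in my_clusters:
            seed_seq = _mutate(ancestor, m_base, rng, pool, protected)
            proteins[cluster[0]] = seed_seq
            m_t = max(1, round(_TANDEM_MUTATION_FRACTION * L))
            for g in cluster[1:]:
                proteins[g] = _mutate(seed_seq, m_t, rng, pool, protected)
            for i, a in enumerate(cluster):
                for b in cluster[i + 1:]:
                    pair = tuple(sorted((a, b)))
                    dup_truth[pair] = "tandem"
                    planted_pairs.add(pair)
        for g in free:
            proteins[g] = _mutate(ancestor, m_base, rng, pool, protected)

        # enforce the unplanted-identity ceiling so no spurious pair can
        # pass the segmental similarity threshold
        for _ in range(200):
            violation = None
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if tuple(sorted((a, b))) in planted_pairs:
                        continue
                    if _identity_pct(proteins[a], proteins[b]) > _MAX_UNPLANNED_IDENTITY:
                        violation = (a, b)
                        break
                if violation:
                    break
            if violation is None:
                break
            va, vb = violation
            planted_members = {m for pair in planted_pairs for m in pair}
            if vb not in planted_members:
                proteins[vb] = _mutate(ancestor, m_base, rng, pool, protected)
            elif va not in planted_members:
                proteins[va] = _mutate(ancestor, m_base, rng, pool, protected)
            else:
                raise ConfigurationError(
                    f"group {group}: planted duplicates {va}/{vb} collide "
                    "above the unplanted identity ceiling"
                )
        else:
            raise ConfigurationError(
                f"group {group}: could not keep unplanted pairs below "
                f"{_MAX_UNPLANNED_IDENTITY}% identity"
            )
    return proteins, dup_truth, clusters_of


def _assign_introns(
    config: SimConfig, all_genes: list[str], ids: dict[str, list[str]], rng: np.random.Generator
) -> dict[str, int]:
    """Per-gene intron counts honouring the planted distribution.

    Genes with three or more introns are taken from the SMP group when one
    is present (mirroring the one three-intron gene of the survey design).
    """
    counts: dict[str, int] = {}
    n3 = config.intron_distribution.get("3", 0)
    smp = list(ids.get("SMP", []))
    three_genes = smp[:n3]
    if len(three_genes) < n3:
        three_genes += [g for g in all_genes if g not in three_genes][: n3 - len(three_genes)]
    for g in three_genes:
        counts[g] = 3
    remaining = [g for g in all_genes if g not in counts]
    perm = rng.permutation(len(remaining))
    remaining = [remaining[int(i)] for i in perm]
    n0 = config.intron_distribution.get("0", 0)
    n12 = config.intron_distribution.get("1-2", 0)
    for g in remaining[:n0]:
        counts[g] = 0
    for j, g in enumerate(remaining[n0:n0 + n12]):
        counts[g] = 1 + (j % 2)
    leftover = remaining[n0 + n12:]
    if leftover:
        raise ConfigurationError("intron_distribution does not cover every gene")
    return counts


@dataclass
class _GeneUnit:
    gene_id: str
    strand: str
    promoter: str | None  # coding-strand promoter (None for spacer genes)
    exons_coding: list[str]  # exon sequences, coding strand, 5'->3'
    introns_coding: list[str]
    is_family: bool

    @property
    def body_coding(self) -> str:
        parts = []
        for i, ex in enumerate(self.exons_coding):
            parts.append(ex)
            if i < len(self.introns_coding):
                parts.append(self.introns_coding[i])
        return "".join(parts)

    def unit_seq(self) -> str:
        body = self.body_coding
        if self.promoter is None:
            return body if self.strand == "+" else reverse_complement(body)
        if self.strand == "+":
            return self.promoter + body
        return reverse_complement(body) + reverse_complement(self.promoter)


def _make_gene_unit(
    gene_id: str,
    protein: str,
    n_introns: int,
    strand: str,
    promoter: str | None,
    rng: np.random.Generator,
    is_family: bool = True,
) -> _GeneUnit:
    cds = _reverse_translate(protein, rng)
    if n_introns == 0:
        exons = [cds]
        introns: list[str] = []
    else:
        cut_points = sorted(
            int(x) for x in rng.choice(np.arange(30, len(cds) - 30), size=n_introns, replace=False)
        )
        exons, prev = [], 0
        for cp in cut_points:
            exons.append(cds[prev:cp])
            prev = cp
        exons.append(cds[prev:])
        introns = [_random_dna(rng, int(rng.integers(80, 301))) for _ in range(n_introns)]
    return _GeneUnit(gene_id, strand, promoter, exons, introns, is_family)


def _gff_rows_for_unit(unit: _GeneUnit, chrom: str, offset: int) -> tuple[list[str], int, int]:
    """GFF3 rows for a unit whose first base sits at 0-based ``offset``.

    Returns (rows, gene_start, gene_end) in 1-based inclusive coords.
    """
    body = unit.body_coding
    promoter_len = len(unit.promoter) if unit.promoter else 0
    if unit.strand == "+":
        body_start0 = offset + promoter_len
    else:
        body_start0 = offset
    gene_start = body_start0 + 1
    gene_end = body_start0 + len(body)

    # coding-strand exon intervals within the body
    intervals = []
    pos = 0
    for i, ex in enumerate(unit.exons_coding):
        intervals.append((pos, pos + len(ex)))  # half-open
        pos += len(ex)
        if i < len(unit.introns_coding):
            pos += len(unit.introns_coding[i])
    L = len(body)
    genomic = []
    for a, b in intervals:
        if unit.strand == "+":
            genomic.append((gene_start + a, gene_start + b - 1))
        else:
            genomic.append((gene_start + (L - b), gene_start + (L - a) - 1))
    genomic.sort()

    gid = unit.gene_id
    tid = f"{gid}.t1"
    rows = [
        f"{chrom}\tleasim\tgene\t{gene_start}\t{gene_end}\t.\t{unit.strand}\t.\tID={gid}",
        f"{chrom}\tleasim\tmRNA\t{gene_start}\t{gene_end}\t.\t{unit.strand}\t.\t"
        f"ID={tid};Parent={gid};protein_id={gid}",
    ]
    # phases in transcription order
    order = genomic if unit.strand == "+" else genomic[::-1]
    phase_of = {}
    cum = 0
    for s, e in order:
        phase_of[(s, e)] = (3 - (cum % 3)) % 3
        cum += e - s + 1
    for i, (s, e) in enumerate(genomic, 1):
        rows.append(
            f"{chrom}\tleasim\texon\t{s}\t{e}\t.\t{unit.strand}\t.\t"
            f"ID={tid}.exon{i};Parent={tid}"
        )
    for i, (s, e) in enumerate(genomic, 1):
        rows.append(
            f"{chrom}\tleasim\tCDS\t{s}\t{e}\t.\t{unit.strand}\t{phase_of[(s, e)]}\t"
            f"ID={tid}.cds{i};Parent={tid}"
        )
    return rows, gene_start, gene_end


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Emit the full synthetic dataset into ``out_dir`` and return paths
    plus the planted ground truth."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ids = gene_ids(config.group_sizes)
    all_genes = [g for lst in ids.values() for g in lst]
    group_of = {g: grp for grp, lst in ids.items() for g in lst}

    proteins, dup_truth, clusters_of = _make_proteins(config, ids, rng)
    intron_of = _assign_introns(config, all_genes, ids, rng)

    plants = (
        config.promoter_plants
        if config.promoter_plants is not None
        else _default_promoter_plants(ids)
    )
    missing = [g for g in all_genes if g not in plants]
    if missing:
        raise ConfigurationError(f"promoter_plants missing genes: {missing[:5]}")
    forbidden = _forbidden_strings(config.registry)
    promoters = {
        g: _build_promoter(rng, plants[g], config.registry, forbidden)
        for g in all_genes
    }
    motif_truth = {
        (g, name): plants[g].get(name, 0)
        for g in all_genes
        for name, _ in config.registry
    }

    # --- layout -----------------------------------------------------------
    chrom_items: dict[int, list[object]] = {c: [] for c in range(1, config.n_chromosomes + 1)}
    placed: set[str] = set()
    spacer_counter = 0

    cluster_specs = list(config.tandem_clusters)
    cluster_members: list[list[str]] = []
    by_group_iter = {g: iter(clusters_of[g]) for g in clusters_of}
    for spec in cluster_specs:
        members = next(by_group_iter[spec.group])
        cluster_members.append(members)

    for spec, members in zip(cluster_specs, cluster_members):
        items: list[_GeneUnit | str] = []
        n_gaps = len(members) - 1
        spacer_slots = [0] * n_gaps
        for s in range(spec.spacer_genes):
            spacer_slots[s % n_gaps] += 1
        for i, g in enumerate(members):
            strand = "+" if (i % 3) != 2 else "-"
            unit = _make_gene_unit(
                g, proteins[g], intron_of[g], strand, promoters[g], rng
            )
            items.append(unit)
            placed.add(g)
            if i < n_gaps:
                for _ in range(spacer_slots[i]):
                    spacer_counter += 1
                    sp_protein = "M" + "".join(
                        _HYDROPHILIC[rng.integers(0, len(_HYDROPHILIC))] for _ in range(79)
                    )
                    items.append(
                        _make_gene_unit(
                            f"SPC{spacer_counter:03d}", sp_protein, 0, "+", None, rng,
                            is_family=False,
                        )
                    )
        chrom_items[spec.chromosome].append(("cluster", items, spec))

    # segmental pairs on explicit chromosomes
    auto = 1
    seg_placement: list[tuple[str, int]] = []
    for grp in ids:
        pair_specs = [p for p in config.segmental_pairs if p.group == grp]
        cursor = 0
        for spec in pair_specs:
            a, b = ids[grp][cursor], ids[grp][cursor + 1]
            cursor += 2
            ca = spec.chromosome_a or (auto := auto % config.n_chromosomes + 1)
            cb = spec.chromosome_b or (auto := auto % config.n_chromosomes + 1)
            if ca == cb:
                cb = cb % config.n_chromosomes + 1
            seg_placement += [(a, ca), (b, cb)]
    for g, c in seg_placement:
        strand = "+" if sum(map(ord, g)) % 3 != 2 else "-"
        unit = _make_gene_unit(g, proteins[g], intron_of[g], strand, promoters[g], rng)
        chrom_items[c].append(("gene", unit, None))
        placed.add(g)

    free = [g for g in all_genes if g not in placed]
    for i, g in enumerate(free):
        c = (i % config.n_chromosomes) + 1
        strand = "+" if (i % 3) != 2 else "-"
        unit = _make_gene_unit(g, proteins[g], intron_of[g], strand, promoters[g], rng)
        chrom_items[c].append(("gene", unit, None))

    # --- assemble chromosomes & GFF --------------------------------------
    fasta_parts: list[str] = []
    gff_rows: list[str] = ["##gff-version 3"]
    for c in range(1, config.n_chromosomes + 1):
        name = f"chr{c}"
        seq_parts: list[str] = []
        pos = 0

        def _filler(n: int) -> None:
            nonlocal pos
            seq_parts.append(_random_dna(rng, n))
            pos += n

        _filler(5000)
        for kind, payload, spec in chrom_items[c]:
            _filler(_BIG_GAP)
            if kind == "gene":
                unit = payload
                rows, *_ = _gff_rows_for_unit(unit, name, pos)
                s = unit.unit_seq()
                seq_parts.append(s)
                pos += len(s)
                gff_rows.extend(rows)
            else:
                first = True
                prev_family_end = None
                for unit in payload:
                    if not first:
                        _filler(_CLUSTER_GAP)
                    first = False
                    rows, g_start, g_end = _gff_rows_for_unit(unit, name, pos)
                    s = unit.unit_seq()
                    seq_parts.append(s)
                    pos += len(s)
                    gff_rows.extend(rows)
                    if unit.is_family:
                        if (
                            prev_family_end is not None
                            and g_start - prev_family_end - 1 > spec.max_gap_bp
                        ):
                            raise ConfigurationError(
                                f"tandem cluster of {spec.group} on {name}: "
                                f"intra-cluster gap exceeds {spec.max_gap_bp} bp"
                            )
                        prev_family_end = g_end
            if pos > config.chromosome_capacity_bp:
                label = f" (cluster of {spec.group})" if kind == "cluster" and spec else ""
                raise ConfigurationError(
                    f"chromosome {name} exceeds capacity "
                    f"{config.chromosome_capacity_bp} bp{label}"
                )
        _filler(3000)
        fasta_parts.append(f">{name}\n{_wrap_fasta(''.join(seq_parts))}\n")

    genome_fasta = out / "genome.fasta"
    genome_fasta.write_text("".join(fasta_parts))
    gff3 = out / "annotation.gff3"
    gff3.write_text("\n".join(gff_rows) + "\n")

    # --- proteome / domain hits / alignments ------------------------------
    proteome = out / "proteome.fasta"
    proteome.write_text(
        "".join(f">{g}\n{_wrap_fasta(proteins[g])}\n" for g in all_genes)
    )

    n_orph = int(math.floor(config.orphan_fraction * len(all_genes)))
    orphan_idx = rng.choice(len(all_genes), size=n_orph, replace=False) if n_orph else []
    orphans = sorted(all_genes[int(i)] for i in orphan_idx)

    dom_lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ----------  ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for k, g in enumerate(all_genes):
        if g in orphans:
            continue
        grp = group_of[g]
        L = len(proteins[g])
        evalue = f"{1.5 + (k % 7):.1f}e-{25 + (k % 10)}"
        score = f"{90.0 + (k % 40):.1f}"
        dom_lines.append(
            f"{grp:<20} {GROUP_TO_PROFILE[grp]:<10} {len(_GROUP_SIGNATURES[grp]):5d} "
            f"{g:<20} {'-':<10} {L:5d} {evalue:>9} {score:>6} {0.1:5.1f} "
            f"  1   1 {evalue:>9} {evalue:>9} {score:>6} {0.1:5.1f} "
            f"{1:5d} {len(_GROUP_SIGNATURES[grp]):5d} "
            f"{_SIGNATURE_OFFSET + 1:5d} {_SIGNATURE_OFFSET + len(_GROUP_SIGNATURES[grp]):5d} "
            f"{1:5d} {L:5d} 0.98 -"
        )
    domain_hits = out / "domain_hits.domtblout"
    domain_hits.write_text("\n".join(dom_lines) + "\n")

    max_len = max(len(p) for p in proteins.values())
    aln_path = out / "alignment.fasta"
    aln_path.write_text(
        "".join(
            f">{g}\n{_wrap_fasta(proteins[g] + '-' * (max_len - len(proteins[g])))}\n"
            for g in all_genes
        )
    )
    group_alignments = {}
    for grp, lst in ids.items():
        p = out / f"alignment_{grp}.fasta"
        p.write_text("".join(f">{g}\n{_wrap_fasta(proteins[g])}\n" for g in lst))
        group_alignments[grp] = p

    # --- expression -------------------------------------------------------
    clades = sorted(config.expression_patterns)
    clade_of = {g: clades[i % len(clades)] for i, g in enumerate(all_genes)}
    rpkm_lines = ["gene\t" + "\t".join(TISSUES)]
    for g in all_genes:
        profile = np.asarray(config.expression_patterns[clade_of[g]], dtype=float)
        scale = float(2.0 ** rng.normal(0.0, 0.5))
        noise = 2.0 ** rng.normal(0.0, 0.05, size=len(profile))
        vals = profile * scale * noise
        rpkm_lines.append(g + "\t" + "\t".join(f"{v:.4f}" for v in vals))
    rpkm_tsv = out / "rpkm.tsv"
    rpkm_tsv.write_text("\n".join(rpkm_lines) + "\n")

    # --- qPCR -------------------------------------------------------------
    effects = (
        config.qpcr_effects if config.qpcr_effects is not None else _default_qpcr_effects(ids)
    )
    effect_of = {(g, trt, tis): fc for g, trt, tis, fc in effects}
    panel_genes = sorted({g for g, _, _, _ in effects} | set(
        _default_candidate_genes(ids) if config.promoter_plants is None else []
    ))
    cq_lines = ["gene\ttreatment\ttissue\tcondition\treplicate\tcq"]
    for g in list(REFERENCE_GENES) + panel_genes:
        base = 19.0 + (sum(map(ord, g)) % 9) * 0.7
        for trt in TREATMENTS:
            for tis in QPCR_TISSUES:
                fc = 0.0 if g in REFERENCE_GENES else effect_of.get((g, trt, tis), 0.0)
                for cond, mean in (("control", base), ("treated", base - fc)):
                    for rep in range(1, 4):
                        cq = mean + rng.normal(0.0, config.cq_replicate_sd)
                        cq_lines.append(
                            f"{g}\t{trt}\t{tis}\t{cond}\t{rep}\t{cq:.4f}"
                        )
    qpcr_tsv = out / "qpcr_cq.tsv"
    qpcr_tsv.write_text("\n".join(cq_lines) + "\n")

    fold_truth = {
        (g, trt, tis): effect_of.get((g, trt, tis), 0.0)
        for g in panel_genes
        for trt in TREATMENTS
        for tis in QPCR_TISSUES
    }

    truth = SimTruth(
        group_of=group_of,
        duplication_class_of=dup_truth,
        planted_motif_counts=motif_truth,
        planted_fold_changes=fold_truth,
        intron_count_of=intron_of,
        expression_clade_of=clade_of,
        orphans=orphans,
    )
    truth_tsv = out / "truth.tsv"
    truth_tsv.write_text(_truth_to_tsv(truth))

    return SimBundle(
        out_dir=out,
        genome_fasta=genome_fasta,
        gff3=gff3,
        proteome_fasta=proteome,
        domain_hits=domain_hits,
        alignment_fasta=aln_path,
        group_alignments=group_alignments,
        rpkm_tsv=rpkm_tsv,
        qpcr_cq_tsv=qpcr_tsv,
        truth_tsv=truth_tsv,
        truth=truth,
    )


def _truth_to_tsv(truth: SimTruth) -> str:
    lines = ["section\tkey\tvalue"]
    for g in sorted(truth.group_of):
        lines.append(f"group\t{g}\t{truth.group_of[g]}")
    for (a, b), klass in sorted(truth.duplication_class_of.items()):
        lines.append(f"duplication\t{a},{b}\t{klass}")
    for (g, m), n in sorted(truth.planted_motif_counts.items()):
        lines.append(f"motif\t{g},{m}\t{n}")
    for (g, trt, tis), fc in sorted(truth.planted_fold_changes.items()):
        lines.append(f"fold_change\t{g},{trt},{tis}\t{fc:g}")
    for g in sorted(truth.intron_count_of):
        lines.append(f"introns\t{g}\t{truth.intron_count_of[g]}")
    for g in sorted(truth.expression_clade_of):
        lines.append(f"clade\t{g}\t{truth.expression_clade_of[g]}")
    for g in truth.orphans:
        lines.append(f"orphan\t{g}\t1")
    return "\n".join(lines) + "\n"


def read_truth(path: str | Path) -> SimTruth:
    group_of, dup, motif, fold, introns, clade, orphans = {}, {}, {}, {}, {}, {}, []
    with open(path) as fh:
        next(fh)
        for line in fh:
            section, key, value = line.rstrip("\n").split("\t")
            if section == "group":
                group_of[key] = value
            elif section == "duplication":
                a, b = key.split(",")
                dup[(a, b)] = value
            elif section == "motif":
                g, m = key.split(",")
                motif[(g, m)] = int(value)
            elif section == "fold_change":
                g, trt, tis = key.split(",")
                fold[(g, trt, tis)] = float(value)
            elif section == "introns":
                introns[key] = int(value)
            elif section == "clade":
                clade[key] = int(value)
            elif section == "orphan":
                orphans.append(key)
    return SimTruth(group_of, dup, motif, fold, introns, clade, orphans)
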