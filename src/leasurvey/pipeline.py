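"""End-to-end survey pipeline: from inputs (or a simulation) to a report.

Stages run in dependency order: family assignment -> physchem / phylogeny
-> gene structure / duplication / promoters -> expression & qPCR.  Every
stage's outputs are written before the next starts, and all parameters
actually used are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from Bio import SeqIO
from pyfaidx import Fasta

from . import duplication, expression, families, phylo, physchem, promoters, structure
from .errors import ConfigurationError, LeaSurveyError
from .registry import DEFAULT_REGISTRY, GROUPS
from .simulate import REFERENCE_GENES, SimConfig, SimTruth, generate_dataset

log = logging.getLogger("leasurvey")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 1
    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None  # proteome, gff, genome, hits, alignment, rpkm, qpcr
    evalue_cutoff: float = families.DEFAULT_EVALUE_CUTOFF
    bootstrap_reps: int = 100
    similarity_screen_pct: float = 60.0
    min_abre: int = 10
    n_expression_clusters: int = 5

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of a simulate block or explicit input paths is required"
            )
        if self.inputs is not None:
            required = {"proteome", "gff", "genome", "hits", "alignment", "rpkm", "qpcr"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigurationError(f"missing input paths: {sorted(missing)}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"input {key!r}: no such file {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim) if isinstance(sim, dict) else SimConfig()
        return cls(
            out_dir=Path(raw.pop("out_dir", "leasurvey_out")),
            simulate=sim,
            inputs=raw.pop("inputs", None),
            **{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
        )


@dataclass
class SurveyReport:
    group_counts: dict[str, int]
    unassigned: list[str]
    physchem_summary: pd.DataFrame
    newick: str
    intron_summary: dict
    duplication_calls: pd.DataFrame
    duplicated_pct: int
    tandem_clusters: list[tuple[str, ...]]
    motif_counts: pd.DataFrame
    motif_group_averages: pd.DataFrame
    abre_candidates: list[str]
    expression_clusters: dict[str, int]
    qpcr_table: pd.DataFrame
    truth: SimTruth | None = None
    files: dict[str, Path] = field(default_factory=dict)


def run(config: PipelineConfig) -> SurveyReport:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.simulate is not None:
        log.info("simulating dataset (seed=%d)", config.simulate.seed)
        bundle = generate_dataset(config.simulate, out / "sim")
        truth = bundle.truth
        paths = {
            "proteome": bundle.proteome_fasta,
            "gff": bundle.gff3,
            "genome": bundle.genome_fasta,
            "hits": bundle.domain_hits,
            "alignment": bundle.alignment_fasta,
            "rpkm": bundle.rpkm_tsv,
            "qpcr": bundle.qpcr_cq_tsv,
        }
    else:
        paths = {k: Path(v) for k, v in config.inputs.items()}

    files: dict[str, Path] = {}

    def _stage(name):
        log.info("stage: %s", name)

    # --- family assignment ------------------------------------------------
    _stage("assign")
    proteins = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(paths["proteome"]), "fasta")
    }
    hits = families.parse_domain_hits(str(paths["hits"]))
    assignments, orphans = families.assign_by_domain(
        hits, config.evalue_cutoff, all_proteins=sorted(proteins)
    )

    _stage("tree")
    aln = phylo.read_alignment(str(paths["alignment"]))
    tree = phylo.bootstrap(aln, n_reps=config.bootstrap_reps, seed=config.seed)
    newick = phylo.write_newick(tree, str(out / "tree.nwk"))
    files["tree"] = out / "tree.nwk"

    if orphans:
        assignments += families.assign_orphans_by_tree(orphans, tree, assignments)
    assignments = families.reconcile(assignments, tree)
    (out / "assignments.tsv").write_text(families.assignments_table(assignments))
    files["assignments"] = out / "assignments.tsv"
    group_of = {a.protein_id: a.group for a in assignments if a.group is not None}
    unassigned = sorted(a.protein_id for a in assignments if a.group is None)
    group_counts = {
        g: sum(1 for v in group_of.values() if v == g)
        for g in GROUPS
        if any(v == g for v in group_of.values())
    }

    # --- physchem ---------------------------------------------------------
    _stage("physchem")
    records = physchem.profile(proteins)
    physchem.records_frame(records).to_csv(
        out / "physchem.tsv", sep="\t", index=False, float_format="%.2f"
    )
    files["physchem"] = out / "physchem.tsv"
    pc_summary = physchem.summarize_groups(
        [r for r in records if r.protein_id in group_of], group_of
    )
    pc_summary.to_csv(out / "physchem_groups.tsv", sep="\t", float_format="%.3f")

    # --- gene structure ---------------------------------------------------
    _stage("structure")
    models = structure.parse_gff3(str(paths["gff"]), str(paths["genome"]))
    models_by_id = {m.gene_id: m for m in models}
    family_models = [m for m in models if m.gene_id in proteins]
    per_gene, intron_summary = structure.intron_stats(family_models)
    per_gene.to_csv(out / "gene_structure.tsv", sep="\t", index=False)
    files["gene_structure"] = out / "gene_structure.tsv"

    # --- duplication ------------------------------------------------------
    _stage("dupes")
    pairs = duplication.candidate_pairs(
        group_of, tree, proteins, config.similarity_screen_pct
    )
    calls = duplication.classify(pairs, group_of, proteins, models_by_id)
    calls_df = duplication.calls_frame(calls)
    calls_df.to_csv(out / "duplications.tsv", sep="\t", index=False)
    files["duplications"] = out / "duplications.tsv"
    dup_pct = duplication.duplicated_fraction(calls, total_genes=len(proteins))
    clusters = duplication.tandem_clusters(calls)

    # --- promoters --------------------------------------------------------
    _stage("promoters")
    genome = Fasta(str(paths["genome"]))
    motif_counts, motif_hits = promoters.scan_genes(
        family_models, genome, DEFAULT_REGISTRY
    )
    motif_counts.to_csv(out / "motif_counts.tsv", sep="\t")
    files["motif_counts"] = out / "motif_counts.tsv"
    (out / "motif_hits.bed").write_text(promoters.hits_bed(motif_hits))
    group_avg = promoters.group_averages(
        motif_counts.loc[[g for g in motif_counts.index if g in group_of]], group_of
    )
    group_avg.to_csv(out / "motif_group_averages.tsv", sep="\t")
    candidates = promoters.candidate_filter(motif_counts, "ABRE", config.min_abre)

    # --- expression -------------------------------------------------------
    _stage("express")
    rpkm = pd.read_csv(paths["rpkm"], sep="\t", index_col=0)
    logm = expression.log_transform(rpkm)
    logm.to_csv(out / "rpkm_log2.tsv", sep="\t", float_format="%.4f")
    clust = expression.hcluster(logm)
    (out / "gene_order.txt").write_text("\n".join(clust.gene_order) + "\n")
    clusters_map = clust.cut(config.n_expression_clusters)

    _stage("qpcr")
    cq = expression.read_cq_table(str(paths["qpcr"]))
    qpcr_table = expression.qpcr_panel(cq, REFERENCE_GENES)
    qpcr_table.to_csv(out / "qpcr_calls.tsv", sep="\t", index=False, float_format="%.4f")
    files["qpcr"] = out / "qpcr_calls.tsv"

    report = SurveyReport(
        group_counts=group_counts,
        unassigned=unassigned,
        physchem_summary=pc_summary,
        newick=newick,
        intron_summary=intron_summary,
        duplication_calls=calls_df,
        duplicated_pct=dup_pct,
        tandem_clusters=clusters,
        motif_counts=motif_counts,
        motif_group_averages=group_avg,
        abre_candidates=candidates,
        expression_clusters=clusters_map,
        qpcr_table=qpcr_table,
        truth=truth,
        files=files,
    )
    render_report(report, out)
    return report


def render_report(report: SurveyReport, out_dir: str | Path) -> str:
    """Human-readable summary; also written to ``summary.txt``."""
    out = Path(out_dir)
    lines = ["LEA gene family survey", "=" * 40, "", "Group census:"]
    for g, n in report.group_counts.items():
        lines.append(f"  {g:<10} {n}")
    if report.unassigned:
        lines.append(f"  unassigned: {', '.join(report.unassigned)}")
    lines.append("")
    if report.intron_summary:
        s = report.intron_summary
        lines.append(
            f"Intron distribution: {s['pct_intronless']}% intronless, "
            f"{s['pct_one_or_two']}% with 1-2 introns, "
            f"{s['n_three_or_more']} gene(s) with >= 3 (n={s['n_genes']})"
        )
    n_tandem = int((report.duplication_calls["class"] == "tandem").sum())
    n_seg = int((report.duplication_calls["class"] == "segmental").sum())
    lines.append(
        f"Duplications: {n_tandem} tandem pair(s) in "
        f"{len(report.tandem_clusters)} cluster(s), {n_seg} segmental pair(s); "
        f"{report.duplicated_pct}% of genes duplicated"
    )
    lines.append(
        f"ABRE candidates (>= 10 ABREs in 1 kb promoter): {len(report.abre_candidates)}"
    )
    de = report.qpcr_table[report.qpcr_table["call"] != "unchanged"]
    lines.append(
        f"qPCR: {de['gene'].nunique()} gene(s) differentially expressed "
        f"across {len(de)} condition/tissue combinations"
    )
    text = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(text)
    return text


def run_from_yaml(path: str | Path) -> SurveyReport:
    return run(PipelineConfig.from_yaml(path))
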