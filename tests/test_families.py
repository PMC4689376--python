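"""Domain-hit parsing, group assignment, orphan rescue, reconciliation."""

import pytest

from leasurvey.errors import LeaSurveyError, ParseError
from leasurvey import phylo
from leasurvey.families import (
    DomainHit,
    GroupAssignment,
    assign_by_domain,
    assign_orphans_by_tree,
    parse_domain_hits,
    reconcile,
)
from leasurvey.simulate import SimConfig, generate_dataset


def _hit(pid, profile, evalue, score=100.0, start=1, end=20):
    return DomainHit(pid, profile, evalue, score, start, end)


class TestParseDomainHits:
    def test_synthetic_table_parses_fully(self, bundle):
        hits = parse_domain_hits(str(bundle.domain_hits))
        assert len(hits) == 72
        assert all(h.known_profile for h in hits)
        assert {h.group for h in hits} == set(bundle.truth.group_of.values())

    def test_comment_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.domtblout"
        p.write_text("# nothing\n# here\n\n")
        assert parse_domain_hits(str(p)) == []

    def test_bad_evalue_names_line(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        good = (
            "DEHYDRIN PF00257 15 P1 - 100 1e-20 50.0 0.1 1 1 "
            "1e-20 1e-20 50.0 0.1 1 15 11 25 1 100 0.98 -"
        )
        p.write_text(good + "\n" + good.replace("1e-20", "oops", 1) + "\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_domain_hits(str(p))


class TestAssignByDomain:
    def test_single_significant_hit(self):
        assignments, orphans = assign_by_domain([_hit("P1", "PF00257", 1e-20)])
        (a,) = assignments
        assert (a.group, a.evidence) == ("DEHYDRIN", "domain")
        assert orphans == []

    def test_best_hit_among_significant_wins(self):
        hits = [_hit("P2", "PF03168", 1e-30), _hit("P2", "PF02987", 1e-4)]
        assignments, _ = assign_by_domain(hits, evalue_cutoff=1e-5)
        assert assignments[0].group == "LEA_2"

    def test_protein_without_hits_is_orphan(self):
        _, orphans = assign_by_domain(
            [_hit("P1", "PF00257", 1e-20)], all_proteins=["P1", "P3"]
        )
        assert orphans == ["P3"]

    def test_exact_tie_across_groups_is_flagged_ambiguous(self):
        hits = [
            _hit("P4", "PF03760", 1e-10, score=55.0),
            _hit("P4", "PF04927", 1e-10, score=55.0),
        ]
        assignments, orphans = assign_by_domain(hits)
        assert assignments[0].group is None
        assert "ambiguous" in assignments[0].flags
        assert orphans == []

    def test_synthetic_assignments_equal_truth(self, bundle):
        hits = parse_domain_hits(str(bundle.domain_hits))
        assignments, orphans = assign_by_domain(hits)
        assert orphans == []
        assert {a.protein_id: a.group for a in assignments} == bundle.truth.group_of


class TestOrphanRescue:
    def test_recovers_planted_groups(self, tmp_path):
        """With 10% of proteins lacking hits, the tree places >= 90% of
        them back into their planted (monophyletic) groups."""
        b = generate_dataset(SimConfig(seed=3, orphan_fraction=0.1), tmp_path)
        hits = parse_domain_hits(str(b.domain_hits))
        assignments, orphans = assign_by_domain(
            hits, all_proteins=sorted(b.truth.group_of)
        )
        assert sorted(orphans) == b.truth.orphans and len(orphans) == 7
        aln = phylo.read_alignment(str(b.alignment_fasta))
        tree = phylo.nj_build(phylo.p_distance(aln))
        rescued = assign_orphans_by_tree(orphans, tree, assignments)
        correct = sum(
            1 for a in rescued if a.group == b.truth.group_of[a.protein_id]
        )
        assert correct >= 0.9 * len(orphans)
        assert all(a.evidence == "tree" for a in rescued if a.group)

    def test_single_group_tree_assigns_that_group(self):
        tree = phylo.read_newick("(A:1,B:1,(C:1,O:1):1);")
        assignments = [
            GroupAssignment(x, "SMP", "domain") for x in ("A", "B", "C")
        ]
        (res,) = assign_orphans_by_tree(["O"], tree, assignments)
        assert (res.group, res.evidence) == ("SMP", "tree")

    def test_unbreakable_tie_leaves_unassigned(self):
        tree = phylo.read_newick("(O:1,A:1,B:1);")
        assignments = [
            GroupAssignment("A", "LEA_1", "domain"),
            GroupAssignment("B", "SMP", "domain"),
        ]
        (res,) = assign_orphans_by_tree(["O"], tree, assignments)
        assert res.group is None and "unassigned" in res.flags

    def test_orphan_missing_from_tree_is_an_error(self):
        tree = phylo.read_newick("(A:1,B:1,C:1);")
        assignments = [GroupAssignment("A", "SMP", "domain")]
        with pytest.raises(LeaSurveyError, match="ZZZ"):
            assign_orphans_by_tree(["ZZZ"], tree, assignments)


class TestReconcile:
    def test_discordant_domain_assignment_keeps_group_but_flagged(self):
        # X has domain evidence LEA_3 but sits inside an SMP clade
        tree = phylo.read_newick("((S1:0.1,S2:0.1):0.1,(S3:0.1,X:0.1):0.1,L1:5);")
        assignments = [
            GroupAssignment("S1", "SMP", "domain"),
            GroupAssignment("S2", "SMP", "domain"),
            GroupAssignment("S3", "SMP", "domain"),
            GroupAssignment("L1", "LEA_3", "domain"),
            GroupAssignment("X", "LEA_3", "domain"),
        ]
        out = {a.protein_id: a for a in reconcile(assignments, tree)}
        assert out["X"].group == "LEA_3"
        assert "tree_discordant" in out["X"].flags
        assert out["S1"].flags == frozenset()

    def test_tree_rescued_proteins_are_never_flagged(self):
        tree = phylo.read_newick("(A:1,B:1,(C:1,O:1):1);")
        assignments = [
            GroupAssignment(x, "SMP", "domain") for x in ("A", "B", "C")
        ] + [GroupAssignment("O", "LEA_1", "tree")]
        out = {a.protein_id: a for a in reconcile(assignments, tree)}
        assert out["O"].flags == frozenset()

    def test_every_protein_ends_in_exactly_one_state(self, bundle):
        hits = parse_domain_hits(str(bundle.domain_hits))
        assignments, orphans = assign_by_domain(
            hits, all_proteins=sorted(bundle.truth.group_of)
        )
        states = [
            "assigned" if a.group else
            ("ambiguous" if "ambiguous" in a.flags else "unassigned")
            for a in assignments
        ]
        assert len(assignments) + len(orphans) == 72
        assert all(s == "assigned" for s in states)
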