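"""Pairwise alignment metrics and tandem/segmental classification."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from leasurvey.duplication import (
    DuplicationCall,
    PairMetrics,
    candidate_pairs,
    classify,
    duplicated_fraction,
    global_align,
    pair_metrics,
    tandem_clusters,
)
from leasurvey.errors import LeaSurveyError
from leasurvey.structure import GeneModel

from _oracles import nw_score_bruteforce


def _model(gene, chrom, start, end):
    return GeneModel(gene, chrom, "+", (start, end), ((start, end),), (start, end), gene)


class TestGlobalAlign:
    def test_self_alignment_is_identity(self):
        s = "MKVLLEANDPQ"
        res = global_align(s, s)
        assert res.identities == len(s)
        assert res.coverage == 1.0
        assert res.similarity_pct == 100.0

    def test_single_substitution_hand_alignment(self):
        res = global_align("ACDEFG", "ACDKFG")
        assert (res.identities, res.aligned_len) == (5, 6)

    def test_one_residue_mismatch(self):
        res = global_align("A", "G")
        assert (res.aligned_len, res.identities) == (1, 0)

    def test_score_matches_bruteforce_enumeration(self):
        """On tiny proteins the DP score equals an exhaustive enumeration
        over all affine-gap alignments."""
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = "".join(rng.choice(list(aa), size=rng.integers(3, 8)))
            b = "".join(rng.choice(list(aa), size=rng.integers(3, 8)))
            expected = nw_score_bruteforce(a, b, blosum)
            assert global_align(a, b).score == pytest.approx(expected)


class TestClassify:
    def _proteins(self):
        base = "MKVLLEANDPQWRTSYHGFEDCAKLMNPQRST"
        return {"gA": base, "gB": base, "gC": base[:-1] + "W"}

    def test_same_chromosome_close_pair_is_tandem(self):
        proteins = self._proteins()
        models = {
            "gA": _model("gA", "chr1", 1000, 2000),
            "gB": _model("gB", "chr1", 52000, 53000),
        }
        group_of = {"gA": "SMP", "gB": "SMP"}
        (call,) = classify([("gA", "gB")], group_of, proteins, models)
        assert call.klass == "tandem"
        assert call.metrics.genomic_distance_bp == pytest.approx(49999)
        assert call.metrics.spacer_genes == 0

    def test_cross_chromosome_similar_pair_is_segmental(self):
        proteins = self._proteins()
        models = {
            "gA": _model("gA", "chr1", 1000, 2000),
            "gB": _model("gB", "chr2", 1000, 2000),
        }
        (call,) = classify([("gA", "gB")], {"gA": "SMP", "gB": "SMP"}, proteins, models)
        assert call.klass == "segmental"
        assert call.metrics.genomic_distance_bp is None

    def test_low_similarity_cross_chromosome_is_none(self):
        rng = np.random.default_rng(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aa), size=40))
        b = "".join(rng.choice(list(aa), size=40))  # ~5% identity
        models = {
            "gA": _model("gA", "chr1", 1000, 2000),
            "gB": _model("gB", "chr2", 1000, 2000),
        }
        (call,) = classify(
            [("gA", "gB")], {"gA": "SMP", "gB": "SMP"}, {"gA": a, "gB": b}, models
        )
        assert call.klass == "none"

    def test_spacer_genes_exclude_family_members(self):
        proteins = self._proteins()
        models = {
            "gA": _model("gA", "chr1", 1000, 2000),
            "gB": _model("gB", "chr1", 52000, 53000),
            "gC": _model("gC", "chr1", 10000, 11000),  # family gene between
            "SPC1": _model("SPC1", "chr1", 20000, 21000),
        }
        m = pair_metrics(("gA", "gB"), proteins, models, family_ids={"gA", "gB", "gC"})
        assert m.spacer_genes == 1

    def test_classification_symmetric_in_pair_order(self):
        proteins = self._proteins()
        models = {
            "gA": _model("gA", "chr1", 1000, 2000),
            "gB": _model("gB", "chr1", 52000, 53000),
        }
        group_of = {"gA": "SMP", "gB": "SMP"}
        c1 = classify([("gA", "gB")], group_of, proteins, models)[0]
        c2 = classify([("gB", "gA")], group_of, proteins, models)[0]
        assert c1.klass == c2.klass and c1.pair == c2.pair

    def test_missing_gene_is_an_error(self):
        proteins = self._proteins()
        models = {"gA": _model("gA", "chr1", 1000, 2000)}
        with pytest.raises(LeaSurveyError, match="gZ.*missing from annotation"):
            pair_metrics(("gA", "gZ"), proteins, models, set())


class TestSyntheticRecovery:
    def test_candidates_cover_all_planted_pairs(self, bundle, proteins, family_tree):
        pairs = set(
            candidate_pairs(bundle.truth.group_of, family_tree, proteins)
        )
        assert set(bundle.truth.duplication_class_of) <= pairs

    def test_planted_classes_recovered_with_no_false_calls(
        self, bundle, proteins, family_tree, all_models
    ):
        models = {m.gene_id: m for m in all_models}
        pairs = candidate_pairs(bundle.truth.group_of, family_tree, proteins)
        calls = classify(pairs, bundle.truth.group_of, proteins, models)
        called = {c.pair: c.klass for c in calls if c.klass != "none"}
        assert called == bundle.truth.duplication_class_of

    def test_tandem_clusters_match_planted_geometry(
        self, bundle, proteins, family_tree, all_models
    ):
        models = {m.gene_id: m for m in all_models}
        pairs = candidate_pairs(bundle.truth.group_of, family_tree, proteins)
        calls = classify(pairs, bundle.truth.group_of, proteins, models)
        clusters = tandem_clusters(calls)
        assert len(clusters) == 7
        assert sorted(len(c) for c in clusters) == [2, 2, 2, 2, 3, 3, 4]


class TestDuplicatedFraction:
    def _call(self, a, b, klass):
        m = PairMetrics((a, b), 1, 1.0, 100.0, False, None, None)
        return DuplicationCall((a, b), klass, m)

    def test_no_calls_is_zero(self):
        assert duplicated_fraction([], 72) == 0

    def test_hand_division_rounds_to_whole_percent(self):
        calls = [
            self._call(f"g{2*i}", f"g{2*i+1}", "tandem") for i in range(11)
        ] + [self._call("g22", "g0", "segmental")]
        # 23 distinct genes of 72 -> 31.9% -> 32
        assert duplicated_fraction(calls, 72) == 32

    def test_every_gene_called_is_100(self):
        calls = [self._call("a", "b", "segmental")]
        assert duplicated_fraction(calls, 2) == 100
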