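"""Expression transforms, clustering and the delta-delta-Cq caller."""

import numpy as np
import pandas as pd
import pytest

from leasurvey.errors import LeaSurveyError
from leasurvey.expression import (
    QPCRRecord,
    de_call,
    hcluster,
    log_transform,
    qpcr_log2fc,
    qpcr_panel,
    read_cq_table,
    tissue_preference,
)


class TestLogTransform:
    def test_hand_values(self):
        m = pd.DataFrame({"t": [0.0, 7.0, 1.0]}, index=["a", "b", "c"])
        out = log_transform(m)
        assert list(out["t"]) == [0.0, 3.0, 1.0]

    def test_negative_values_rejected(self):
        with pytest.raises(LeaSurveyError):
            log_transform(pd.DataFrame({"t": [-1.0]}))


class TestHCluster:
    def test_identical_profiles_merge_first_at_zero_height(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        res = hcluster(m)
        # a and b are perfectly correlated -> first merge, height 0;
        # c is perfectly anti-correlated -> distance 2 from both
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.linkage[-1, 2] == pytest.approx(2.0)

    def test_zero_variance_gene_flagged_with_max_distance(self):
        m = pd.DataFrame(
            [[1, 2, 3], [5, 5, 5], [1, 2, 3]], index=["a", "flat", "c"]
        )
        res = hcluster(m)
        assert res.zero_variance_genes == ["flat"]

    def test_partition_invariant_to_input_order(self, bundle):
        m = log_transform(pd.read_csv(bundle.rpkm_tsv, sep="\t", index_col=0))
        part1 = hcluster(m).cut(5)
        shuffled = m.sample(frac=1.0, random_state=0)
        part2 = hcluster(shuffled).cut(5)

        def canon(p):
            groups = {}
            for g, c in p.items():
                groups.setdefault(c, set()).add(g)
            return {frozenset(v) for v in groups.values()}

        assert canon(part1) == canon(part2)

    def test_recovers_planted_clades_exactly(self, bundle):
        m = log_transform(pd.read_csv(bundle.rpkm_tsv, sep="\t", index_col=0))
        part = hcluster(m).cut(5)
        truth = bundle.truth.expression_clade_of
        got = {}
        for g, c in part.items():
            got.setdefault(c, set()).add(g)
        want = {}
        for g, c in truth.items():
            want.setdefault(c, set()).add(g)
        assert {frozenset(v) for v in got.values()} == {
            frozenset(v) for v in want.values()
        }


class TestTissuePreference:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((10, 4, 3, 1), "t0"),  # 10 >= 2*4
            ((10, 6, 1, 1), None),  # 10 < 12
            ((0, 0, 0, 0), None),
        ],
    )
    def test_fold_rule(self, values, expected):
        m = pd.DataFrame([values], index=["g"], columns=["t0", "t1", "t2", "t3"])
        assert tissue_preference(m)["g"] == expected


class TestQpcr:
    def _rec(self, gene, ctrl, trt, treatment="PEG", tissue="leaf"):
        return QPCRRecord(gene, treatment, tissue, tuple(ctrl), tuple(trt))

    def test_target_drop_one_cycle_is_plus_one(self):
        target = self._rec("g", [24, 24, 24], [23, 23, 23])
        ref = self._rec("GAPC2", [20, 20, 20], [20, 20, 20])
        assert qpcr_log2fc(target, [ref]) == pytest.approx(1.0)

    def test_everything_unchanged_is_zero(self):
        target = self._rec("g", [24, 24], [24, 24])
        ref = self._rec("GAPC2", [20, 20], [20, 20])
        assert qpcr_log2fc(target, [ref]) == pytest.approx(0.0)

    def test_reference_drop_subtracts(self):
        target = self._rec("g", [24, 24], [24, 24])
        refs = [
            self._rec("GAPC2", [20, 20], [19, 19]),
            self._rec("UPL7", [21, 21], [20, 20]),
        ]
        assert qpcr_log2fc(target, refs) == pytest.approx(-1.0)

    def test_missing_condition_reference_is_an_error(self):
        target = self._rec("g", [24, 24], [24, 24], treatment="NaCl")
        ref = self._rec("GAPC2", [20, 20], [20, 20], treatment="PEG")
        with pytest.raises(LeaSurveyError, match="reference"):
            qpcr_log2fc(target, [ref])

    @pytest.mark.parametrize(
        "fc, expected",
        [(1.0, "up"), (1.7, "up"), (-1.0, "down"), (-0.99, "unchanged"),
         (0.0, "unchanged")],
    )
    def test_de_call_boundaries_inclusive(self, fc, expected):
        assert de_call(fc) == expected

    def test_replicate_and_range_validation(self):
        with pytest.raises(LeaSurveyError, match="replicates"):
            QPCRRecord("g", "PEG", "leaf", (24.0,), (23.0, 23.0))
        with pytest.raises(LeaSurveyError, match="45"):
            QPCRRecord("g", "PEG", "leaf", (24.0, 24.0), (50.0, 50.0))


class TestSyntheticPanel:
    def test_estimates_within_tolerance_of_planted_effects(self, bundle):
        table = qpcr_panel(read_cq_table(str(bundle.qpcr_cq_tsv)))
        truth = bundle.truth.planted_fold_changes
        for row in table.itertuples():
            planted = truth[(row.gene, row.treatment, row.tissue)]
            assert abs(row.log2fc - planted) <= 0.2, row

    def test_calls_reproduce_planted_labels_exactly(self, bundle):
        table = qpcr_panel(read_cq_table(str(bundle.qpcr_cq_tsv)))
        truth = bundle.truth.planted_fold_changes
        for row in table.itertuples():
            planted = truth[(row.gene, row.treatment, row.tissue)]
            expected = "up" if planted >= 1 else "down" if planted <= -1 else "unchanged"
            assert row.call == expected, row
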