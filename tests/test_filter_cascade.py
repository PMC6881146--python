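"""Filter cascade: single stages, ordering, conservation and planted fixtures."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapscore import filter_cascade as fc
from trapscore.enrichment import fscore_table
from trapscore.psm_io import ProteinAnnotation, ValidationError
from trapscore.synthetic_data import CONTROL_ID, planted_violation_fixture

from conftest import record_from_cm, record_from_tech


def records_of(*recs):
    return {r.protein_id: r for r in recs}


CONTROL_REPS = {  # F = 0.6, 0.5, 0.55 -> SD 0.05
    1: ((5, 5), (2, 2)),
    2: ((5, 5), (2, 3)),
    3: ((10, 10), (4, 5)),
}


class TestEnrichedInK:
    def test_two_of_three_retained(self):
        rec = record_from_cm("a", [(5, 0), (5, 0), (4, 6)])  # F = 1, 1, -0.5
        part = fc.filter_enriched_in_k(records_of(rec), k=2, mode="strict")
        assert "a" in part.retained

    def test_one_of_three_removed(self):
        rec = record_from_cm("a", [(10, 8), (10, 11), (10, 11)])
        part = fc.filter_enriched_in_k(records_of(rec), k=2, mode="strict")
        assert "a" in part.removed

    def test_k_exceeding_replicates_errors(self):
        rec = record_from_cm("a", [(5, 0)] * 3)
        with pytest.raises(ValidationError):
            fc.filter_enriched_in_k(records_of(rec), k=4)

    def test_all_replicate_cull_nested_in_compile(self):
        # over every possible enrichment pattern, the all-replicates cull
        # retains a subset of the 2-of-3 compile (the raw-list reduction
        # is structurally a nesting)
        recs = []
        for i, pattern in enumerate(itertools.product([0, 1], repeat=3)):
            cms = [(10, 0) if e else (10, 12) for e in pattern]
            recs.append(record_from_cm(f"p{i}", cms))
        records = records_of(*recs)
        compiled = set(fc.filter_enriched_in_k(records, 2, "strict").retained)
        culled = set(fc.filter_all_replicates(records, "inclusive").retained)
        assert culled <= compiled
        assert compiled == {"p3", "p5", "p6", "p7"}  # >= 2 enriched reps
        assert culled == {"p7"}  # all 3 enriched


class TestAllReplicates:
    @pytest.mark.parametrize(
        "cms,kept",
        [
            ([(5, 5), (10, 7), (10, 1)], True),  # F = 0 boundary counts
            ([(10, 11), (10, 7), (10, 1)], False),  # one negative replicate
            ([(0, 3), (10, 7), (10, 1)], False),  # depleted sentinel
        ],
    )
    def test_inclusive_cull(self, cms, kept):
        rec = record_from_cm("a", cms)
        part = fc.filter_all_replicates(records_of(rec), mode="inclusive")
        assert ("a" in part.retained) == kept


class TestTechnicalConsistency:
    @pytest.mark.parametrize(
        "tech,kept",
        [
            ({1: ((3, 0), (0, 0)), 2: ((2, 2), (0, 0)), 3: ((2, 1), (0, 0))}, False),
            ({1: ((1, 0), (0, 0)), 2: ((2, 2), (0, 0)), 3: ((2, 1), (0, 0))}, True),
            ({1: ((4, 3), (0, 0)), 2: ((2, 2), (0, 0)), 3: ((2, 1), (0, 0))}, True),
        ],
    )
    def test_multiple_vs_zero_rule(self, tech, kept):
        rec = record_from_tech("a", tech)
        part = fc.filter_technical_consistency(records_of(rec))
        assert ("a" in part.retained) == kept


class TestSdVsControl:
    def control(self):
        return record_from_tech(CONTROL_ID, CONTROL_REPS)

    def test_noisier_than_control_removed(self):
        noisy = record_from_cm("a", [(10, 0), (10, 8), (10, 1)])  # SD ~0.44
        part = fc.filter_sd_vs_control(
            records_of(self.control(), noisy), CONTROL_ID
        )
        assert "a" in part.removed
        assert CONTROL_ID in part.retained

    def test_equal_sd_retained(self):
        ctrl = self.control()
        # same F values as the control -> identical SD, strict rule keeps it
        twin = record_from_tech("a", CONTROL_REPS)
        part = fc.filter_sd_vs_control(records_of(ctrl, twin), CONTROL_ID)
        assert "a" in part.retained

    def test_missing_control_errors(self):
        rec = record_from_cm("a", [(5, 0)] * 3)
        with pytest.raises(ValidationError, match="control"):
            fc.filter_sd_vs_control(records_of(rec), CONTROL_ID)

    def test_undefined_control_sd_errors(self):
        ctrl = record_from_cm(CONTROL_ID, [(5, 0), (0, 0), (0, 0)])
        with pytest.raises(ValidationError, match="undefined"):
            fc.filter_sd_vs_control(records_of(ctrl), CONTROL_ID)


class TestRibosomal:
    def test_pattern_flag_and_retention(self):
        recs = records_of(
            record_from_cm("RpL13A", [(5, 0)] * 3),
            record_from_cm("Kap-a2", [(5, 0)] * 3),
            record_from_cm("sneaky", [(5, 0)] * 3),
        )
        annotations = {
            "RpL13A": ProteinAnnotation("RpL13A", display_name="RpL13A"),
            "Kap-a2": ProteinAnnotation("Kap-a2", display_name="Kap-α2"),
            "sneaky": ProteinAnnotation("sneaky", is_ribosomal=True),
        }
        part = fc.filter_ribosomal(recs, annotations)
        assert set(part.removed) == {"RpL13A", "sneaky"}
        assert "Kap-a2" in part.retained


class TestMinTechnicalEnrichment:
    def test_counts_runs_with_bait_above_mock(self):
        four_of_six = record_from_tech(
            "a", {1: ((3, 3), (1, 1)), 2: ((3, 3), (4, 4)), 3: ((3, 3), (1, 1))}
        )
        one_of_six = record_from_tech(
            "b", {1: ((3, 1), (1, 1)), 2: ((1, 1), (4, 4)), 3: ((1, 1), (1, 1))}
        )
        recs = records_of(four_of_six, one_of_six)
        part = fc.filter_min_technical_enrichment(recs, threshold=2)
        assert "a" in part.retained and "b" in part.removed
        assert not fc.filter_min_technical_enrichment(recs, threshold=0).removed


STAGE_NAMES = [
    "all_replicates",
    "technical_consistency",
    "sd_vs_control",
    "ribosomal",
    "min_technical_enrichment",
    "inspection",
]


class TestApplyCascade:
    def config(self):
        return fc.FilterConfig(control_protein_id=CONTROL_ID)

    def run_fixture(self, stage):
        exp, violator = planted_violation_fixture(stage)
        records = fscore_table(
            exp.matrix, exp.layout, "trap", threshold_mode="inclusive"
        )
        retained, trace = fc.apply_cascade(records, exp.annotations, self.config())
        return exp, violator, records, retained, trace

    @pytest.mark.parametrize("stage", STAGE_NAMES)
    def test_planted_violation_removed_at_its_stage(self, stage):
        exp, violator, records, retained, trace = self.run_fixture(stage)
        removed_at = {name: set(removed) for name, removed in trace.stages}
        assert removed_at[stage] == {violator}
        for name, removed in removed_at.items():
            if name != stage:
                assert not removed
        assert set(retained) == set(records) - {violator}
        assert CONTROL_ID in retained and "good_hit" in retained

    @pytest.mark.parametrize("stage", STAGE_NAMES)
    def test_conservation_invariant(self, stage):
        _, _, records, retained, trace = self.run_fixture(stage)
        removed_sets = [set(r) for _, r in trace.stages]
        for a, b in itertools.combinations(removed_sets, 2):
            assert not (a & b)
        assert set().union(*removed_sets, set(retained)) == set(records)

    def test_clean_input_passes_untouched(self):
        records = records_of(
            record_from_tech(CONTROL_ID, CONTROL_REPS),
            record_from_cm("hit", [(5, 0)] * 3),
        )
        retained, trace = fc.apply_cascade(records, {}, self.config())
        assert set(retained) == set(records)
        assert all(not removed for _, removed in trace.stages)

    def test_control_failing_cull_errors(self):
        ctrl = record_from_cm(CONTROL_ID, [(10, 12)] * 3)  # F < 0 everywhere
        with pytest.raises(ValidationError, match="positive control"):
            fc.apply_cascade(records_of(ctrl), {}, self.config())

    def test_stage_order_changes_attribution_not_outcome(self):
        # with one independent violator per stage, applying the stage
        # partitions in any order yields the same final retained set
        combined = {}
        annotations = {}
        for stage in STAGE_NAMES:
            exp, violator = planted_violation_fixture(stage)
            records = fscore_table(
                exp.matrix, exp.layout, "trap", threshold_mode="inclusive"
            )
            combined[violator] = records[violator]
            annotations.update(
                {violator: exp.annotations[violator]}
            )
            if CONTROL_ID not in combined:
                combined[CONTROL_ID] = records[CONTROL_ID]
                combined["good_hit"] = records["good_hit"]
                annotations[CONTROL_ID] = exp.annotations[CONTROL_ID]
                annotations["good_hit"] = exp.annotations["good_hit"]

        stages = {
            "all_replicates": lambda r: fc.filter_all_replicates(r, "inclusive"),
            "technical_consistency": fc.filter_technical_consistency,
            "sd_vs_control": lambda r: fc.filter_sd_vs_control(r, CONTROL_ID),
            "ribosomal": lambda r: fc.filter_ribosomal(r, annotations),
            "min_technical_enrichment": (
                lambda r: fc.filter_min_technical_enrichment(r, 2)
            ),
            "inspection": lambda r: fc.filter_inspection(r, annotations),
        }
        outcomes = set()
        for order in itertools.permutations(STAGE_NAMES):
            current = dict(combined)
            for name in order:
                current = stages[name](current).retained
            outcomes.add(frozenset(current))
        assert outcomes == {frozenset({CONTROL_ID, "good_hit"})}

    @given(
        data=st.lists(
            st.tuples(
                st.lists(
                    st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=3,
                    max_size=3,
                )
            ),
            min_size=0,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_random_fixtures_conserve_and_shrink(self, data):
        records = records_of(
            record_from_tech(CONTROL_ID, CONTROL_REPS),
            *[
                record_from_cm(f"p{i}", cms)
                for i, (cms,) in enumerate(data)
            ],
        )
        retained, trace = fc.apply_cascade(records, {}, self.config())
        all_removed = trace.removed_ids
        assert set(retained) | all_removed == set(records)
        assert not (set(retained) & all_removed)
        # adding a stage never enlarges the retained set: each prefix of
        # the trace retains a superset of the final set
        surviving = set(records)
        for _, removed in trace.stages:
            assert set(retained) <= surviving
            surviving -= set(removed)
        assert surviving == set(retained)
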