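import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triosift as ts
from oracle_utils import brute_force_candidates, random_vset

CFG = ts.CascadeConfig()


def one_record_set(
    af=1e-4,
    cls=ts.Classification.uncertain,
    cons=ts.Consequence.missense,
    gts=((0, 1), (0, 1), (0, 0)),
    depths=(100, 100, 100),
):
    samples = ("A1", "A2", "U1")
    calls = {
        s: ts.GenotypeCall(s, g, d) for s, g, d in zip(samples, gts, depths)
    }
    rec = ts.VariantRecord(
        "1", 1000, "A", "G", calls=calls,
        annotation=ts.AnnotationBundle(
            gene_symbol="G1", pop_af=af, classification=cls, consequence=cons
        ),
    )
    return ts.VariantSet.from_records([rec], samples)


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "af,kept",
        [
            (0.5, False),        # common variant far above the cut-off
            (None, True),        # absent from the frequency resource: novel = rare
            (1e-4, True),        # rare candidate
            (0.01, False),       # exactly 1%: strict-less keeps it out
            (0.0099, True),
        ],
    )
    def test_default_policy(self, af, kept):
        out = ts.filter_by_population_frequency(one_record_set(af=af), CFG)
        assert (len(out) == 1) is kept

    def test_missing_af_can_be_made_failing(self):
        cfg = ts.CascadeConfig(missing_af_passes=False)
        assert len(ts.filter_by_population_frequency(one_record_set(af=None), cfg)) == 0


class TestAffectedSharing:
    @pytest.mark.parametrize(
        "gts,kept",
        [
            (((0, 1), (0, 1), (0, 0)), True),   # both het
            (((0, 1), (1, 1), (0, 0)), True),   # hom-alt still counts as shared
            (((0, 1), (0, 0), (0, 0)), False),  # one sibling lacks the allele
            (((0, 1), None, (0, 0)), False),    # missing genotype, strict policy
        ],
    )
    def test_default_policy(self, trio_design, gts, kept):
        out = ts.keep_shared_by_affected(one_record_set(gts=gts), trio_design, CFG)
        assert (len(out) == 1) is kept

    def test_lenient_policy_keeps_missing_affected(self, trio_design):
        cfg = ts.CascadeConfig(affected_missing_gt_policy="lenient_keep")
        vset = one_record_set(gts=((0, 1), None, (0, 0)))
        assert len(ts.keep_shared_by_affected(vset, trio_design, cfg)) == 1


class TestUnaffectedExclusion:
    @pytest.mark.parametrize(
        "gts,kept",
        [
            (((0, 1), (0, 1), (0, 1)), False),  # control carries the allele
            (((0, 1), (0, 1), (0, 0)), True),
            (((0, 1), (0, 1), None), False),    # absence unconfirmed, strict policy
        ],
    )
    def test_default_policy(self, trio_design, gts, kept):
        out = ts.drop_unaffected_carriers(one_record_set(gts=gts), trio_design, CFG)
        assert (len(out) == 1) is kept

    def test_lenient_policy_keeps_missing_control(self, trio_design):
        cfg = ts.CascadeConfig(unaffected_missing_gt_policy="lenient_keep")
        vset = one_record_set(gts=((0, 1), (0, 1), None))
        assert len(ts.drop_unaffected_carriers(vset, trio_design, cfg)) == 1

    def test_zero_unaffected_is_identity(self):
        design = ts.FamilyDesign(
            samples=(
                ts.SampleInfo("A1", affected=True),
                ts.SampleInfo("A2", affected=True),
                ts.SampleInfo("U1", affected=True),  # everyone affected
            )
        )
        vset = one_record_set(gts=((0, 1), (0, 1), (0, 1)))
        assert len(ts.drop_unaffected_carriers(vset, design, CFG)) == 1


class TestClassConsequence:
    @pytest.mark.parametrize(
        "cls,cons,kept",
        [
            (ts.Classification.benign, ts.Consequence.missense, False),
            (ts.Classification.likely_benign, ts.Consequence.missense, False),
            (ts.Classification.uncertain, ts.Consequence.synonymous, False),
            (ts.Classification.uncertain, ts.Consequence.missense, True),
            (None, ts.Consequence.missense, True),  # missing class treated as VUS
            (ts.Classification.pathogenic, ts.Consequence.intronic, False),
        ],
    )
    def test_default_policy(self, cls, cons, kept):
        out = ts.drop_benign_and_silent(one_record_set(cls=cls, cons=cons), CFG)
        assert (len(out) == 1) is kept

    def test_literal_benign_only_reading_is_one_flag_away(self):
        cfg = ts.CascadeConfig(excluded_classes=frozenset({ts.Classification.benign}))
        vset = one_record_set(cls=ts.Classification.likely_benign)
        assert len(ts.drop_benign_and_silent(vset, cfg)) == 1


class TestDepthFilter:
    @pytest.mark.parametrize(
        "depths,kept",
        [
            ((100, 19, 100), False),   # one sample below threshold
            ((20, 20, 20), True),      # boundary: >= passes
            ((100, 100, 100), True),
            ((None, None, None), True),  # no depth assertion anywhere
            ((None, 100, 100), True),    # missing depth makes no assertion
        ],
    )
    def test_default_policy(self, trio_design, depths, kept):
        out = ts.enforce_min_depth(one_record_set(depths=depths), trio_design, CFG)
        assert (len(out) == 1) is kept


class TestRunCascade:
    def test_empty_input_gives_empty_output_and_zero_counts(self, trio_design):
        vset = ts.VariantSet.from_records([], ["A1", "A2", "U1"])
        cands, trace = ts.run_cascade(vset, trio_design)
        assert len(cands) == 0
        assert all(sc.n_in == 0 and sc.n_out == 0 for sc in trace.stage_counts)

    def test_trace_telescopes_and_partitions(self, trio_design):
        vset = random_vset(seed=7, n=120)
        cands, trace = ts.run_cascade(vset, trio_design)
        trace.check_telescoping()
        assert trace.survivors() == set(cands.keys)
        assert set(trace.removal_stage) == set(vset.keys)
        removed = sum(len(trace.removed_at(s)) for s in
                      list(ts.cascade.DEFAULT_STAGE_ORDER) + [ts.cascade.STAGE_REPORT])
        assert removed + len(cands) == len(vset)

    def test_nonsense_survivor_excluded_from_missense_report(self, trio_design):
        vset = one_record_set(cons=ts.Consequence.nonsense)
        cands, trace = ts.run_cascade(vset, trio_design)
        assert len(cands) == 0
        assert trace.removal_stage[vset.records[0].key] == ts.cascade.STAGE_REPORT

    def test_snv_only_flag_drops_indels(self, trio_design):
        samples = ("A1", "A2", "U1")
        calls = {
            s: ts.GenotypeCall(s, (0, 1) if s != "U1" else (0, 0), 100)
            for s in samples
        }
        indel = ts.VariantRecord(
            "1", 500, "AT", "A", calls=calls,
            annotation=ts.AnnotationBundle(
                pop_af=1e-4, consequence=ts.Consequence.missense,
                classification=ts.Classification.uncertain,
            ),
        )
        vset = ts.VariantSet.from_records([indel], samples)
        assert len(ts.run_cascade(vset, trio_design)[0]) == 1
        cfg = ts.CascadeConfig(snv_only=True)
        assert len(ts.run_cascade(vset, trio_design, cfg)[0]) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, trio_design, seed):
        vset = random_vset(seed=seed, n=200)
        cands, _ = ts.run_cascade(vset, trio_design)
        assert set(cands.keys) == brute_force_candidates(vset, trio_design, CFG)

    def test_candidates_invariant_under_stage_order(self, trio_design):
        vset = random_vset(seed=3, n=40)
        baseline, _ = ts.run_cascade(vset, trio_design)
        for perm in itertools.permutations(ts.cascade.DEFAULT_STAGE_ORDER):
            cands, _ = ts.run_cascade(vset, trio_design, stage_order=perm)
            assert set(cands.keys) == set(baseline.keys)

    def test_monotone_in_af_threshold_and_depth(self, trio_design):
        for seed in (0, 1, 2):
            vset = random_vset(seed=seed, n=150)
            counts = [
                len(ts.run_cascade(vset, trio_design, ts.CascadeConfig(af_threshold=t))[0])
                for t in (0.05, 0.01, 0.001)
            ]
            assert counts == sorted(counts, reverse=True)
            counts = [
                len(ts.run_cascade(vset, trio_design, ts.CascadeConfig(min_depth=d))[0])
                for d in (0, 20, 50)
            ]
            assert counts == sorted(counts, reverse=True)


class TestConfig:
    def test_report_must_be_subset_of_allowed(self):
        with pytest.raises(ts.TriosiftError):
            ts.CascadeConfig(
                allowed_consequences=frozenset({ts.Consequence.missense}),
                report_consequences=frozenset({ts.Consequence.nonsense}),
            )

    def test_af_threshold_bounds(self):
        with pytest.raises(ts.TriosiftError):
            ts.CascadeConfig(af_threshold=0.0)

    def test_config_file_round_trip(self, tmp_path):
        p = tmp_path / "cascade.cfg"
        p.write_text(
            "af_threshold = 0.005\n"
            "min_depth = 30  # stricter coverage\n"
            "excluded_classes = benign\n"
            "snv_only = true\n"
        )
        cfg = ts.read_config(p)
        assert cfg.af_threshold == pytest.approx(0.005)
        assert cfg.min_depth == 30
        assert cfg.excluded_classes == frozenset({ts.Classification.benign})
        assert cfg.snv_only is True

    def test_unknown_config_key_fatal(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("maximum_depth = 10\n")
        with pytest.raises(ts.TriosiftError, match="maximum_depth"):
            ts.read_config(p)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    af=st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    cls=st.sampled_from([None] + list(ts.Classification)),
    cons=st.sampled_from([None] + list(ts.Consequence)),
    gt_a1=st.sampled_from([None, (0, 0), (0, 1), (1, 1)]),
    gt_a2=st.sampled_from([None, (0, 0), (0, 1), (1, 1)]),
    gt_u1=st.sampled_from([None, (0, 0), (0, 1), (1, 1)]),
    depths=st.tuples(*[st.one_of(st.none(), st.integers(0, 60))] * 3),
)
def test_single_record_cascade_agrees_with_rule_conjunction(
    af, cls, cons, gt_a1, gt_a2, gt_u1, depths
):
    """Property: for any one-record input, the staged cascade equals the
    brute-force conjunction of the filtering rules."""
    design = ts.FamilyDesign(
        samples=(
            ts.SampleInfo("A1", affected=True),
            ts.SampleInfo("A2", affected=True),
            ts.SampleInfo("U1", affected=False),
        )
    )
    vset = one_record_set(af=af, cls=cls, cons=cons, gts=(gt_a1, gt_a2, gt_u1), depths=depths)
    cands, _ = ts.run_cascade(vset, design)
    assert set(cands.keys) == brute_force_candidates(vset, design, CFG)
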