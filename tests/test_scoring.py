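import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pmrtox import (
    ActivityTrace,
    PHASES,
    PMRProtocol,
    classify_response,
    compute_phase_auc,
    flag_nonresponders,
    flag_untrackable,
    lowest_effect_concentration,
    remove_dead,
)
from pmrtox.scoring import AUC_COLUMNS


def second_trace(values, **meta):
    v = np.asarray(values, dtype=float)
    kwargs = dict(well_id="A1", time_s=np.arange(v.size, dtype=float),
                  activity=v, sampling="second")
    kwargs.update(meta)
    return ActivityTrace(**kwargs)


def scores_frame(triples, status="alive", group="control"):
    rows = []
    for i, (b, e, r) in enumerate(triples):
        rows.append(dict(plate="P1", well_id=f"W{i}", status=status, group=group,
                         concentration=0.0, age_hpf=30.0, auc_background=b,
                         auc_excitatory=e, auc_refractory=r, included=True,
                         exclusion_reason="none"))
    return pd.DataFrame(rows)


class TestPhaseAUC:
    def test_all_zero_trace_scores_zero(self, protocol):
        ps = compute_phase_auc(second_trace(np.zeros(50)), protocol)
        assert ps.triple() == (0.0, 0.0, 0.0)

    def test_constant_activity_window_length_ratio(self, protocol):
        """30 s background window carries three times the area of the 10 s
        excitatory window under constant activity."""
        ps = compute_phase_auc(second_trace(np.ones(50)), protocol)
        assert ps.auc_background == pytest.approx(3 * ps.auc_excitatory)

    def test_three_point_toy_window_trapezoid(self, toy_protocol):
        # background spans samples at t = 0, 1, 2 -> trapezoid of (0, .2, .4)
        ps = compute_phase_auc(second_trace([0.0, 0.2, 0.4, 0.0]), toy_protocol)
        assert ps.auc_background == pytest.approx(0.4)

    def test_short_trace_rejected(self, protocol):
        with pytest.raises(ValueError, match="span"):
            compute_phase_auc(second_trace(np.ones(30)), protocol)

    @given(arrays(float, 50, elements=st.floats(0, 1)))
    @settings(max_examples=50, deadline=None)
    def test_phase_aucs_sum_to_whole_trace_auc(self, values):
        protocol = PMRProtocol()
        ps = compute_phase_auc(second_trace(values), protocol)
        whole = np.trapezoid(values, np.arange(50.0))
        assert sum(ps.triple()) == pytest.approx(whole, abs=1e-9)


class TestFilters:
    def test_remove_dead_bookkeeping(self):
        df = pd.concat([
            scores_frame([(1, 1, 1)] * 3),
            scores_frame([(0, 0, 0)] * 2, status="dead"),
        ], ignore_index=True)
        out = remove_dead(df)
        assert (out["exclusion_reason"] == "dead").sum() == 2
        assert out["included"].sum() == 3

    def test_remove_dead_requires_flags(self):
        df = scores_frame([(1, 1, 1)]).drop(columns="status")
        with pytest.raises(ValueError, match="viability"):
            remove_dead(df)

    def test_all_dead_leaves_empty_included_set(self):
        out = remove_dead(scores_frame([(0, 0, 0)] * 4, status="dead"))
        assert out["included"].sum() == 0

    def test_partial_zero_triple_is_retained(self):
        df = scores_frame([(0.0, 0.1, 0.0)])
        out, rate = flag_nonresponders(df)
        assert out["included"].all()
        assert rate == 0.0

    @pytest.mark.parametrize("n_zero,expected", [(29, 4.8), (2, 0.3), (4, 0.7)])
    def test_nonresponder_rates_match_cohort_bookkeeping(self, n_zero, expected):
        """All-zero AUC triples among 603 living embryos yield the reported
        percentages to one decimal."""
        df = scores_frame([(0, 0, 0)] * n_zero + [(1, 2, 1)] * (603 - n_zero))
        out, rate = flag_nonresponders(df)
        assert round(100 * rate, 1) == expected
        assert (out["exclusion_reason"] == "nonresponder").sum() == n_zero

    def test_flag_nonresponders_is_idempotent(self):
        df = scores_frame([(0, 0, 0)] * 3 + [(1, 1, 1)] * 7)
        once, r1 = flag_nonresponders(df)
        twice, r2 = flag_nonresponders(once)
        pd.testing.assert_frame_equal(once, twice)
        assert r1 == r2

    def test_controls_only_scope_spares_treated_zeros(self):
        ctrl = scores_frame([(0, 0, 0), (1, 1, 1)])
        trt = scores_frame([(0, 0, 0)], group="treatment")
        trt["well_id"] = "T0"
        out, _ = flag_nonresponders(pd.concat([ctrl, trt], ignore_index=True))
        assert out.loc[out["group"] == "treatment", "included"].all()
        out_all, _ = flag_nonresponders(
            pd.concat([ctrl, trt], ignore_index=True), scope="all"
        )
        assert not out_all.loc[out_all["group"] == "treatment", "included"].all()

    def test_untrackable_wells_excluded(self):
        df = scores_frame([(1, 1, 1)] * 2, status="untrackable")
        out = flag_untrackable(df)
        assert (out["exclusion_reason"] == "untrackable").all()


class TestClassifyResponse:
    def test_identical_groups_labelled_normal_with_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        s = classify_response(vals, vals, "excitatory")
        assert s.label == "normal"
        assert s.p_value == pytest.approx(1.0)

    def test_constant_equal_groups_handled(self):
        s = classify_response([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], "background")
        assert s.label == "normal" and s.p_value == 1.0

    def test_clear_hypoactivity_detected(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(10, 1, 32)
        trt = rng.normal(2, 1, 32)
        s = classify_response(trt, ctrl, "excitatory")
        assert s.label == "hypoactive" and s.p_value < 1e-10

    def test_clear_hyperactivity_detected(self):
        rng = np.random.default_rng(0)
        s = classify_response(rng.normal(10, 1, 32), rng.normal(2, 1, 32),
                              "background")
        assert s.label == "hyperactive"

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_label_invariant_under_common_rescaling(self, k):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(10, 2, 20)
        trt = rng.normal(7, 2, 20)
        base = classify_response(trt, ctrl, "excitatory")
        scaled = classify_response(trt * k, ctrl * k, "excitatory")
        assert scaled.label == base.label
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6)

    def test_undersized_group_not_evaluable(self):
        s = classify_response([1.0], [1.0, 2.0, 3.0], "refractory")
        assert s.label == "not_evaluable"

    def test_turbid_group_not_evaluable(self):
        trt = scores_frame([(1, 1, 1)] * 4, group="treatment",
                           status="untrackable")
        trt = flag_untrackable(trt)
        ctrl = scores_frame([(1, 1, 1)] * 4)
        s = classify_response(trt, ctrl, "excitatory", concentration=100.0)
        assert s.label == "not_evaluable"


class TestLowestEffect:
    def summaries(self, entries):
        return pd.DataFrame(
            [dict(concentration=c, phase=p, label=lab) for c, p, lab in entries]
        )

    def test_minimum_significant_concentration_reported(self):
        s = self.summaries([(10.7, "excitatory", "hypoactive"),
                            (50.0, "excitatory", "hypoactive"),
                            (10.7, "background", "normal")])
        out = lowest_effect_concentration(s)
        assert out["excitatory"] == 10.7
        assert out["background"] == "None"

    def test_effect_only_above_turbidity_cutoff_censored(self):
        s = self.summaries([(100.0, "background", "hypoactive")])
        assert lowest_effect_concentration(s, trackable_max=50.0)["background"] == ">50"

    def test_no_significant_entries_reports_none(self):
        s = self.summaries([(10.0, p, "normal") for p in PHASES])
        assert set(lowest_effect_concentration(s).values()) == {"None"}
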