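import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmrtox import (
    ConcResponseTable,
    DissolutionProfile,
    TrimmedSpearmanKarber,
    TSKEstimationError,
    abbott_correct,
    adjust_ionic,
    ec50_malformation,
    format_estimate,
    smooth_monotone,
    tsk_estimate,
)


def table(conc, affected, n=32, control_n=32, control_affected=0):
    conc = np.asarray(conc, dtype=float)
    return ConcResponseTable(conc, np.full(conc.size, n), np.asarray(affected),
                             control_n=control_n, control_affected=control_affected)


class TestAbbott:
    def test_zero_control_is_identity(self):
        p = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(abbott_correct(p, 0.0), p)

    def test_worked_example(self):
        np.testing.assert_allclose(
            abbott_correct([0.1, 0.55, 1.0], 0.1), [0.0, 0.5, 1.0]
        )

    def test_background_level_maps_to_zero(self):
        np.testing.assert_allclose(abbott_correct([0.2, 0.2, 0.2], 0.2), 0.0)

    def test_total_control_response_rejected(self):
        with pytest.raises(TSKEstimationError):
            abbott_correct([0.5], 1.0)


class TestSmoothMonotone:
    def test_monotone_input_unchanged(self):
        p = [0.0, 0.2, 0.5, 1.0]
        np.testing.assert_allclose(smooth_monotone(p), p)

    def test_violating_pair_averaged(self):
        np.testing.assert_allclose(
            smooth_monotone([0.0, 0.6, 0.4, 1.0]), [0.0, 0.5, 0.5, 1.0]
        )

    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=8),
        st.lists(st.integers(1, 64), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_pava_properties(self, p, w):
        w = np.asarray(w[: len(p)], dtype=float)
        out = smooth_monotone(p, w)
        assert np.all(np.diff(out) >= -1e-12)
        assert out.min() >= min(p) - 1e-12 and out.max() <= max(p) + 1e-12
        # weighted mean preserved
        assert np.dot(out, w) == pytest.approx(np.dot(p, w))


class TestTSKEstimate:
    def test_cdf_crossing_middle_concentration(self):
        res = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        assert res.estimate == pytest.approx(10.0)
        assert res.censoring == "none"

    def test_classical_spearman_karber_agreement(self):
        """With trim 0, no control mortality and monotone proportions hitting
        0 and 1, the estimate equals the classical Spearman-Karber mean."""
        conc = np.array([1.0, 3.16, 10.0, 31.6, 100.0])
        aff = np.array([0, 6, 17, 28, 32])
        res = tsk_estimate(table(conc, aff), trim=0.0)
        x = np.log10(conc)
        p = aff / 32
        mu = np.sum(np.diff(p) * (x[:-1] + x[1:]) / 2)
        assert np.log10(res.estimate) == pytest.approx(mu, abs=1e-12)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, k):
        t0 = table([1.0, 3.16, 10.0, 31.6, 100.0], [0, 6, 17, 28, 32])
        base = tsk_estimate(t0, trim=0.0).estimate
        scaled = tsk_estimate(t0.scaled(k), trim=0.0).estimate
        assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_zero_mortality_censored_above_highest(self):
        res = tsk_estimate(table([5, 50, 500], [0, 0, 0]))
        assert res.censoring == "above_highest"
        assert format_estimate(res) == ">500"

    def test_total_response_censored_below_lowest(self):
        res = tsk_estimate(table([5, 50, 500], [32, 32, 32]))
        assert res.censoring == "below_lowest"
        assert format_estimate(res) == "<5"

    def test_trim_half_rejected(self):
        with pytest.raises(TSKEstimationError):
            TrimmedSpearmanKarber(table([1, 10], [0, 32]), trim=0.5)

    def test_single_concentration_rejected(self):
        with pytest.raises(TSKEstimationError):
            tsk_estimate(table([10.0], [16]))

    def test_unreachable_trim_quantiles_fail_explicitly(self):
        # proportions span only [0.25, 0.75]: no candidate trim interpolates
        with pytest.raises(TSKEstimationError, match="interpolable"):
            tsk_estimate(table([1, 10, 100], [8, 16, 24]), trim="auto")

    def test_auto_trim_escalates_when_tails_incomplete(self):
        # tails at 1/32 = 0.03 and 31/32 = 0.97 need a 5% trim
        res = tsk_estimate(table([1, 3.16, 10, 31.6, 100], [1, 6, 17, 28, 31]),
                           trim="auto")
        assert res.trim == 0.05

    def test_control_mortality_shifts_through_abbott(self):
        clean = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        # same underlying curve plus 25% background mortality everywhere
        noisy = tsk_estimate(
            table([1, 10, 100], [8, 20, 32], control_n=32, control_affected=8),
            trim=0.0,
        )
        assert noisy.estimate == pytest.approx(clean.estimate)

    def test_malformed_counts_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 1"):
            table([1, 10], [0, 40])

    def test_summary_mentions_estimate_and_trim(self):
        res = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        text = res.summary()
        assert "LC50: 10" in text and "trim: 0" in text


class TestIonicAdjustment:
    profile = DissolutionProfile("silver-25nm", 0.012, "01 June 2016")

    def test_fraction_one_is_identity(self):
        res = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        adj = adjust_ionic(res, DissolutionProfile("m", 1.0))
        assert adj.estimate == pytest.approx(res.estimate)

    def test_silver_worked_example_two_decimals(self):
        """An LC50 of 3.68 rescaled by a 1.2% free-ion fraction reports as
        0.04 at two decimals."""
        base = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        unadjusted = adjust_ionic(base, DissolutionProfile("m", 0.368))
        assert unadjusted.estimate == pytest.approx(3.68)
        adj = adjust_ionic(unadjusted, self.profile)
        assert adj.estimate == pytest.approx(0.04416)
        assert format_estimate(adj, decimals=2) == "0.04"

    def test_adjust_commutes_with_estimation(self):
        t0 = table([1, 3.16, 10, 31.6, 100], [0, 6, 17, 28, 32])
        est_then_adjust = adjust_ionic(tsk_estimate(t0, trim=0.0), self.profile)
        adjust_then_est = tsk_estimate(adjust_ionic(t0, self.profile), trim=0.0)
        assert est_then_adjust.estimate == pytest.approx(adjust_then_est.estimate)

    def test_zero_fraction_rejected(self):
        res = tsk_estimate(table([1, 10, 100], [0, 16, 32]), trim=0.0)
        with pytest.raises(ValueError, match="ionic"):
            adjust_ionic(res, DissolutionProfile("m", 0.0))

    def test_provenance_recorded(self):
        res = adjust_ionic(tsk_estimate(table([1, 10, 100], [0, 16, 32]),
                                        trim=0.0), self.profile)
        prov = res.provenance["ionic_adjustment"]
        assert prov["material_id"] == "silver-25nm"
        assert prov["free_ion_fraction"] == 0.012


class TestEC50Malformation:
    def endpoints(self, rows):
        return pd.DataFrame(rows, columns=["concentration", "alive",
                                           "bent_tail", "edema"])

    def test_no_malformations_censored_like_nd(self):
        rows = [(c, True, False, False) for c in [0, 5, 50, 500] for _ in range(8)]
        res = ec50_malformation(self.endpoints(rows))
        assert res.censoring == "above_highest"
        assert format_estimate(res) == ">500"

    def test_everything_affected_censored_below_lowest(self):
        rows = [(c, True, True, False) for c in [5, 50, 500] for _ in range(8)]
        res = ec50_malformation(self.endpoints(rows))
        assert res.censoring == "below_lowest"

    def test_all_dead_group_excluded(self, caplog):
        import logging

        rows = [(0, True, False, False)] * 8
        rows += [(5, True, False, False)] * 8
        rows += [(50, True, True, False)] * 8
        rows += [(500, False, False, False)] * 8  # all dead at the top dose
        with caplog.at_level(logging.INFO, logger="pmrtox.doseresponse"):
            res = ec50_malformation(self.endpoints(rows))
        assert "all dead" in caplog.text
        assert 500 not in res.table.concentration

    def test_any_endpoint_counts_as_affected(self):
        rows = [(0, True, False, False)] * 8
        rows += [(1, True, False, False)] * 8
        rows += [(10, True, False, True)] * 4 + [(10, True, False, False)] * 4
        rows += [(100, True, True, True)] * 8
        res = ec50_malformation(self.endpoints(rows))
        assert res.endpoint == "EC50"
        assert res.estimate == pytest.approx(10.0)
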