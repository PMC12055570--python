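"""Flux scores: R partition, T accounting, RUF, reference, pre/post report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureaflux.metrics import (
    ControlReference,
    MatrixMismatchWarning,
    RUFResult,
    UndefinedMetricError,
    build_control_reference,
    compare_pre_post,
    compute_R,
    compute_RUF,
    compute_T,
    pathway_shares,
    ruf_repeatability_cv,
    tracer_recovery,
)

AUCS = {
    "urea": 3.0,
    "citrulline": 1.0,
    "arginine": 0.5,
    "glutamine": 4.0,
    "glycine": 1.0,
    "glutamate": 0.5,
}


class TestR:
    def test_only_urea(self):
        aucs = dict.fromkeys(AUCS, 0.0) | {"urea": 2.0}
        assert compute_R(aucs) == 1.0

    def test_only_glutamine(self):
        aucs = dict.fromkeys(AUCS, 0.0) | {"glutamine": 2.0}
        assert compute_R(aucs) == 0.0

    def test_direct_partition(self):
        assert compute_R(AUCS) == pytest.approx(4.5 / 10.0)

    def test_excluded_metabolite_dropped_from_both_sums(self):
        r = compute_R(AUCS, excluded=("glutamine",))
        assert r == pytest.approx(4.5 / 6.0)

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_R(dict.fromkeys(AUCS, 0.0))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_bounds(self, c):
        scaled = {m: v * c for m, v in AUCS.items()}
        r = compute_R(scaled)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(compute_R(AUCS), rel=1e-9)


class TestT:
    def test_zero_aucs_give_zero(self):
        T, _ = compute_T(dict.fromkeys(AUCS, 0.0), 2.0, 70.0)
        assert T == 0.0

    def test_measured_equals_theoretical_gives_100(self):
        """An AUC constructed to hold the whole dose in the urea pool maps
        to exactly T = 100."""
        from ureaflux.constants import DEFAULT_POOLS_UMOL_L
        from ureaflux.simulate import dose_umol

        weight, v_dist, span = 70.0, 0.6, 120.0
        dose = dose_umol(2.0, weight)
        target_auc = dose / (DEFAULT_POOLS_UMOL_L["urea"] * v_dist * weight) * 100 * span
        aucs = dict.fromkeys(AUCS, 0.0) | {"urea": target_auc}
        T, partition = compute_T(aucs, 2.0, weight)
        assert T == pytest.approx(100.0)
        assert partition["urea"] == pytest.approx(1.0)

    def test_partition_shares_sum_to_one(self):
        _, partition = tracer_recovery(AUCS, 2.0, 70.0)
        assert sum(partition.values()) == pytest.approx(1.0)
        shares = pathway_shares(partition)
        assert shares["urea_cycle"] + shares["alternative"] == pytest.approx(1.0)

    def test_zero_dose_guard(self):
        with pytest.raises(UndefinedMetricError):
            tracer_recovery(AUCS, 0.0, 70.0)

    def test_missing_pool_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            compute_T(AUCS, 2.0, 70.0, pools={"urea": 5000.0})


def _ref(R=0.7, T=50.0):
    return ControlReference(
        R_bar_C=R, T_bar_C=T, ruf_mean=100.0, ruf_sd=10.0,
        ruf_range=(90.0, 110.0), n_controls=5,
    )


class TestRUF:
    def test_control_identity(self):
        assert compute_RUF(0.7, 50.0, _ref()) == pytest.approx(100.0)

    def test_linearity_in_R(self):
        assert compute_RUF(0.35, 50.0, _ref()) == pytest.approx(50.0)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedMetricError):
            compute_RUF(0.7, 50.0, _ref(R=0.0))

    def test_zero_flux_pipeline_gives_near_zero_ruf(self, clean_control_cohort, config):
        """A complete enzyme block (residual_flux=0, noise off) scores ≈ 0."""
        from ureaflux.pipeline import run_pipeline
        from ureaflux.simulate import NOISE_FREE, DiseasePreset, simulate_cohort

        null = simulate_cohort(
            1, DiseasePreset("NULLFLUX", residual_flux=0.0),
            noise=NOISE_FREE, inter_subject_cv=0.0, seed=2,
        )
        res = run_pipeline(clean_control_cohort + null, config)
        patient = [r for r in res.results if r.group == "NULLFLUX"][0]
        assert patient.RUF == pytest.approx(0.0, abs=1e-6)


class TestControlReference:
    def _result(self, i, R, T):
        return RUFResult(assay_id=f"C{i}", R=R, T=T, recovery=T, group="CONTROL")

    def test_two_identical_controls_degenerate_band(self):
        results = [self._result(i, 0.7, 50.0) for i in range(2)]
        ref = build_control_reference(results)
        assert ref.ruf_mean == pytest.approx(100.0)
        assert ref.ruf_sd == pytest.approx(0.0)
        assert ref.ruf_range == pytest.approx((100.0, 100.0))

    def test_mean_control_ruf_near_100(self, noisy_control_cohort, config):
        """Leave-in control RUFs average to 100 up to R–T covariance."""
        from ureaflux.pipeline import run_pipeline

        res = run_pipeline(noisy_control_cohort, config)
        assert res.reference.ruf_mean == pytest.approx(100.0, abs=1.0)

    def test_fewer_than_two_controls_rejected(self):
        with pytest.raises(UndefinedMetricError):
            build_control_reference([self._result(0, 0.7, 50.0)])

    def test_leave_one_out_option(self):
        results = [self._result(i, R, T) for i, (R, T) in
                   enumerate([(0.6, 45.0), (0.7, 50.0), (0.8, 55.0)])]
        leave_in = build_control_reference(results)
        loo = build_control_reference(results, leave_one_out=True)
        assert loo.ruf_sd > leave_in.ruf_sd  # each subject vs others-only means


class TestRepeatability:
    def test_cv_across_repeats(self):
        assert ruf_repeatability_cv([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_single_assay_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ruf_repeatability_cv([100.0])


class TestPrePost:
    def _result(self, aid, ruf, rec, matrix="plasma", partition=None):
        return RUFResult(
            assay_id=aid, R=0.5, T=rec, recovery=rec, RUF=ruf,
            partition=partition or {"urea": 0.5, "glutamine": 0.5}, matrix=matrix,
        )

    def test_identical_assays_zero_deltas(self):
        pre = self._result("P1_pre", 40.0, 30.0)
        report = compare_pre_post(pre, pre)
        assert report["delta_ruf"] == 0.0
        assert report["delta_recovery"] == 0.0
        assert all(v == 0.0 for v in report["delta_pathway"].values())

    def test_matrix_mismatch_warns(self):
        pre = self._result("P1_pre", 40.0, 30.0, matrix="plasma")
        post = self._result("P1_post", 90.0, 50.0, matrix="DBS")
        with pytest.warns(MatrixMismatchWarning):
            compare_pre_post(pre, post)

    def test_simulated_liver_transplant(self, clean_control_cohort, config):
        """Restoring flux raises RUF and shifts label out of glutamine."""
        from ureaflux.pipeline import run_pipeline
        from ureaflux.simulate import NOISE_FREE, DiseasePreset, simulate_cohort

        def patient(residual, seed):
            a = simulate_cohort(
                1, DiseasePreset("UCD", residual_flux=residual),
                noise=NOISE_FREE, inter_subject_cv=0.0, seed=seed,
            )[0]
            a.subject_id = f"P_{residual}"
            return a

        res = run_pipeline(
            clean_control_cohort + [patient(0.05, 3), patient(1.0, 3)], config
        )
        by_id = {r.assay_id: r for r in res.results}
        report = compare_pre_post(by_id["P_0.05"], by_id["P_1.0"])
        assert report["delta_ruf"] > 50.0
        assert report["delta_pathway"]["alternative"] < 0.0
        pre_share = by_id["P_0.05"].partition["glutamine"]
        post_share = by_id["P_1.0"].partition["glutamine"]
        assert post_share < pre_share
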