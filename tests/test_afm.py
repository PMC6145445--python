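"""Force-curve analytics: segmentation, contact, Hertz fit, adhesion."""

import numpy as np
import pandas as pd
import pytest

from nodulescope import afm, synth
from nodulescope.afm import (
    IndenterGeometry,
    aggregate,
    analyze_curve,
    analyze_curves,
    compute_adhesion,
    detect_contact,
    estimate_baseline,
    fit_hertz,
    split_segments,
)
from nodulescope.synth import AdhesionEvent, ForceCurveGroundTruth, RampDesign


class TestSplitSegments:
    def test_labelled_table(self):
        table = pd.DataFrame(
            {
                "segment": ["approach"] * 60 + ["retract"] * 80,
                "height_nm": list(range(60, 0, -1)) + list(range(1, 81)),
                "force_nN": [0.0] * 140,
            }
        )
        c = split_segments(table, curve_id="x")
        assert c.approach_height_nm.size == 60
        assert c.retract_height_nm.size == 80
        assert c.approach_height_nm[0] > c.approach_height_nm[-1]

    def test_unlabelled_split_at_extremum(self):
        z = np.concatenate([np.arange(100, 0, -1.0), np.arange(1.0, 81)])
        table = pd.DataFrame({"height_nm": z, "force_nN": np.zeros(z.size)})
        c = split_segments(table)
        assert c.approach_height_nm.size == 100
        assert c.retract_height_nm.size == 81  # turning point shared

    def test_monotone_trace_rejected(self):
        table = pd.DataFrame(
            {"height_nm": np.arange(100.0), "force_nN": np.zeros(100)}
        )
        with pytest.raises(ValueError, match="turning point"):
            split_segments(table)


class TestBaselineAndContact:
    def test_flat_zero_segment(self):
        z = np.arange(1000.0)
        b, s = estimate_baseline(z, np.zeros_like(z))
        assert b == 0.0 and s == 0.0

    def test_noisy_offset_recovered(self):
        rng = np.random.default_rng(7)
        z = np.arange(1000.0)
        f = 2.0 + rng.normal(0, 0.5, z.size)
        b, s = estimate_baseline(z, f)
        assert b == pytest.approx(2.0, abs=0.1)
        assert s == pytest.approx(0.5, rel=0.1)

    def test_contact_region_inclusion_biases_upward(self):
        """Documented failure mode: a window reaching into the contact
        region drags the baseline above the free-air level."""
        truth = ForceCurveGroundTruth()
        c = synth.generate_force_curve(
            truth, ramp=RampDesign(approach_span_nm=100.0, step_nm=1.0)
        )
        b_good, _ = estimate_baseline(c.approach_height_nm, c.approach_force_nN, 0.3)
        b_bad, _ = estimate_baseline(c.approach_height_nm, c.approach_force_nN, 0.95)
        assert b_bad > b_good + 1.0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.arange(100.0), np.zeros(100), fraction=1.5)

    def test_contact_point_detected_on_noiseless_curve(self, pyramid_truth):
        c = synth.generate_force_curve(pyramid_truth)
        z0 = detect_contact(c.approach_height_nm, c.approach_force_nN, 0.0, 0.0)
        # threshold 0 on noiseless data: first strictly positive force point
        step = 2.0
        assert abs(z0 - pyramid_truth.contact_point_nm) <= step

    def test_all_baseline_curve_raises(self):
        z = np.arange(500.0)
        with pytest.raises(ValueError, match="no contact"):
            detect_contact(z, np.zeros_like(z), 0.0, 1.0)


class TestHertz:
    def test_noiseless_pyramid_recovery_within_0p1_percent(self, pyramid_truth):
        c = synth.generate_force_curve(pyramid_truth)
        res = fit_hertz(c)
        assert res.status == "ok"
        assert res.youngs_modulus_Pa == pytest.approx(2.0e9, rel=1e-3)
        assert res.contact_point_nm == pytest.approx(
            pyramid_truth.contact_point_nm, abs=0.5
        )

    def test_cone_with_matched_prefactor_gives_same_modulus(self, pyramid_truth):
        """Same delta^2 functional form: a cone whose C equals the pyramid's
        must return an identical modulus."""
        c = synth.generate_force_curve(pyramid_truth)
        pyr = IndenterGeometry(shape="pyramid", face_half_angle_deg=20.0)
        tan_eq = 0.7453 * np.tan(np.radians(20.0)) * np.pi / 2.0
        cone = IndenterGeometry(
            shape="cone", face_half_angle_deg=float(np.degrees(np.arctan(tan_eq)))
        )
        e_pyr = fit_hertz(c, pyr).youngs_modulus_Pa
        e_cone = fit_hertz(c, cone).youngs_modulus_Pa
        assert e_cone == pytest.approx(e_pyr, rel=1e-9)

    def test_force_rescaling_doubles_modulus(self, pyramid_truth):
        c = synth.generate_force_curve(pyramid_truth)
        doubled = synth.generate_force_curve(
            ForceCurveGroundTruth(youngs_modulus_Pa=4.0e9)
        )
        e1 = fit_hertz(c).youngs_modulus_Pa
        e2 = fit_hertz(doubled).youngs_modulus_Pa
        assert e2 / e1 == pytest.approx(2.0, rel=1e-3)

    def test_reduced_modulus_mode_differs_from_rigid(self, pyramid_truth):
        c = synth.generate_force_curve(pyramid_truth)
        rigid = fit_hertz(c, IndenterGeometry(rigid_tip=True)).youngs_modulus_Pa
        soft = fit_hertz(c, IndenterGeometry(rigid_tip=False)).youngs_modulus_Pa
        assert soft > rigid  # part of the compliance assigned to the tip


class TestAdhesion:
    def _curve(self, events, noise=0.0, step=4.0, seed=0):
        truth = ForceCurveGroundTruth(adhesion_events=events, noise_sd_nN=noise)
        return (
            synth.generate_force_curve(
                truth, ramp=RampDesign(step_nm=step), seed=seed
            ),
            truth,
        )

    def test_triangular_event_oracle(self):
        # 250 points per um
        c, truth = self._curve([AdhesionEvent(0.5, 10.0, "triangular", 0.5)])
        m = compute_adhesion(c, truth.contact_point_nm, 0.0, 0.0)
        assert m.adhesion_force_nN == pytest.approx(10.0, rel=0.01)
        assert m.adhesion_energy_fJ == pytest.approx(2.5, rel=0.01)
        assert m.n_events == 1

    def test_flat_retraction_all_zero(self):
        c, truth = self._curve([])
        m = compute_adhesion(c, truth.contact_point_nm, 0.0, 0.0)
        assert m == afm.AdhesionMetrics(0.0, 0.0, 0.0, 0)

    def test_two_events_length_at_last_rupture(self):
        c, truth = self._curve(
            [
                AdhesionEvent(1.0, 8.0, "triangular", 0.4),
                AdhesionEvent(3.0, 5.0, "triangular", 0.4),
            ]
        )
        m = compute_adhesion(c, truth.contact_point_nm, 0.0, 0.0)
        assert m.n_events == 2
        assert m.adhesion_length_um == pytest.approx(3.0, abs=0.005)

    def test_force_scaling_is_exactly_linear(self):
        events = [AdhesionEvent(1.0, 10.0, "triangular", 0.5)]
        scaled = [AdhesionEvent(1.0, 30.0, "triangular", 0.5)]
        c1, t1 = self._curve(events)
        c2, t2 = self._curve(scaled)
        m1 = compute_adhesion(c1, t1.contact_point_nm, 0.0, 0.0)
        m2 = compute_adhesion(c2, t2.contact_point_nm, 0.0, 0.0)
        assert m2.adhesion_force_nN == pytest.approx(3 * m1.adhesion_force_nN)
        # on the fixed height axis the work integral is exactly linear in
        # the force; the separation axis adds a tiny deflection coupling
        h1 = compute_adhesion(c1, t1.contact_point_nm, 0.0, 0.0, axis="height")
        h2 = compute_adhesion(c2, t2.contact_point_nm, 0.0, 0.0, axis="height")
        assert h2.adhesion_energy_fJ == pytest.approx(
            3 * h1.adhesion_energy_fJ, rel=1e-9
        )
        assert m2.adhesion_energy_fJ == pytest.approx(
            3 * m1.adhesion_energy_fJ, rel=5e-3
        )

    def test_stiff_cantilever_separation_equals_height(self):
        """With k -> infinity the deflection correction vanishes, so the
        separation- and height-axis readings coincide."""
        events = [AdhesionEvent(1.0, 10.0, "triangular", 0.5)]
        truth = ForceCurveGroundTruth(
            adhesion_events=events, spring_constant_N_per_m=1e9
        )
        c = synth.generate_force_curve(truth, ramp=RampDesign(step_nm=4.0))
        m_sep = compute_adhesion(c, truth.contact_point_nm, 0.0, 0.0)
        m_h = compute_adhesion(c, truth.contact_point_nm, 0.0, 0.0, axis="height")
        assert m_sep.adhesion_length_um == pytest.approx(
            m_h.adhesion_length_um, rel=1e-9
        )
        assert m_sep.adhesion_energy_fJ == pytest.approx(
            m_h.adhesion_energy_fJ, rel=1e-9
        )

    def test_noisy_curve_recovers_event_count_and_length(self):
        events = [
            AdhesionEvent(1.0, 60.0, "exponential", 0.5),
            AdhesionEvent(3.0, 30.0, "triangular", 0.6),
        ]
        hits = 0
        for seed in range(10):
            c, truth = self._curve(events, noise=2.0, step=2.0, seed=seed)
            m = compute_adhesion(c, truth.contact_point_nm, 0.0, 2.0)
            if m.n_events == 2 and abs(m.adhesion_length_um - 3.0) < 0.01:
                hits += 1
        assert hits >= 9


class TestAggregate:
    def _metrics(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "curve_id", "location_id", "nodule_id", "group",
                "E_Pa", "F_adh_nN", "L_adh_um", "W_adh_fJ", "status",
            ],
        )

    def test_single_location_median(self):
        rows = [
            [f"c{i}", "l0", "n0", "g", e, 1.0, 1.0, 1.0, "ok"]
            for i, e in enumerate([1e9, 2e9, 3e9])
        ]
        summaries, pooled = aggregate(self._metrics(rows))
        assert summaries[0].median_E_Pa == 2e9
        assert summaries[0].n_curves == 3

    def test_all_flagged_nodule_absent(self):
        rows = [["c0", "l0", "n0", "g", 1e9, 1, 1, 1, "flagged"]]
        summaries, pooled = aggregate(self._metrics(rows))
        assert summaries == [] and pooled.empty

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            [f"c{i}", f"l{i % 3}", f"n{i % 2}", "g",
             float(rng.uniform(1, 5)), 1.0, 1.0, 1.0, "ok"]
            for i in range(12)
        ]
        m = self._metrics(rows)
        _, pooled1 = aggregate(m)
        _, pooled2 = aggregate(m.sample(frac=1.0, random_state=4))
        pd.testing.assert_frame_equal(
            pooled1.reset_index(drop=True), pooled2.reset_index(drop=True)
        )

    def test_group_scaling_recovered_through_full_analysis(self):
        design = synth.CohortDesign(
            groups=("control", "DBeQ"),
            n_per_group=12,
            seed=13,
            offsets={"DBeQ": synth.GroupOffsets(e_scale=0.5)},
        )
        curves, _ = synth.generate_cohort(design, "afm")
        metrics = analyze_curves(curves)
        _, pooled = aggregate(metrics)
        med = pooled.groupby("group")["E_Pa"].median()
        assert med["DBeQ"] / med["control"] == pytest.approx(0.5, rel=0.25)


class TestAnalyzeCurve:
    def test_full_readout_matches_truth(self):
        truth = ForceCurveGroundTruth(
            adhesion_events=[
                AdhesionEvent(1.0, 60.0, "exponential", 0.5),
                AdhesionEvent(3.0, 30.0, "triangular", 0.6),
            ],
            noise_sd_nN=2.0,
        )
        r = analyze_curve(synth.generate_force_curve(truth, seed=3))
        assert r["status"] == "ok"
        assert r["E_Pa"] == pytest.approx(2.0e9, rel=0.02)
        assert r["F_adh_nN"] == pytest.approx(60.0, rel=0.1)
        assert r["L_adh_um"] == pytest.approx(3.0, abs=0.01)
        assert r["n_events"] == 2
        total = sum(e.energy_fJ for e in truth.adhesion_events)
        assert r["W_adh_fJ"] == pytest.approx(total, rel=0.1)
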