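"""Contact-probability model: geometry, estimators, hairpin, yield curves."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from walkerstep.kinetics import KineticParams, yield_from_rates
from walkerstep.mechanics import (
    Calibration,
    ContactEstimate,
    ContactModel,
    HairpinModel,
    TrackGeometry,
    UndefinedReferenceError,
    WalkerDesign,
    apply_hairpin,
    chord_from_arc,
    contact_probability,
    default_walker_design,
    delta_barrier,
    max_reach,
    predict_yield_curve,
    sample_end_density,
)
from walkerstep.polymer import ds_segment, sample_chain, ss_segment


class TestChordFromArc:
    def test_flat_limit(self):
        assert chord_from_arc(10.0, 1e6) == pytest.approx(10.0, rel=1e-6)

    def test_half_circumference_is_diameter(self):
        R = 9.0
        assert chord_from_arc(math.pi * R, R) == pytest.approx(2 * R)

    def test_full_wrap_closes(self):
        R = 9.0
        assert chord_from_arc(2 * math.pi * R, R) == pytest.approx(0.0, abs=1e-12)

    def test_wrap_around_uses_short_way(self):
        R = 60.0 / (2.0 * math.pi)
        assert chord_from_arc(45.0, R) == pytest.approx(chord_from_arc(15.0, R))


class TestDeltaBarrier:
    def test_definition(self):
        p = 1e-4
        assert delta_barrier(p, p) == 0.0
        assert delta_barrier(p / math.e, p) == pytest.approx(1.0)
        assert delta_barrier(0.0, p) == math.inf

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedReferenceError):
            delta_barrier(1e-4, 0.0)


class TestMaxReach:
    def test_two_rod_triangle_inequality(self):
        design = WalkerDesign(
            arm_bound=(ds_segment(15),),  # 5.1 nm rod
            arm_fuel=(ds_segment(12),),  # 4.08 nm rod
            capture_radius=0.5,
        )
        assert max_reach(design) == pytest.approx(5.1 + 4.08 + 0.5)

    def test_contact_vanishes_beyond_reach_and_persists_below(self):
        design = WalkerDesign(
            arm_bound=(ss_segment(12), ds_segment(10)),
            arm_fuel=(ss_segment(12),),
            capture_radius=0.5,
        )
        reach = max_reach(design)
        track = TrackGeometry(kind="flat")
        model = ContactModel(design, track, n=20_000, seed=8)
        p_below, _ = model.probability(0.9 * reach)
        p_above, _ = model.probability(1.05 * reach)
        assert p_below > 0.0
        assert p_above == 0.0

    def test_default_design_reach_value(self, design):
        # 2+3+16 nt ss (13.23 nm) + 34 bp rod on one arm, 2+16 nt ss +
        # 18 bp rod on the other, plus the 1 nm capture radius.
        assert max_reach(design) == pytest.approx(43.25, abs=0.01)


class TestContactEstimators:
    def test_two_rods_same_anchor_distance_law(self):
        """Two rods of length b pivoting at the same point, no wall: the
        end-end distance pdf is s/(2b^2), so P(within delta) = delta^2/(4 b^2)."""
        b, delta, n = 5.0, 1.0, 30_000
        ends_a = sample_chain(np.array([b]), n, np.random.default_rng(21)).ends
        ends_b = sample_chain(np.array([b]), n, np.random.default_rng(22)).ends
        counts = cKDTree(ends_b).query_ball_point(ends_a, delta, return_length=True)
        p_hat = counts.sum() / (n * n)
        rates = counts / n
        se = math.sqrt(2.0) * rates.std(ddof=1) / math.sqrt(n)
        assert abs(p_hat - delta**2 / (4 * b * b)) <= 3 * se

    @pytest.mark.parametrize("d", [15.0, 20.0])
    def test_overlap_and_direct_agree(self, flat_model, d):
        p_o, se_o = flat_model.probability(d, method="overlap")
        p_d, se_d = flat_model.probability(d, method="direct")
        assert p_d > 0
        assert abs(p_o - p_d) <= 3 * math.hypot(se_o, se_d)

    def test_monotone_decay_beyond_20nm(self, flat_model):
        grid = [20.0, 25.0, 30.0, 35.0, 40.0]
        est = [flat_model.probability(d) for d in grid]
        for (p0, s0), (p1, s1) in zip(est, est[1:]):
            assert p1 <= p0 + 3 * math.hypot(s0, s1)

    def test_huge_cylinder_reproduces_flat(self, design, flat_model):
        huge = ContactModel(
            design, TrackGeometry(kind="cylinder", radius=1e6), n=20_000, seed=77
        )
        for d in (10.0, 20.0, 28.0):
            p_f, s_f = flat_model.probability(d)
            p_c, s_c = huge.probability(d)
            assert abs(p_f - p_c) <= 3 * math.hypot(s_f, s_c) + 1e-12

    def test_wraparound_beats_flat_extrapolation(self, design, flat_model):
        """Beyond half the circumference the short 3-D route keeps contact
        alive where the flat track at equal arc length is beyond reach."""
        cyl = ContactModel(
            design, TrackGeometry(kind="cylinder", radius=60 / (2 * math.pi)),
            n=20_000, seed=31,
        )
        p_wrap, _ = cyl.probability(45.0)
        p_flat, _ = flat_model.probability(45.0)
        assert p_flat == 0.0
        assert p_wrap > 0.0

    def test_estimate_object_invariants(self, flat_model):
        est = flat_model.estimate(15.0, reference_separation=12.0)
        assert 0.0 <= est.p_contact <= 1.0
        assert math.isfinite(est.dG_rel)
        assert est.stderr >= 0.0
        assert est.n_samples == flat_model.n
        with pytest.raises(ValueError):
            ContactEstimate(d=5.0, p_contact=0.0, dG_rel=1.0, stderr=0.0,
                            n_samples=10, seed=0)

    def test_contact_probability_wrapper(self, design):
        track = TrackGeometry(kind="flat", separation=50.0)  # beyond reach
        est = contact_probability(design, track, n=2000, seed=3)
        assert est.p_contact == 0.0
        assert est.dG_rel == math.inf


class TestSampleEndDensity:
    def test_cloud_and_grid(self, design, flat_track):
        dens = sample_end_density(design.arm_fuel, flat_track, n=4000, seed=12)
        assert dens.points.shape == (4000, 3)
        assert 0 < dens.acceptance_rate <= 1
        assert dens.grid.sum() == 4000
        contour = sum(seg.contour for seg in design.arm_fuel)
        assert dens.sample.radius_percentile(95.0) <= contour


class TestHairpin:
    def test_open_probability_two_state(self):
        assert HairpinModel(dG_hp=0.0, sequestered_units=5).p_open == pytest.approx(0.5)
        assert HairpinModel(dG_hp=20.0, sequestered_units=5).p_open == pytest.approx(1.0, abs=1e-8)
        assert HairpinModel(dG_hp=-20.0, sequestered_units=5).p_open == pytest.approx(0.0, abs=1e-8)

    def test_sequestration_bounded_by_overhang(self, design):
        with pytest.raises(ValueError, match="exceeds the overhang"):
            apply_hairpin(design, HairpinModel(dG_hp=0.0, sequestered_units=17))

    def test_folded_design_shortens_fuel_arm(self, design):
        eff = apply_hairpin(design, HairpinModel(dG_hp=-2.0, sequestered_units=10))
        assert eff.design_folded.fuel_contour == pytest.approx(
            design.fuel_contour - 10 * 0.63
        )
        assert eff.design_open is design

    def test_always_open_limit_matches_no_hairpin(self, design, flat_track, flat_model):
        from walkerstep.mechanics import BlendedContactModel

        eff = apply_hairpin(design, HairpinModel(dG_hp=20.0, sequestered_units=10))
        blended = BlendedContactModel(eff, flat_track, n=20_000, seed=91)
        p_b, se_b = blended.probability(15.0)
        p_0, se_0 = flat_model.probability(15.0)
        assert abs(p_b - p_0) <= 3 * math.hypot(se_b, se_0)

    def test_folded_hairpin_hits_short_steps_hardest(self, design, flat_track):
        """A fully folded fuel hairpin suppresses contact more at 5 nm than
        at 10 nm: the shortened overhang can no longer sag back down to the
        surface near the foothold anchor."""
        eff = apply_hairpin(design, HairpinModel(dG_hp=-20.0, sequestered_units=10))
        full = ContactModel(design, flat_track, n=100_000, seed=61)
        folded = ContactModel(eff.design_folded, flat_track, n=100_000, seed=62)
        ratios = {}
        for d in (5.0, 10.0):
            p_full, _ = full.probability(d)
            p_fold, _ = folded.probability(d)
            ratios[d] = p_fold / p_full
        assert ratios[5.0] < ratios[10.0]


@pytest.fixture(scope="module")
def prediction(design, flat_track):
    return predict_yield_curve(
        design,
        flat_track,
        d_grid=[5.0, 12.0, 20.0, 30.0, 50.0],
        F1_list=[1e-9, 1e-8, 1e-5],
        calibration=Calibration(d_ref=12.0, k_s_ref=3.5),
        n=20_000,
        seed=17,
    )


class TestPredictYieldCurve:
    def test_reference_anchoring_is_exact(self, prediction):
        cal = prediction.calibration
        at_ref = prediction.curve.query("step_size_nm == 12.0")
        for _, row in at_ref.iterrows():
            expected = yield_from_rates(
                KineticParams(cal.k_s_ref, cal.k_FB, row["fuel_conc_M"])
            )
            assert row["yield"] == pytest.approx(expected, rel=1e-12)

    def test_yield_decreasing_in_fuel(self, prediction):
        for d, group in prediction.curve.groupby("step_size_nm"):
            g = group.sort_values("fuel_conc_M")
            y = g["yield"].to_numpy()
            assert np.all(np.diff(y) <= 1e-15)

    def test_beyond_reach_rows_are_zero(self, prediction):
        beyond = prediction.curve.query("step_size_nm == 50.0")
        assert (beyond["yield"] == 0.0).all()
        contacts = prediction.contacts.set_index("d_nm")
        assert contacts.loc[50.0, "p_contact"] == 0.0
        assert math.isinf(contacts.loc[50.0, "dG_rel_kBT"])

    def test_convex_cylinder_no_easier_than_flat_at_30nm(self, design, flat_track):
        """Convex curvature reduces the overlap of the accessible volumes."""
        cal = Calibration(d_ref=12.0, k_s_ref=3.5)
        kwargs = dict(d_grid=[30.0], F1_list=[1e-9], calibration=cal, n=20_000, seed=41)
        flat_pred = predict_yield_curve(design, flat_track, **kwargs)
        cyl_pred = predict_yield_curve(
            design, TrackGeometry(kind="cylinder", radius=60 / (2 * math.pi)), **kwargs
        )
        y_flat = flat_pred.curve["yield"].iloc[0]
        y_cyl = cyl_pred.curve["yield"].iloc[0]
        assert y_cyl <= y_flat + 1e-12

    def test_reference_beyond_reach_rejected(self, design, flat_track):
        with pytest.raises(ValueError, match="beyond the design reach"):
            predict_yield_curve(
                design, flat_track, d_grid=[10.0], F1_list=[1e-9],
                calibration=Calibration(d_ref=60.0, k_s_ref=3.5), n=100, seed=0,
            )
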