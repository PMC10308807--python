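"""Centrifugal ramp kinematics, event detection and retention quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropwet.fluids import WATER, BACTERIA_OD10, FluidProperties
from dropwet.forced_wetting import (
    bond_number,
    detect_events,
    frames_from_truths,
    furmidge_k,
    retention_force,
    rs_to_aT,
)
from dropwet.synthetic import RampTargets, SyntheticScene, gen_rotation_ramp


class TestKinematics:
    def test_100rpm_at_25cm(self):
        assert rs_to_aT(100.0, 0.25) == pytest.approx(27.4, abs=0.05)

    def test_zero_speed(self):
        assert rs_to_aT(0.0, 0.25) == 0.0

    def test_50rpm(self):
        assert rs_to_aT(50.0, 0.25) == pytest.approx(6.85, abs=0.005)

    @given(st.floats(min_value=0.1, max_value=200.0))
    @settings(deadline=None, max_examples=50)
    def test_exactly_quadratic(self, rs):
        assert rs_to_aT(2 * rs, 0.25) == pytest.approx(4 * rs_to_aT(rs, 0.25), rel=1e-12)


class TestBondNumber:
    def test_reference_value(self):
        assert bond_number(WATER, 0.001, 27.4) == pytest.approx(0.381, abs=0.001)

    def test_zero_acceleration(self):
        assert bond_number(WATER, 0.001, 0.0) == 0.0

    def test_quadratic_in_length(self):
        assert bond_number(WATER, 0.002, 10.0) == pytest.approx(
            4 * bond_number(WATER, 0.001, 10.0)
        )

    @given(
        rho=st.floats(min_value=800, max_value=1500),
        sigma=st.floats(min_value=0.02, max_value=0.08),
        aT=st.floats(min_value=0.1, max_value=30.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotonicity(self, rho, sigma, aT):
        f = FluidProperties(density=rho, surface_tension=sigma)
        base = bond_number(f, 0.001, aT)
        assert bond_number(f, 0.0012, aT) > base
        assert bond_number(f, 0.001, aT * 1.1) > base
        f2 = FluidProperties(density=rho, surface_tension=sigma * 1.1)
        assert bond_number(f2, 0.001, aT) < base


class TestRetentionForce:
    def test_reference_value(self):
        # rho*V*aT = 1000 * 35e-9 m^3 * 6.85 m/s^2
        assert retention_force(WATER, 35.0, 6.85) == pytest.approx(2.40e-4, rel=0.005)

    def test_zero_acceleration(self):
        assert retention_force(WATER, 35.0, 0.0) == 0.0

    def test_linear_in_density(self):
        dense = FluidProperties(density=1200.0, surface_tension=0.069)
        assert retention_force(dense, 35.0, 6.85) == pytest.approx(
            1.2 * retention_force(WATER, 35.0, 6.85)
        )


class TestFurmidge:
    def test_reference_value(self):
        k = furmidge_k(2.40e-4, 6.1e-3, 0.072, 53.0, 15.0)
        assert k == pytest.approx(1.50, abs=0.01)

    def test_zero_hysteresis_rejected(self):
        with pytest.raises(ValueError):
            furmidge_k(1e-4, 6e-3, 0.072, 30.0, 30.0)

    @given(
        Fs=st.floats(min_value=1e-5, max_value=1e-3),
        R1=st.floats(min_value=3e-3, max_value=8e-3),
        R2=st.floats(min_value=3e-3, max_value=8e-3),
    )
    @settings(deadline=None, max_examples=50)
    def test_k_R_product_invariant(self, Fs, R1, R2):
        """k1*R1 = k2*R2 for the same force, tension and angles."""
        k1 = furmidge_k(Fs, R1, 0.069, 53.0, 15.0)
        k2 = furmidge_k(Fs, R2, 0.069, 53.0, 15.0)
        assert k1 * R1 == pytest.approx(k2 * R2, rel=1e-12)


class TestDetectEvents:
    def test_reference_ramp_recovered(self):
        frames = frames_from_truths(
            gen_rotation_ramp(RampTargets(), SyntheticScene(), WATER, render=False)
        )
        ev = detect_events(frames, fluid=WATER, volume_uL=35.0)
        assert abs(ev.rs_spread_rpm - 40.0) <= 1.0
        assert abs(ev.rs_slide_rpm - 50.0) <= 1.0
        assert ev.theta_adv_deg == pytest.approx(53.0, abs=1.0)
        assert ev.theta_rec_deg == pytest.approx(15.0, abs=1.0)
        # exact algebraic identity between the two k factors
        assert ev.k1 * ev.L_initial_mm == pytest.approx(
            ev.k2 * ev.L_sliding_mm, rel=1e-12
        )

    def test_pinned_rear_gives_no_sliding(self):
        frames = frames_from_truths(
            gen_rotation_ramp(
                RampTargets(rs_slide_rpm=None), SyntheticScene(), WATER, render=False
            )
        )
        ev = detect_events(frames)
        assert ev.rs_slide_rpm is None
        assert ev.theta_rec_deg == pytest.approx(15.0, abs=1.0)
        assert ev.theta_adv_deg == pytest.approx(53.0, abs=1.0)

    def test_static_series_flagged(self):
        frames = frames_from_truths(
            gen_rotation_ramp(
                RampTargets(advance_rate_mm_per_rpm=0.0), SyntheticScene(), WATER,
                render=False,
            )
        )
        ev = detect_events(frames)
        assert ev.static
        assert ev.rs_spread_rpm is None

    def test_end_to_end_k_recovery(self):
        """Generator ramp -> detect_events -> Furmidge k matches the k
        implied by the generator's target parameters within 5%."""
        targets = RampTargets()
        frames = frames_from_truths(
            gen_rotation_ramp(targets, SyntheticScene(), BACTERIA_OD10, render=False)
        )
        ev = detect_events(frames, fluid=BACTERIA_OD10, volume_uL=targets.volume_uL)
        aT_true = rs_to_aT(targets.rs_slide_rpm, 0.25)
        Fs_true = retention_force(BACTERIA_OD10, targets.volume_uL, aT_true)
        k_true = furmidge_k(
            Fs_true,
            ev.L_initial_mm * 1e-3,
            BACTERIA_OD10.surface_tension,
            targets.theta_adv_deg,
            targets.theta_rec_deg,
        )
        assert ev.k1 == pytest.approx(k_true, rel=0.05)

    def test_too_few_frames_rejected(self):
        frames = frames_from_truths(
            gen_rotation_ramp(
                RampTargets(), SyntheticScene(), WATER, render=False
            )
        )[:5]
        with pytest.raises(ValueError):
            detect_events(frames)
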