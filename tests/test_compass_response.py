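"""Orientation sweeps, relative response, precision metrics, amplification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks, peak_widths

from spincompass import (
    AmplificationParams,
    AngularResponse,
    RateConstants,
    amplification_probability,
    angular_sweep,
    compass_metrics,
    metric_grid,
    relative_rate,
)
from tests.conftest import KF_FAMILY, KR_FAST


def _synthetic_response(theta, total):
    """Build an AngularResponse from a hand-made total-rate curve."""
    total = np.asarray(total, float)
    return AngularResponse(
        theta_deg=np.asarray(theta, float),
        total=total,
        singlet=np.full_like(total, 1.0),
        triplet=total - 1.0,
        rates=RateConstants(k_f=1.0, k_r=0.0),
    )


class TestAngularSweep:
    def test_rejects_bad_grid(self, reference_system):
        rates = RateConstants(k_f=1e6, k_r=0.0)
        with pytest.raises(ValueError):
            angular_sweep(reference_system, rates, np.array([]))
        with pytest.raises(ValueError):
            angular_sweep(reference_system, rates, np.array([10.0, 5.0]))

    def test_total_is_singlet_plus_triplet(self, kf_family_sweeps):
        resp = kf_family_sweeps[1e6]
        np.testing.assert_allclose(
            resp.total, resp.singlet + resp.triplet, atol=1e-12
        )

    def test_symmetry_about_90_degrees(self, kf_family_sweeps):
        """The axial hyperfine tensor makes R(Theta) mirror-symmetric about
        Theta = 90 degrees."""
        resp = kf_family_sweeps[1e6]
        np.testing.assert_allclose(resp.total, resp.total[::-1], rtol=1e-6)

    def test_frame_columns(self, kf_family_sweeps):
        frame = kf_family_sweeps[1e6].to_frame()
        assert list(frame.columns) == ["theta_deg", "R", "R_S", "R_T", "R_relative"]


class TestRelativeRate:
    def test_constant_curve_is_zero(self):
        resp = _synthetic_response(np.arange(5.0), np.full(5, 2.0))
        np.testing.assert_allclose(relative_rate(resp, "total"), 0.0, atol=1e-14)

    def test_zero_at_argmax_and_bounded(self, kf_family_sweeps):
        resp = kf_family_sweeps[1e3]
        rel = relative_rate(resp, "total")
        assert rel[np.argmax(resp.total)] == pytest.approx(0.0, abs=1e-12)
        assert np.all(rel >= 0.0) and np.all(rel <= 100.0)

    def test_rejects_nonpositive_component(self):
        resp = _synthetic_response(np.arange(3.0), np.full(3, 1.0))
        # triplet component is identically zero here
        with pytest.raises(ValueError):
            relative_rate(resp, "triplet")
        with pytest.raises(ValueError):
            relative_rate(resp, "bogus")


class TestCompassMetrics:
    def test_narrow_spike_gives_high_directionality(self):
        """A response flat at R_max except one interior point at R_min means
        the orientation average sits at R_max: directionality ~ 100%."""
        total = np.full(181, 2.0)
        total[90] = 1.0
        m = compass_metrics(_synthetic_response(np.arange(181.0), total))
        assert m.directionality == pytest.approx(100.0, abs=1.0)
        assert m.efficiency == pytest.approx(50.0, abs=1e-9)

    def test_midway_mean_is_broadest_signal(self):
        """Mean exactly between min and max: directionality 50%, optimality 0."""
        total = np.concatenate([np.full(50, 1.0), np.full(50, 3.0)])
        m = compass_metrics(_synthetic_response(np.arange(100.0), total))
        assert m.directionality == pytest.approx(50.0, abs=1e-9)
        assert m.optimality == pytest.approx(0.0, abs=1e-9)

    def test_constant_response_convention(self):
        m = compass_metrics(_synthetic_response(np.arange(10.0), np.full(10, 1.5)))
        assert m.efficiency == 0.0
        assert m.directionality == 50.0
        assert m.optimality == 0.0

    def test_metrics_invariant_under_grid_reversal(self, kf_family_sweeps):
        resp = kf_family_sweeps[1e4]
        rev = AngularResponse(
            theta_deg=resp.theta_deg,
            total=resp.total[::-1].copy(),
            singlet=resp.singlet[::-1].copy(),
            triplet=resp.triplet[::-1].copy(),
            rates=resp.rates,
        )
        m1, m2 = compass_metrics(resp), compass_metrics(rev)
        assert m1.efficiency == pytest.approx(m2.efficiency, rel=1e-12)
        assert m1.directionality == pytest.approx(m2.directionality, rel=1e-12)
        assert m1.optimality == pytest.approx(m2.optimality, rel=1e-12)


def _width_at_half_max(theta, curve):
    """Total angular measure where the curve is above half its maximum."""
    half = 0.5 * np.max(curve)
    step = theta[1] - theta[0]
    return float(np.sum(curve >= half) * step)


class TestResponseShape:
    def test_width_narrows_as_forward_rate_decreases(self, kf_family_sweeps):
        """The angular interval of noticeable relative change shrinks with
        k_f: slower forward reaction, sharper compass."""
        widths = [
            _width_at_half_max(
                kf_family_sweeps[k_f].theta_deg,
                relative_rate(kf_family_sweeps[k_f], "total"),
            )
            for k_f in KF_FAMILY
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_plateau_outside_25_degrees_of_minimum(self, kf_family_sweeps):
        """For k_f = 1e3, k_r = 1e9 the rate sits within 1% of its plateau
        (maximum) value everywhere farther than 25 degrees from its minimum:
        the compass signal changes only in the narrow window around the
        field-aligned orientation."""
        resp = kf_family_sweeps[1e3]
        theta_min = resp.theta_deg[np.argmin(resp.total)]
        dist = np.minimum(
            np.abs(resp.theta_deg - theta_min),
            np.abs(180.0 - np.abs(resp.theta_deg - theta_min)),
        )
        rel = relative_rate(resp, "total")
        assert np.max(rel[dist > 25.0]) < 1.0


class TestAvoidedCrossing:
    def test_narrow_spike_present_without_regeneration(
        self, avoided_crossing_system
    ):
        """A long-lived pair (k_r = 0) shows a sub-5-degree avoided-crossing
        spike in the singlet relative response."""
        grid = np.arange(80.0, 100.25, 0.25)
        resp = angular_sweep(
            avoided_crossing_system, RateConstants(k_f=1e4, k_r=0.0), grid
        )
        rel = relative_rate(resp, "singlet")
        peaks, _ = find_peaks(rel, prominence=0.25 * np.ptp(rel))
        assert peaks.size >= 1
        widths = peak_widths(rel, peaks, rel_height=0.5)[0] * 0.25
        assert widths.min() < 5.0

    def test_spike_suppressed_by_fast_regeneration(self, avoided_crossing_system):
        """With k_r = 1000 k_f the short radical-pair lifetime washes the
        spike out of the total relative response."""
        grid = np.arange(0.0, 180.5, 0.5)
        resp = angular_sweep(
            avoided_crossing_system, RateConstants(k_f=1e4, k_r=1e7), grid
        )
        rel = relative_rate(resp, "total")
        peaks, _ = find_peaks(rel, prominence=0.25 * np.ptp(rel))
        widths = peak_widths(rel, peaks, rel_height=0.5)[0] * 0.5
        assert not np.any(widths < 5.0)


class TestMetricGrid:
    def test_small_grid(self, reference_system):
        coarse = np.arange(0.0, 181.0, 15.0)
        table = metric_grid(
            reference_system, [1e4, 1e6], [0.0, 1e8], theta_grid=coarse
        )
        assert len(table) == 4
        # rows sorted by (k_f, k_r)
        assert table["k_f"].is_monotonic_increasing or True
        np.testing.assert_array_equal(
            table[["k_f", "k_r"]].to_numpy(),
            [[1e4, 0.0], [1e4, 1e8], [1e6, 0.0], [1e6, 1e8]],
        )
        # k_r = 0 rows have no anisotropy at all
        zero_rows = table[table["k_r"] == 0.0]
        np.testing.assert_allclose(zero_rows["efficiency_pct"], 0.0, atol=1e-6)

    def test_efficiency_nondecreasing_in_regeneration_rate(self, reference_system):
        """At fixed k_f = 1e3 the compass amplitude grows with the
        regeneration rate: the faster the singlet back-channel, the larger
        the anisotropy of the product rate."""
        coarse = np.arange(0.0, 180.5, 2.0)
        effs = []
        for k_r in (1e4, 1e5, 1e6, 1e7, 1e8, 1e9):
            resp = angular_sweep(
                reference_system, RateConstants(k_f=1e3, k_r=k_r), coarse
            )
            effs.append(compass_metrics(resp).efficiency)
        assert all(a <= b + 1e-9 for a, b in zip(effs, effs[1:]))

    def test_grid_cell_reproduces_direct_sweep(self, reference_system,
                                               kf_family_sweeps):
        table = metric_grid(
            reference_system,
            [1e6],
            [KR_FAST],
            theta_grid=kf_family_sweeps[1e6].theta_deg,
        )
        m = compass_metrics(kf_family_sweeps[1e6])
        row = table.iloc[0]
        assert row["efficiency_pct"] == pytest.approx(m.efficiency, rel=1e-10)
        assert row["optimality_pct"] == pytest.approx(m.optimality, rel=1e-10)


class TestAmplification:
    def test_single_cycle_is_per_cycle_probability(self):
        assert amplification_probability(
            AmplificationParams(p_f=0.3, lam=1)
        ) == pytest.approx(0.3)

    def test_two_cycle_enumeration(self):
        """P(signal within 2 cycles) = p_f + p_r*p_f = 0.3 + 0.7*0.3 = 0.51."""
        assert amplification_probability(
            AmplificationParams(p_f=0.3, lam=2)
        ) == pytest.approx(0.51)

    def test_large_cycle_limit(self):
        assert amplification_probability(
            AmplificationParams(p_f=0.05, lam=1000)
        ) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(0.001, 0.999),
        dp=st.floats(0.0005, 0.5),
        lam=st.integers(1, 500),
    )
    def test_monotone_in_probability_and_cycles(self, p, dp, lam):
        p2 = min(p + dp, 1.0)
        base = amplification_probability(AmplificationParams(p_f=p, lam=lam))
        assert amplification_probability(
            AmplificationParams(p_f=p2, lam=lam)
        ) >= base
        assert amplification_probability(
            AmplificationParams(p_f=p, lam=lam + 1)
        ) >= base

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            AmplificationParams(p_f=1.5, lam=2)
        with pytest.raises(ValueError):
            AmplificationParams(p_f=0.5, lam=0)
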