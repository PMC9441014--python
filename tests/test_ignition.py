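"""Tests of the intrinsic-ignition measures: phases, phase locking, event
detection, integration, and the session comparison."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbec.containers import ParcellatedTimeSeries
from wbec.errors import InvalidInputError, InvalidParameterError
from wbec.ignition import (
    IgnitionProfile,
    PhaseSeries,
    _largest_component_size,
    compare_ignition,
    detect_events,
    ignition_profile,
    instantaneous_phases,
    integration_for_event,
    phase_lock_value,
)
from wbec.synthetic import simulate_phase_signals


def sinusoid_ts(freq_hz=0.05, tr=2.0, n=400, n_regions=3, phases=None):
    t = np.arange(n) * tr
    phases = np.zeros(n_regions) if phases is None else np.asarray(phases)
    x = np.sin(2 * np.pi * freq_hz * t[:, None] + phases[None, :])
    return ParcellatedTimeSeries(values=x, tr_seconds=tr)


class TestInstantaneousPhases:
    def test_phase_slope_matches_frequency(self):
        f = 0.05
        ts = sinusoid_ts(freq_hz=f, n=600)
        ph = instantaneous_phases(ts, band=(0.04, 0.07)).phases[:, 0]
        mid = slice(100, -100)
        slope = np.diff(np.unwrap(ph))[mid].mean() / ts.tr_seconds
        assert abs(slope - 2 * np.pi * f) / (2 * np.pi * f) < 0.05

    def test_output_range_and_shape(self):
        ts = sinusoid_ts(n_regions=4)
        ps = instantaneous_phases(ts)
        assert ps.phases.shape == ts.values.shape
        assert np.all(ps.phases > -np.pi) and np.all(ps.phases <= np.pi)

    def test_band_violating_nyquist_rejected(self):
        ts = sinusoid_ts()
        with pytest.raises(InvalidParameterError):
            instantaneous_phases(ts, band=(0.1, 0.4))


class TestPhaseLockValue:
    def test_zero_difference_gives_one(self):
        assert phase_lock_value(1.2, 1.2) == pytest.approx(1.0)

    def test_antiphase_gives_exp_minus_three_pi(self):
        assert phase_lock_value(0.0, np.pi) == pytest.approx(
            np.exp(-3 * np.pi), rel=1e-12)

    def test_wrapping_across_pi_boundary(self):
        # 3.0 vs -3.0: circular distance 2*pi - 6 ~ 0.2832
        d = 2 * np.pi - 6.0
        assert phase_lock_value(3.0, -3.0) == pytest.approx(
            np.exp(-3 * d), rel=1e-12)
        assert phase_lock_value(3.0, -3.0) == pytest.approx(0.4276, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_bounds_and_symmetry(self, a, b):
        v = phase_lock_value(a, b)
        assert 0 < v <= 1
        assert v == pytest.approx(phase_lock_value(b, a))


class TestDetectEvents:
    def test_single_bump_gives_one_event(self):
        x = np.zeros((100, 2))
        x[:, 1] = np.random.default_rng(0).normal(0, 1e-3, 100)
        x[50, 0] = 5.0  # solitary spike -> one rising crossing
        ts = ParcellatedTimeSeries(values=x, tr_seconds=2.0)
        raster = detect_events(ts)
        assert raster.events[:, 0].sum() == 1
        assert raster.events[50, 0]

    def test_constant_region_flagged_no_events(self):
        x = np.column_stack([np.ones(50), np.random.default_rng(1).normal(size=50)])
        ts = ParcellatedTimeSeries(values=x, tr_seconds=2.0)
        raster = detect_events(ts)
        assert 0 in raster.flagged_regions
        assert raster.events[:, 0].sum() == 0

    def test_white_noise_upcrossing_rate(self):
        # for iid normal samples, P(event at t) = P(z_t > 1) * P(z_{t-1} <= 1)
        rng = np.random.default_rng(2)
        T = 20_000
        ts = ParcellatedTimeSeries(values=rng.standard_normal((T, 2)),
                                   tr_seconds=2.0)
        raster = detect_events(ts)
        from scipy.stats import norm
        p = norm.sf(1.0) * norm.cdf(1.0)
        expect = (T - 1) * p
        sd = np.sqrt((T - 1) * p * (1 - p))
        for r in range(2):
            assert abs(raster.events[:, r].sum() - expect) < 3 * sd


class TestIntegration:
    def phases_from(self, rows):
        return PhaseSeries(phases=np.asarray(rows, dtype=float),
                           band_hz=(0.04, 0.07), tr_seconds=2.0)

    def test_fully_synchronized_integration_is_one(self):
        ph = self.phases_from(np.full((6, 5), 0.3))
        assert integration_for_event(ph, 0, range(5), window_trs=4) == 1.0

    def test_fully_desynchronized_gives_singleton(self):
        # spread phases so every pairwise distance is > ln(2)/3
        ph = self.phases_from(np.tile(np.linspace(-2.8, 2.8, 8), (4, 1)))
        got = integration_for_event(ph, 0, range(8), window_trs=4,
                                    binarize_threshold=0.9)
        assert got == pytest.approx(1 / 8)

    def test_two_blocks_give_five_eighths(self):
        # 5 regions at one phase, 3 at another, mutually desynchronized
        row = np.array([0.0] * 5 + [2.5] * 3)
        ph = self.phases_from(np.tile(row, (4, 1)))
        got = integration_for_event(ph, 0, range(8), window_trs=4)
        assert got == pytest.approx(5 / 8)

    def test_matches_networkx_components_on_random_graphs(self, rng):
        for _ in range(25):
            n = rng.integers(2, 10)
            b = rng.random((n, n)) < 0.3
            b = b | b.T
            np.fill_diagonal(b, True)
            expect = max(len(c) for c in nx.connected_components(
                nx.from_numpy_array(b)))
            assert _largest_component_size(b) == expect

    def test_monotone_in_binarize_threshold(self, rng):
        ph = self.phases_from(rng.uniform(-np.pi, np.pi, (5, 10)))
        vals = [
            integration_for_event(ph, 0, range(10), window_trs=4,
                                  binarize_threshold=th)
            for th in (0.9, 0.5, 0.2)
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_subset_equals_whole_brain_restricted(self, rng):
        # computing on a subset must equal restricting the binarized
        # matrix before taking components
        ph = self.phases_from(rng.uniform(-np.pi, np.pi, (6, 12)))
        subset = [1, 4, 5, 9]
        direct = integration_for_event(ph, 1, subset, window_trs=4)
        restricted = integration_for_event(
            PhaseSeries(phases=ph.phases[:, subset], band_hz=ph.band_hz,
                        tr_seconds=ph.tr_seconds),
            1, range(4), window_trs=4)
        assert direct == pytest.approx(restricted)

    def test_empty_subset_rejected(self):
        ph = self.phases_from(np.zeros((5, 3)))
        with pytest.raises(InvalidInputError):
            integration_for_event(ph, 0, [], window_trs=4)

    def test_overrunning_window_rejected(self):
        ph = self.phases_from(np.zeros((5, 3)))
        with pytest.raises(InvalidParameterError):
            integration_for_event(ph, 3, range(3), window_trs=4)


class TestIgnitionProfile:
    def test_synchronized_signal_idmi_one_metastability_zero(self):
        ts = sinusoid_ts(freq_hz=0.05, n=300, n_regions=6)
        prof = ignition_profile(ts, band=(0.04, 0.07))
        valid = prof.n_events > 0
        assert valid.any()
        assert np.allclose(prof.idmi[valid], 1.0)
        two = prof.n_events >= 2
        assert np.allclose(prof.metastability[two], 0.0)

    def test_default_window_is_four_trs(self):
        ts = sinusoid_ts(n=200, n_regions=4)
        prof = ignition_profile(ts)
        assert prof.window_trs == 4

    def test_mixed_synchrony_gives_positive_metastability(self):
        # half-coupled noisy oscillations: integration varies across events
        ts = simulate_phase_signals(10, coupling=0.6, n_volumes=400, seed=3)
        prof = ignition_profile(ts)
        two = prof.n_events >= 2
        assert np.nanmean(prof.metastability[two]) > 0

    def test_region_without_events_flagged_nan(self):
        x = np.random.default_rng(5).normal(size=(120, 3))
        x[:, 0] = np.ones(120)  # constant: no events
        ts = ParcellatedTimeSeries(values=x, tr_seconds=2.0)
        prof = ignition_profile(ts)
        assert prof.n_events[0] == 0
        assert np.isnan(prof.idmi[0])


class TestCompareIgnition:
    def profile(self, idmi, meta, subject=""):
        n = len(idmi)
        return IgnitionProfile(
            idmi=np.asarray(idmi, float), metastability=np.asarray(meta, float),
            node_subset=np.arange(n), window_trs=4,
            n_events=np.full(n, 5), subject_id=subject,
        )

    def test_identical_paired_profiles_not_significant(self):
        profs = [self.profile([0.5, 0.6], [0.1, 0.2], f"s{i}") for i in range(5)]
        res = compare_ignition(profs, profs, paired=True)
        assert res["idmi"].p_value >= 0.99
        assert res["metastability"].p_value >= 0.99

    def test_halved_metastability_detected_at_n17(self, rng):
        pre, post = [], []
        for i in range(17):
            meta = rng.uniform(0.1, 0.4, 8)
            noise = rng.normal(0, 0.01, 8)
            pre.append(self.profile(rng.uniform(0.4, 0.8, 8), meta, f"s{i}"))
            post.append(self.profile(rng.uniform(0.4, 0.8, 8),
                                     meta / 2 + noise, f"s{i}"))
        res = compare_ignition(pre, post, paired=True)
        assert res["metastability"].p_value < 0.05
        assert res["metastability"].direction == "a"
        assert 0 <= res["idmi"].p_value <= 1

    def test_mismatched_pairing_rejected(self):
        a = [self.profile([0.5], [0.1], "s1")]
        b = [self.profile([0.5], [0.1], "s2")]
        with pytest.raises(InvalidInputError):
            compare_ignition(a, b, paired=True)
        with pytest.raises(InvalidInputError):
            compare_ignition(a, a + a, paired=True)
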