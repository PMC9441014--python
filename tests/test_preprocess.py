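"""Tests of band-pass filtering, covariance extraction, time-constant
estimation, and SC-mask construction."""

import numpy as np
import pytest

from wbec.containers import MOUModel, ParcellatedTimeSeries, StructuralMatrix
from wbec.errors import (
    EstimationError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from wbec.preprocess import (
    bandpass,
    build_sc_mask,
    covariance_pair,
    estimate_tau,
    tau_from_autocovariances,
)
from wbec.synthetic import simulate_mou


def sinusoid_ts(freq_hz, tr=2.0, n=600, n_regions=2):
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * freq_hz * t)
    return ParcellatedTimeSeries(
        values=np.tile(x[:, None], (1, n_regions)), tr_seconds=tr
    )


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        ts = sinusoid_ts(0.04)
        out = bandpass(ts, 0.01, 0.07)
        mid = slice(100, -100)  # ignore filter edge effects
        gain = out.values[mid, 0].std() / ts.values[mid, 0].std()
        assert gain >= 0.9

    def test_out_of_band_sinusoid_attenuated(self):
        ts = sinusoid_ts(0.2)
        out = bandpass(ts, 0.01, 0.07)
        mid = slice(100, -100)
        gain = out.values[mid, 0].std() / ts.values[mid, 0].std()
        assert gain <= 0.1

    def test_constant_signal_maps_to_zero(self):
        ts = ParcellatedTimeSeries(values=np.full((200, 3), 7.0), tr_seconds=2.0)
        out = bandpass(ts, 0.01, 0.07)
        assert np.max(np.abs(out.values)) < 1e-8

    def test_zero_phase_no_shift(self):
        ts = sinusoid_ts(0.04)
        out = bandpass(ts, 0.01, 0.07)
        mid = slice(100, -100)
        r = np.corrcoef(ts.values[mid, 0], out.values[mid, 0])[0, 1]
        assert r > 0.999  # any phase shift would decorrelate the sinusoid

    def test_idempotent_on_passband_content(self):
        # refiltering changes a mid-band signal by < 1% RMS; broadband
        # input keeps losing band-edge energy, so idempotency is a
        # passband property
        ts = sinusoid_ts(0.03, n=800)
        once = bandpass(ts, 0.01, 0.07)
        twice = bandpass(once, 0.01, 0.07)
        mid = slice(100, -100)
        rms_change = np.sqrt(np.mean((twice.values[mid] - once.values[mid]) ** 2))
        rms = np.sqrt(np.mean(once.values[mid] ** 2))
        assert rms_change / rms < 0.01

    @pytest.mark.parametrize("band", [(0.0, 0.1), (0.1, 0.05), (0.01, 0.3)])
    def test_invalid_band_rejected(self, band):
        ts = sinusoid_ts(0.04)
        with pytest.raises(InvalidParameterError):
            bandpass(ts, *band)


class TestCovariancePair:
    def test_white_noise_gives_identity_and_zero_lag(self, rng):
        x = rng.standard_normal((20_000, 4))
        ts = ParcellatedTimeSeries(values=x, tr_seconds=2.0)
        cp = covariance_pair(ts, lag_trs=1)
        off = cp.q0[~np.eye(4, dtype=bool)]
        assert np.allclose(np.diag(cp.q0), 1.0, atol=0.05)
        assert np.max(np.abs(off)) < 0.05
        assert np.max(np.abs(cp.q1)) < 0.05

    def test_q0_exactly_symmetric(self, rng):
        ts = ParcellatedTimeSeries(
            values=rng.standard_normal((50, 5)), tr_seconds=2.0
        )
        cp = covariance_pair(ts)
        assert np.array_equal(cp.q0, cp.q0.T)

    def test_ou_lagged_ratio_matches_exponential_decay(self):
        # uncoupled MOU with tau = tr = 2 s: q1/q0 on the diagonal ~ e^-1
        model = MOUModel(ec=np.zeros((3, 3)), sigma=np.ones(3), tau_seconds=2.0)
        ts = simulate_mou(model, duration_seconds=40_000, tr_seconds=2.0, seed=8)
        cp = covariance_pair(ts, lag_trs=1)
        ratio = np.diag(cp.q1) / np.diag(cp.q0)
        assert np.all(np.abs(ratio - np.exp(-1)) / np.exp(-1) < 0.1)

    def test_too_short_series_rejected(self, rng):
        ts = ParcellatedTimeSeries(values=rng.standard_normal((4, 3)),
                                   tr_seconds=2.0)
        with pytest.raises(InsufficientDataError):
            covariance_pair(ts, lag_trs=2)


class TestEstimateTau:
    def test_exact_exponential_recovered_to_machine_precision(self):
        tau_true, tr = 3.7, 2.0
        amps = np.array([0.5, 1.0, 2.0])
        lags = np.arange(0, 4)
        ac = amps[None, :] * np.exp(-lags[:, None] * tr / tau_true)
        tau = tau_from_autocovariances(ac, tr)
        assert tau == pytest.approx(tau_true, rel=1e-12)

    def test_mou_simulation_recovery_within_20pct(self):
        model = MOUModel(ec=np.zeros((4, 4)), sigma=np.ones(4), tau_seconds=2.0)
        ts = simulate_mou(model, duration_seconds=20_000, tr_seconds=2.0, seed=1)
        tau = estimate_tau(ts, max_lag_trs=2)
        assert abs(tau - 2.0) / 2.0 < 0.2

    def test_single_lag_rejected(self, rng):
        ts = ParcellatedTimeSeries(values=rng.standard_normal((100, 3)),
                                   tr_seconds=2.0)
        with pytest.raises(InvalidParameterError):
            estimate_tau(ts, max_lag_trs=1)

    def test_all_nodes_nonpositive_autocov_is_estimation_error(self):
        # alternating signal: lag-1 autocovariance negative everywhere
        x = np.tile(np.array([1.0, -1.0]), 50)[:, None] * np.ones((1, 3))
        ts = ParcellatedTimeSeries(values=x, tr_seconds=2.0)
        with pytest.raises(EstimationError):
            estimate_tau(ts, max_lag_trs=2)


def random_sc(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 1.0, (n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return StructuralMatrix(counts=w)


class TestBuildSCMask:
    def test_density_pair_count_116(self):
        mask = build_sc_mask([random_sc(116, 0)], density=0.30)
        n_pairs = int(mask.mask.sum()) // 2
        assert n_pairs == round(0.30 * 116 * 115 / 2) == 2001
        assert mask.is_symmetric

    def test_density_error_at_most_one_pair(self):
        n = 37
        mask = build_sc_mask([random_sc(n, 1)], density=0.41)
        got = int(mask.mask.sum()) // 2
        assert abs(got - 0.41 * n * (n - 1) / 2) <= 1

    def test_full_density_keeps_only_positive_support(self):
        m = np.zeros((6, 6))
        m[0, 1] = m[1, 0] = 2.0
        m[2, 3] = m[3, 2] = 1.0
        mask = build_sc_mask([StructuralMatrix(m)], density=1.0)
        assert int(mask.mask.sum()) == 4  # two undirected pairs only

    def test_intersection_is_subset_of_each_group(self):
        ga = [random_sc(20, 2), random_sc(20, 3)]
        gb = [random_sc(20, 4)]
        inter = build_sc_mask([ga, gb], density=0.3, mode="intersection")
        ma = build_sc_mask(ga, density=0.3)
        mb = build_sc_mask(gb, density=0.3)
        assert np.all(~inter.mask | ma.mask)
        assert np.all(~inter.mask | mb.mask)

    def test_tie_break_is_lexicographic(self):
        m = np.ones((5, 5))
        np.fill_diagonal(m, 0.0)
        mask = build_sc_mask([StructuralMatrix(m)], density=0.3)
        # round(0.3 * 10) = 3 pairs; with all weights tied the smallest
        # (row, col) pairs win
        iu, ju = np.nonzero(np.triu(mask.mask, k=1))
        assert list(zip(iu.tolist(), ju.tolist())) == [(0, 1), (0, 2), (0, 3)]

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            build_sc_mask([], density=0.3)
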