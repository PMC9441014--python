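"""Tests of the synthetic-data generators: skeletons, MOU simulation,
cohorts, and phase-coupled signals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbec.containers import MOUModel
from wbec.errors import InvalidInputError, InvalidParameterError, StabilityError
from wbec.ignition import instantaneous_phases, phase_lock_value
from wbec.model import model_covariances
from wbec.synthetic import (
    CohortSpec,
    generate_cohort,
    make_parcellation,
    random_sc_mask,
    random_stable_model,
    simulate_mou,
    simulate_phase_signals,
)


class TestRandomSCMask:
    @pytest.mark.parametrize(
        "n,density,expected_directed",
        [
            (116, 1.0, 13_340),  # all off-diagonal cells
            (116, 0.30, 2 * round(0.30 * 116 * 115 / 2)),  # 2x2001 pairs
            (10, 0.5, 2 * round(0.5 * 45)),
        ],
    )
    def test_symmetric_density_counts(self, n, density, expected_directed):
        m = random_sc_mask(n, density, symmetric=True, seed=3)
        assert int(m.mask.sum()) == expected_directed
        assert m.is_symmetric

    def test_zero_diagonal_and_determinism(self):
        a = random_sc_mask(20, 0.4, seed=7)
        b = random_sc_mask(20, 0.4, seed=7)
        assert not np.any(np.diag(a.mask))
        assert np.array_equal(a.mask, b.mask)
        c = random_sc_mask(20, 0.4, seed=8)
        assert not np.array_equal(a.mask, c.mask)

    def test_directed_mask_counts(self):
        m = random_sc_mask(12, 0.25, symmetric=False, seed=0)
        assert int(m.mask.sum()) == round(0.25 * 12 * 11)

    @pytest.mark.parametrize("density", [0.0, -0.1, 1.5])
    def test_invalid_density(self, density):
        with pytest.raises(InvalidParameterError):
            random_sc_mask(10, density)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(3, 30), st.floats(0.05, 1.0), st.integers(0, 10))
    def test_density_rounding_property(self, n, density, seed):
        # retained pair count always equals round(density * n(n-1)/2)
        if round(density * n * (n - 1) / 2) < 1:
            return
        m = random_sc_mask(n, density, symmetric=True, seed=seed)
        assert int(m.mask.sum()) == 2 * round(density * n * (n - 1) / 2)
        assert m.is_symmetric and not np.any(np.diag(m.mask))


class TestSimulateMOU:
    def test_stationary_variance_matches_ou_closed_form(self):
        # uncoupled OU: stationary variance = sigma * tau / 2 = 0.5
        model = MOUModel(ec=np.zeros((3, 3)), sigma=np.ones(3), tau_seconds=1.0)
        ts = simulate_mou(model, duration_seconds=10_000, tr_seconds=2.0, seed=5)
        var = ts.values.var(axis=0)
        assert np.all(np.abs(var - 0.5) / 0.5 < 0.05)

    def test_seed_reproducibility_bit_identical(self):
        model = MOUModel(ec=np.zeros((2, 2)), sigma=np.ones(2), tau_seconds=1.0)
        a = simulate_mou(model, 100, tr_seconds=2.0, seed=1)
        b = simulate_mou(model, 100, tr_seconds=2.0, seed=1)
        assert np.array_equal(a.values, b.values)

    def test_sample_count(self):
        model = MOUModel(ec=np.zeros((2, 2)), sigma=np.ones(2), tau_seconds=1.0)
        ts = simulate_mou(model, duration_seconds=480, tr_seconds=2.0, seed=0)
        assert ts.values.shape == (240, 2)

    def test_unstable_model_rejected_before_simulation(self):
        ec = np.array([[0.0, 2.0], [2.0, 0.0]])  # abscissa = -1/tau + 2 > 0
        model = MOUModel(ec=ec, sigma=np.ones(2), tau_seconds=1.0)
        with pytest.raises(StabilityError):
            simulate_mou(model, 100, tr_seconds=2.0, seed=0)

    def test_long_run_covariance_matches_lyapunov_solution(self):
        # stationarity: sample covariance of a long simulation correlates
        # >= 0.95 entrywise with the analytic stationary covariance
        model = random_stable_model(3, density=1.0, tau_seconds=1.0, seed=2)
        ana = model_covariances(model, lag_trs=1, tr_seconds=1.0)
        ts = simulate_mou(model, duration_seconds=10_000, tr_seconds=1.0, seed=3)
        x = ts.values - ts.values.mean(axis=0)
        q0 = x.T @ x / (len(x) - 1)
        r = np.corrcoef(q0.ravel(), ana.q0.ravel())[0, 1]
        assert r >= 0.95


class TestGenerateCohort:
    def small_spec(self, **kw):
        defaults = dict(
            n_group_a=3, n_group_b=2, n_regions=12, n_volumes=40,
            sc_density=0.4, n_perturbed=3, perturbation_scale=1.0, seed=9,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_session_counts_and_labels(self):
        ds, truth = generate_cohort(self.small_spec())
        assert len(ds) == (3 + 2) * 2
        groups = {ts.group_label for ts in ds}
        assert groups == {"nfb", "ctl"}
        nfb_subjects = {ts.subject_id for ts in ds if ts.group_label == "nfb"}
        assert len(nfb_subjects) == 3
        for ts in ds:
            assert ts.session_label in ("pre", "post")

    def test_zero_perturbation_gives_identical_session_models(self):
        ds, truth = generate_cohort(self.small_spec(perturbation_scale=0.0))
        for sid in truth.group_labels:
            pre = truth.true_models[(sid, "pre")]
            post = truth.true_models[(sid, "post")]
            assert np.array_equal(pre.ec, post.ec)

    def test_perturbation_changes_only_group_a_post(self):
        ds, truth = generate_cohort(self.small_spec())
        for sid, g in truth.group_labels.items():
            pre = truth.true_models[(sid, "pre")]
            post = truth.true_models[(sid, "post")]
            if g == "nfb":
                diff = np.nonzero(pre.ec != post.ec)
                changed = set(zip(diff[0].tolist(), diff[1].tolist()))
                assert changed <= set(truth.perturbed_edges)
                assert changed  # at least one edge actually moved
            else:
                assert np.array_equal(pre.ec, post.ec)

    def test_explicit_edges_recorded_and_validated(self):
        ds, truth = generate_cohort(self.small_spec(seed=9))
        edges = truth.perturbed_edges
        spec2 = self.small_spec(perturbed_edges=edges, seed=9)
        _, truth2 = generate_cohort(spec2)
        assert truth2.perturbed_edges == edges
        with pytest.raises(InvalidInputError):
            diag_edge = (0, 0)
            generate_cohort(self.small_spec(perturbed_edges=[diag_edge]))

    def test_sessions_have_independent_noise(self):
        ds, truth = generate_cohort(self.small_spec(perturbation_scale=0.0))
        by_subject = {}
        for ts in ds:
            by_subject.setdefault(ts.subject_id, {})[ts.session_label] = ts
        for sess in by_subject.values():
            assert not np.array_equal(sess["pre"].values, sess["post"].values)


class TestSimulatePhaseSignals:
    def test_full_coupling_shares_one_phase(self):
        ts = simulate_phase_signals(6, coupling=1.0, n_volumes=200, seed=4)
        ph = instantaneous_phases(ts).phases
        # interior samples: identical phase trajectories across regions
        spread = np.ptp(ph[20:-20], axis=1)
        assert np.max(spread) < 1e-6

    def test_zero_coupling_low_phase_lock(self):
        ts = simulate_phase_signals(10, coupling=0.0, n_volumes=400, seed=4)
        ph = instantaneous_phases(ts).phases[20:-20]
        plvs = []
        for j in range(10):
            for k in range(j):
                plvs.append(phase_lock_value(ph[:, j], ph[:, k]).mean())
        assert np.mean(plvs) < 0.5

    def test_phase_coherence_monotone_in_coupling(self):
        means = []
        for c in (0.0, 0.6, 1.0):
            ts = simulate_phase_signals(8, coupling=c, n_volumes=300, seed=6)
            ph = instantaneous_phases(ts).phases[20:-20]
            vals = [
                phase_lock_value(ph[:, j], ph[:, k]).mean()
                for j in range(8) for k in range(j)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_seed_reproducibility(self):
        a = simulate_phase_signals(4, 0.5, 100, seed=1)
        b = simulate_phase_signals(4, 0.5, 100, seed=1)
        assert np.array_equal(a.values, b.values)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_phase_signals(4, 0.5, 100, tr_seconds=2.0, band=(0.1, 0.3))


class TestParcellation:
    def test_default_has_116_regions_with_subcortex(self):
        p = make_parcellation()
        assert len(p) == 116
        assert (p["compartment"] == "subcortical").sum() == 16
        assert set(p.columns) == {"index", "name", "network", "compartment"}
        assert p["name"].is_unique

    def test_scales_to_other_sizes(self):
        p = make_parcellation(30)
        assert len(p) == 30
        assert p["index"].tolist() == list(range(30))
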