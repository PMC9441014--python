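"""Synthetic cohorts with known ground truth.

The study this package targets is a two-group, two-session resting-state
design: a trained group whose post-session dynamics differ from the
pre-session through a small set of directed coupling changes, and a sham
group whose two sessions are statistically identical.  No such data can be
bundled, so this module generates it: sparse structural skeletons, stable
MOU dynamics simulated forward in time, and narrow-band phase-coupled
signals for the ignition stage.  Every generator is fully determined by its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import MOUModel, ParcellatedTimeSeries, SCMask
from .errors import InvalidInputError, InvalidParameterError, StabilityError

#: Target spectral abscissa of the Jacobian, in units of 1/tau.  Coupling
#: weights are scaled so the slowest network mode decays at this rate.
#: The intermediate value balances two failure modes of coupling recovery:
#: near-critical dynamics (tiny margins) mix so slowly that a session's
#: worth of samples carries little independent information, while weak
#: coupling (large margins) leaves the directional covariance signal below
#: sampling noise.
STABILITY_MARGIN = 0.25


@dataclass
class CohortSpec:
    """Study-design parameters for :func:`generate_cohort`.

    Defaults emulate the target design: 17 trained ("nfb") + 16 sham
    ("ctl") subjects, 116 regions, two sessions of 235 volumes at TR = 2 s,
    a 30%-density symmetric structural skeleton, and five directed edges —
    planted on strong backbone pathways — whose weights change between
    sessions in the trained group only.  The default effect size is strong:
    large enough that each planted edge is partially (not perfectly)
    informative through per-session EC estimation noise.
    """

    n_group_a: int = 17
    n_group_b: int = 16
    n_regions: int = 116
    sessions_per_subject: int = 2
    tr_seconds: float = 2.0
    n_volumes: int = 235
    sc_density: float = 0.30
    perturbed_edges: list[tuple[int, int]] | None = None
    n_perturbed: int = 5  # edges auto-picked from the mask when none given
    perturbation_scale: float = 5.0
    perturbation_mode: str = "multiplicative"  # or "additive"
    tau_seconds: float = 2.0
    subject_jitter: float = 0.3  # per-subject multiplicative weight spread
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise InvalidParameterError("n_regions must be >= 2")
        if self.n_volumes <= 10:
            raise InvalidParameterError("n_volumes must be > 10")
        if not 0 < self.sc_density <= 1:
            raise InvalidParameterError("sc_density must be in (0, 1]")
        if self.sc_density * self.n_regions * (self.n_regions - 1) < 1:
            raise InvalidParameterError("density too low to retain any edge")
        if self.sessions_per_subject != 2:
            raise InvalidParameterError("exactly 2 sessions (pre/post) supported")
        if self.perturbation_mode not in ("multiplicative", "additive"):
            raise InvalidParameterError("perturbation_mode must be "
                                        "'multiplicative' or 'additive'")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream validation."""

    true_models: dict[tuple[str, str], MOUModel]
    perturbed_edges: list[tuple[int, int]]
    group_labels: dict[str, str]
    session_labels: list[str] = field(default_factory=lambda: ["pre", "post"])
    mask: SCMask | None = None
    structural: np.ndarray | None = None


def random_sc_mask(
    n_regions: int, density: float, symmetric: bool = True, seed: int = 0
) -> SCMask:
    """Random binary connectivity skeleton with zero diagonal.

    For a symmetric mask, ``round(density * n(n-1)/2)`` undirected pairs are
    retained uniformly at random; for a directed mask,
    ``round(density * n(n-1))`` ordered pairs.
    """
    if n_regions < 2:
        raise InvalidParameterError("n_regions must be >= 2")
    if not 0 < density <= 1:
        raise InvalidParameterError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_regions
    mask = np.zeros((n, n), dtype=bool)
    if symmetric:
        iu, ju = np.triu_indices(n, k=1)
        k = int(round(density * n * (n - 1) / 2))
        keep = rng.choice(iu.size, size=k, replace=False)
        mask[iu[keep], ju[keep]] = True
        mask |= mask.T
    else:
        src, tgt = np.nonzero(~np.eye(n, dtype=bool))
        k = int(round(density * n * (n - 1)))
        keep = rng.choice(src.size, size=k, replace=False)
        mask[src[keep], tgt[keep]] = True
    return SCMask(mask)


def simulate_mou(
    model: MOUModel,
    duration_seconds: float,
    tr_seconds: float,
    dt_seconds: float | None = None,
    seed: int = 0,
    burn_in_tau: float = 20.0,
) -> ParcellatedTimeSeries:
    """Euler-Maruyama forward simulation of a stable MOU model.

    Integrates ``dx = J x dt + dB`` at step ``dt`` (default TR/100, small
    enough that the discretization bias of the stationary variance is about
    1%), discards a burn-in of ``burn_in_tau * tau`` seconds so the series
    is stationary, and subsamples to the TR.  Returns
    ``floor(duration / tr)`` samples.
    """
    if not model.is_stable():
        raise StabilityError("refusing to simulate an unstable MOU model")
    if dt_seconds is None:
        dt_seconds = tr_seconds / 100.0
    if dt_seconds > tr_seconds:
        raise InvalidParameterError("dt_seconds must not exceed tr_seconds")
    stride = max(1, int(round(tr_seconds / dt_seconds)))
    dt = tr_seconds / stride  # make TR an exact multiple of dt
    n = model.n_regions
    J = model.jacobian()
    A = np.eye(n) + dt * J  # one Euler step
    noise_sd = np.sqrt(dt * model.sigma)
    n_keep = int(np.floor(duration_seconds / tr_seconds))
    burn_steps = int(np.ceil(burn_in_tau * model.tau_seconds / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    out = np.empty((n_keep, n))
    for _ in range(burn_steps):
        x = A @ x + noise_sd * rng.standard_normal(n)
    for k in range(n_keep):
        for _ in range(stride):
            x = A @ x + noise_sd * rng.standard_normal(n)
        out[k] = x
    return ParcellatedTimeSeries(values=out, tr_seconds=tr_seconds)


def random_stable_model(
    n_regions: int,
    density: float = 0.3,
    tau_seconds: float = 2.0,
    seed: int = 0,
    mask: SCMask | None = None,
    sigma_range: tuple[float, float] = (0.8, 1.2),
    stability_margin: float = STABILITY_MARGIN,
) -> MOUModel:
    """Random MOU model on a sparse skeleton, scaled for stability.

    Edge weights are uniform on (0, 1) — independently per direction, so
    reciprocal connections are genuinely asymmetric — and globally rescaled
    so the Jacobian's spectral abscissa equals ``-stability_margin / tau``
    (the Perron root of a non-negative coupling matrix scales linearly, so
    the rescaling is exact).
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = random_sc_mask(n_regions, density, symmetric=True,
                              seed=int(rng.integers(2**31)))
    w = np.where(mask.mask, rng.uniform(0.0, 1.0, size=mask.mask.shape), 0.0)
    lam = np.max(np.linalg.eigvals(w.T).real)  # Perron root of coupling
    if lam > 0:
        w *= (1.0 - stability_margin) / (tau_seconds * lam)
    sigma = rng.uniform(*sigma_range, size=n_regions)
    return MOUModel(ec=w, sigma=sigma, tau_seconds=tau_seconds, mask=mask)


def _perturb(model: MOUModel, edges, scale: float, mode: str) -> MOUModel:
    ec = model.ec.copy()
    for (s, t) in edges:
        if not model.mask.mask[s, t]:
            raise InvalidInputError(f"perturbed edge ({s}, {t}) lies outside the mask")
        if mode == "multiplicative":
            ec[s, t] *= 1.0 + scale
        else:
            ec[s, t] += scale
    ec = np.clip(ec, 0.0, None)
    out = MOUModel(ec=ec, sigma=model.sigma.copy(),
                   tau_seconds=model.tau_seconds, mask=model.mask)
    if not out.is_stable():
        raise StabilityError("perturbation destabilized the model")
    return out


def generate_cohort(spec: CohortSpec):
    """Generate a two-group, two-session cohort of MOU time series.

    All subjects share a cohort-level coupling template on a shared
    structural mask — emulating the common connectome backbone of a real
    cohort — with per-subject multiplicative jitter
    (``subject_jitter``) on every edge weight and subject-specific noise
    variances.  Group-A subjects' post-session models have the planted
    edges' weights changed by ``perturbation_scale``; group-B pre and post
    sessions come from the same model (independent noise).  Each
    subject-session is simulated with an independently spawned random
    stream.

    Returns ``(dataset, truth)`` where ``dataset`` is a list of
    :class:`ParcellatedTimeSeries` (one per subject-session) and ``truth``
    a :class:`GroundTruth`.
    """
    ss = np.random.SeedSequence(spec.seed)
    mask_seed, edge_seed, template_seed, subj_seed = ss.spawn(4)
    mask = random_sc_mask(
        spec.n_regions, spec.sc_density, symmetric=True,
        seed=int(mask_seed.generate_state(1)[0] % 2**31),
    )
    # cohort-level coupling template: the shared connectome backbone
    template_rng = np.random.default_rng(template_seed)
    template = np.where(mask.mask,
                        template_rng.uniform(0.0, 1.0, mask.mask.shape), 0.0)

    edges = spec.perturbed_edges
    if edges is None:
        # plant the training effect on established pathways: only edges in
        # the top 40% of template weight are eligible.  An edge draw whose
        # perturbation would destabilize the template model is redrawn.
        all_edges = mask.edge_list()
        weights = np.array([template[e] for e in all_edges])
        eligible = [e for e, w in zip(all_edges, weights)
                    if w >= np.quantile(weights, 0.6)]
        rng = np.random.default_rng(edge_seed)
        lam0 = np.max(np.linalg.eigvals(template.T).real)
        probe_scale = (1.0 - STABILITY_MARGIN) / (spec.tau_seconds * lam0)
        probe = MOUModel(ec=template * probe_scale,
                         sigma=np.ones(spec.n_regions),
                         tau_seconds=spec.tau_seconds, mask=mask)
        edges = None
        for _ in range(50):
            idx = rng.choice(len(eligible), size=spec.n_perturbed,
                             replace=False)
            cand = [eligible[i] for i in sorted(idx.tolist())]
            try:
                # probe with headroom over the nominal scale so subject
                # jitter cannot push an individual model over the edge
                _perturb(probe, cand, 1.5 * spec.perturbation_scale,
                         spec.perturbation_mode)
            except StabilityError:
                continue
            edges = cand
            break
        if edges is None:
            raise StabilityError(
                "could not find perturbable edges keeping the model stable; "
                "reduce perturbation_scale or increase n_regions"
            )
    else:
        edges = [tuple(e) for e in edges]
        for (s, t) in edges:
            if not mask.mask[s, t]:
                raise InvalidInputError(
                    f"perturbed edge ({s}, {t}) lies outside the generated mask"
                )

    subjects = [("nfb", f"nfb{i + 1:02d}") for i in range(spec.n_group_a)]
    subjects += [("ctl", f"ctl{i + 1:02d}") for i in range(spec.n_group_b)]

    dataset: list[ParcellatedTimeSeries] = []
    true_models: dict[tuple[str, str], MOUModel] = {}
    group_labels: dict[str, str] = {}
    duration = spec.n_volumes * spec.tr_seconds
    streams = subj_seed.spawn(len(subjects))
    for (group, sid), sstream in zip(subjects, streams):
        group_labels[sid] = group
        model_seed, pre_seed, post_seed = (
            int(s.generate_state(1)[0] % 2**31) for s in sstream.spawn(3)
        )
        srng = np.random.default_rng(model_seed)
        j = spec.subject_jitter
        w = template * srng.uniform(1.0 - j, 1.0 + j, template.shape)
        lam = np.max(np.linalg.eigvals(w.T).real)
        if lam > 0:
            w *= (1.0 - STABILITY_MARGIN) / (spec.tau_seconds * lam)
        base = MOUModel(
            ec=w, sigma=srng.uniform(0.8, 1.2, spec.n_regions),
            tau_seconds=spec.tau_seconds, mask=mask,
        )
        if group == "nfb" and spec.perturbation_scale != 0:
            post_model = _perturb(
                base, edges, spec.perturbation_scale, spec.perturbation_mode
            )
        else:
            post_model = base
        for session, m, sim_seed in (
            ("pre", base, pre_seed),
            ("post", post_model, post_seed),
        ):
            ts = simulate_mou(
                m, duration_seconds=duration, tr_seconds=spec.tr_seconds,
                seed=sim_seed,
            )
            ts.subject_id = sid
            ts.session_label = session
            ts.group_label = group
            dataset.append(ts)
            true_models[(sid, session)] = m

    truth = GroundTruth(
        true_models=true_models,
        perturbed_edges=list(edges),
        group_labels=group_labels,
        mask=mask,
    )
    return dataset, truth


def simulate_phase_signals(
    n_regions: int,
    coupling: float,
    n_volumes: int,
    tr_seconds: float = 2.0,
    band: tuple[float, float] = (0.04, 0.07),
    seed: int = 0,
) -> ParcellatedTimeSeries:
    """Narrow-band signals with controllable pairwise phase coherence.

    Each region's signal is a mixture ``c * S + sqrt(1 - c^2) * n_i`` of a
    shared narrow-band process S and an independent one, then scaled by a
    region-specific amplitude.  Pairwise phase locking increases
    monotonically with the coupling c; at c = 1 every region carries the
    same phase trajectory (amplitudes still differ).
    """
    if not 0 <= coupling <= 1:
        raise InvalidParameterError("coupling must be in [0, 1]")
    low, high = band
    nyq = 0.5 / tr_seconds
    if not 0 < low < high < nyq:
        raise InvalidParameterError(
            f"band {band} Hz outside (0, Nyquist={nyq:g}) at TR={tr_seconds:g} s"
        )
    rng = np.random.default_rng(seed)
    pad = 4 * n_volumes  # generous edge padding for the band-pass filter
    T = n_volumes + 2 * pad
    sos = sps.butter(2, [low, high], btype="bandpass", fs=1.0 / tr_seconds,
                     output="sos")

    def narrowband(m):
        x = rng.standard_normal((T, m))
        y = sps.sosfiltfilt(sos, x, axis=0)[pad:pad + n_volumes]
        return y / y.std(axis=0)

    shared = narrowband(1)
    indep = narrowband(n_regions)
    amp = rng.uniform(0.5, 1.5, size=n_regions)
    mix = coupling * shared + np.sqrt(1.0 - coupling**2) * indep
    return ParcellatedTimeSeries(values=mix * amp, tr_seconds=tr_seconds)


_YEO7 = ["Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default"]
_SUBCORTICAL = ["HIP", "AMY", "pTHA", "aTHA", "NAc", "GP", "PUT", "CAU"]


def make_parcellation(n_regions: int = 116) -> pd.DataFrame:
    """Synthetic parcellation label table.

    Emulates a 100-region 7-network cortical parcellation plus 16
    subcortical regions (8 structures x 2 hemispheres) at the default size;
    for other sizes the same cortical/subcortical proportion and cyclic
    network assignment are used.  Columns: index, name, network,
    compartment.
    """
    n_sub = int(round(n_regions * 16 / 116))
    n_cort = n_regions - n_sub
    rows = []
    per_hemi = (n_cort + 1) // 2
    for i in range(n_cort):
        hemi = "LH" if i < per_hemi else "RH"
        net = _YEO7[i % len(_YEO7)]
        rows.append((i, f"{hemi}_{net}_{i + 1}", net, "cortical"))
    for k in range(n_sub):
        struct = _SUBCORTICAL[k % len(_SUBCORTICAL)]
        hemi = "L" if k < (n_sub + 1) // 2 else "R"
        rows.append((n_cort + k, f"{struct}-{hemi}{k + 1}", "Subcortical",
                     "subcortical"))
    return pd.DataFrame(rows, columns=["index", "name", "network", "compartment"])
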