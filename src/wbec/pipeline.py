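"""End-to-end pipeline driver.

Sequences the full analysis on a cohort: SC mask construction, band-pass
and covariance extraction, per-session MOU-EC fitting, within- and
between-group classification with shuffled-label surrogates, SVM-RFE
support-network extraction, and intrinsic-ignition profiling at the
whole-brain level and within the support network.  Fully reproducible from
(config, seed): stage seeds are derived deterministically from the global
seed, and the JSON report is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cl
from . import ignition as ig
from . import io as wio
from . import preprocess as pp
from . import rfe as rf
from .containers import StructuralMatrix
from .errors import InvalidParameterError, WbecError
from .model import FitOptions, fit_mou
from .synthetic import CohortSpec, generate_cohort, make_parcellation

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (global seed, stage name)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run.

    Cohort-generation fields mirror :class:`~wbec.synthetic.CohortSpec`;
    band, optimizer, classification, RFE and ignition settings follow the
    defaults of their consuming modules.
    """

    output_dir: str = "wbec_output"
    seed: int = 0
    # cohort
    synthetic: bool = True
    cohort_dir: str | None = None
    n_group_a: int = 17
    n_group_b: int = 16
    n_regions: int = 116
    n_volumes: int = 235
    tr_seconds: float = 2.0
    sc_density: float = 0.30
    n_perturbed: int = 5
    perturbation_scale: float = 5.0
    tau_seconds: float = 2.0
    # bands (Hz)
    model_band: tuple[float, float] = pp.MODEL_BAND
    ignition_band: tuple[float, float] = pp.IGNITION_BAND
    # optimizer
    rate_ec: float = FitOptions.rate_ec
    rate_sigma: float = FitOptions.rate_sigma
    max_iterations: int = FitOptions.max_iterations
    patience: int = FitOptions.patience
    # classification
    n_splits: int = 50
    test_fraction: float = 0.2
    classifiers: tuple[str, ...] = ("1nn", "svm")
    # RFE
    rfe_repetitions: int = 10
    # ignition
    window_trs: int = 4
    binarize_threshold: float = 0.5

    def validate(self) -> None:
        if self.sc_density is None or not 0 < self.sc_density <= 1:
            raise InvalidParameterError("sc_density must be in (0, 1]")
        if not 0 < self.test_fraction < 1:
            raise InvalidParameterError("test_fraction must be in (0, 1)")
        if self.n_splits < 1 or self.rfe_repetitions < 1:
            raise InvalidParameterError("n_splits and rfe_repetitions must be >= 1")
        nyq = 0.5 / self.tr_seconds
        for band in (self.model_band, self.ignition_band):
            if not 0 < band[0] < band[1] < nyq:
                raise InvalidParameterError(f"band {band} violates Nyquist")
        for clf in self.classifiers:
            if clf not in ("1nn", "svm"):
                raise InvalidParameterError(f"unknown classifier {clf!r}")
        if not self.synthetic and not self.cohort_dir:
            raise InvalidParameterError(
                "either synthetic=True or cohort_dir must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - set(known)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("model_band", "ignition_band", "classifiers"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def small_config(output_dir: str = "wbec_output", seed: int = 0) -> PipelineConfig:
    """A reduced configuration (30 regions, 8+8 subjects) that runs the full
    pipeline in well under a minute; used by the smoke tests and examples."""
    return PipelineConfig(
        output_dir=output_dir, seed=seed,
        n_group_a=8, n_group_b=8, n_regions=30, n_volumes=235,
        max_iterations=1000, n_splits=20, rfe_repetitions=5,
    )


def _load_cohort(cfg: PipelineConfig):
    root = Path(cfg.cohort_dir)
    parcellation = wio.read_parcellation(root / "parcellation.tsv")
    dataset = []
    for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for subj_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
            for f in sorted(subj_dir.glob("*.csv")):
                dataset.append(wio.read_timeseries(
                    f, parcellation, tr_seconds=cfg.tr_seconds,
                    subject_id=subj_dir.name, session_label=f.stem,
                    group_label=group_dir.name,
                ))
    return dataset, None, parcellation


def _stage(report, timings, name):
    logger.info("stage: %s", name)
    timings[name] = time.perf_counter()
    return name


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to
    ``<output_dir>/report.json`` with deterministic byte content)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stage = "cohort"
    try:
        # ---- cohort -------------------------------------------------
        _stage(report, timings, stage)
        if cfg.synthetic:
            spec = CohortSpec(
                n_group_a=cfg.n_group_a, n_group_b=cfg.n_group_b,
                n_regions=cfg.n_regions, n_volumes=cfg.n_volumes,
                tr_seconds=cfg.tr_seconds, sc_density=cfg.sc_density,
                n_perturbed=cfg.n_perturbed,
                perturbation_scale=cfg.perturbation_scale,
                tau_seconds=cfg.tau_seconds,
                seed=derive_seed(cfg.seed, "cohort"),
            )
            dataset, truth = generate_cohort(spec)
            parcellation = make_parcellation(cfg.n_regions)
        else:
            dataset, truth, parcellation = _load_cohort(cfg)
        groups = sorted({ts.group_label for ts in dataset})
        report["cohort"] = {
            "n_sessions": len(dataset),
            "n_regions": dataset[0].n_regions,
            "groups": groups,
            "n_parcellation_regions": int(len(parcellation)),
            "perturbed_edges": ([list(e) for e in truth.perturbed_edges]
                                if truth else None),
        }

        # ---- SC mask ------------------------------------------------
        stage = _stage(report, timings, "sc_mask")
        if truth is not None:
            # synthetic anatomy: average of the symmetrized subject couplings
            per_subject = {}
            for (sid, ses), m in truth.true_models.items():
                if ses == "pre":
                    per_subject[sid] = 0.5 * (m.ec + m.ec.T)
            sc_mats = [StructuralMatrix(w) for w in per_subject.values()]
        else:
            sc_dir = Path(cfg.cohort_dir) / "sc"
            sc_mats = [wio.read_sc_matrix(f) for f in sorted(sc_dir.glob("*.csv"))]
        mask = pp.build_sc_mask(sc_mats, density=cfg.sc_density, mode="average")
        report["sc_mask"] = {
            "density": mask.density,
            "n_directed_edges": int(mask.mask.sum()),
        }

        # ---- signal prep + MOU fits --------------------------------
        stage = _stage(report, timings, "fit")
        fits = {}
        fit_block = {}
        for ts in dataset:
            filtered = pp.bandpass(ts, *cfg.model_band)
            emp = pp.covariance_pair(filtered, lag_trs=1)
            tau = pp.estimate_tau(filtered)
            opts = FitOptions(
                rate_ec=cfg.rate_ec, rate_sigma=cfg.rate_sigma,
                max_iterations=cfg.max_iterations, patience=cfg.patience,
                tr_seconds=cfg.tr_seconds,
            )
            model, rep = fit_mou(emp, mask, tau_init=tau, opts=opts)
            key = (ts.subject_id, ts.session_label)
            fits[key] = {"model": model, "emp": emp, "ts": ts}
            fit_block[f"{ts.subject_id}_{ts.session_label}"] = {
                "tau_seconds": round(tau, 6),
                "iterations": rep.iterations,
                "best_pearson_r": round(rep.best_pearson_r, 6),
                "converged": rep.converged,
            }
            wio.save_model(model, rep, out / "models",
                           f"{ts.subject_id}_{ts.session_label}")
        rs = [v["best_pearson_r"] for v in fit_block.values()]
        report["fit"] = {"sessions": fit_block,
                         "mean_pearson_r": round(float(np.mean(rs)), 6)}

        # ---- classification ----------------------------------------
        stage = _stage(report, timings, "classification")
        cls_block = {}
        tasks = {}
        for g in groups:
            sess = [v for k, v in fits.items()
                    if v["ts"].group_label == g]
            tasks[f"within_{g}"] = {
                "items": sess,
                "labels": [v["ts"].session_label for v in sess],
                "metrics": ("ec", "fc"),
            }
        post = [v for v in fits.values() if v["ts"].session_label == "post"]
        tasks["between_groups_post"] = {
            "items": post,
            "labels": [v["ts"].group_label for v in post],
            "metrics": ("ec", "fc", "sc"),
        }
        ec_within_a = None
        for task, td in tasks.items():
            cls_block[task] = {}
            for metric in td["metrics"]:
                if metric == "ec":
                    inputs = [v["model"] for v in td["items"]]
                elif metric == "fc":
                    inputs = [v["emp"].q0 for v in td["items"]]
                else:
                    if truth is None:
                        continue
                    inputs = [
                        0.5 * (truth.true_models[
                            (v["ts"].subject_id, "pre")].ec
                            + truth.true_models[
                                (v["ts"].subject_id, "pre")].ec.T)
                        for v in td["items"]
                    ]
                fs = cl.build_features(
                    inputs, metric_tag=metric, mask=mask,
                    labels=td["labels"],
                    subject_ids=[v["ts"].subject_id for v in td["items"]],
                )
                # the RFE stage targets the trained group's within-session
                # EC features ("nfb" when present, else the first group)
                if metric == "ec" and task.startswith("within_"):
                    if ec_within_a is None or "nfb" in task:
                        ec_within_a = (task, fs)
                cls_block[task][metric] = {}
                for clf in cfg.classifiers:
                    sd = derive_seed(cfg.seed, f"classify:{task}:{metric}:{clf}")
                    real = cl.evaluate_classifier(
                        fs, clf, n_splits=cfg.n_splits,
                        test_fraction=cfg.test_fraction, seed=sd)
                    surr = cl.surrogate_distribution(
                        fs, clf, n_splits=cfg.n_splits,
                        test_fraction=cfg.test_fraction, seed=sd + 1)
                    comp = cl.compare_distributions(real, surr)
                    cls_block[task][metric][clf] = {
                        "mean_accuracy": round(real.mean, 6),
                        "surrogate_mean_accuracy": round(surr.mean, 6),
                        "p_vs_surrogate": float(f"{comp.p_value:.6g}"),
                        "accuracies": [round(a, 6) for a in
                                       real.accuracies.tolist()],
                    }
        report["classification"] = cls_block

        # ---- SVM-RFE support network -------------------------------
        stage = _stage(report, timings, "support_network")
        task_name, fs_ec = ec_within_a
        net = rf.select_support_network(
            fs_ec, n_repetitions=cfg.rfe_repetitions,
            test_fraction=cfg.test_fraction,
            seed=derive_seed(cfg.seed, "rfe"),
        )
        annot = rf.annotate_support(net, parcellation)
        annot.to_csv(out / "support_network.tsv", sep="\t", index=False)
        sup_block = {
            "task": task_name,
            "n_edges": len(net.edges),
            "n_nodes": len(net.node_set),
            "selected_accuracy": round(net.selected_accuracy, 6),
            "edges": [[int(s), int(t), int(r)] for (s, t, r) in net.edges],
        }
        if truth is not None:
            planted = set(map(tuple, truth.perturbed_edges))
            found = {(s, t) for (s, t, _) in net.edges}
            sup_block["planted_edge_recall"] = round(
                len(planted & found) / len(planted), 6)
            sup_block["planted_edge_precision"] = round(
                len(planted & found) / max(len(found), 1), 6)
        report["support_network"] = sup_block

        # ---- intrinsic ignition ------------------------------------
        stage = _stage(report, timings, "ignition")
        nodes_support = sorted(net.node_set)
        ign_block = {}
        profiles = {"whole_brain": {}, "support": {}}
        for level, subset in (("whole_brain", None),
                              ("support", nodes_support)):
            for v in fits.values():
                ts = v["ts"]
                prof = ig.ignition_profile(
                    ts, node_subset=subset, window_trs=cfg.window_trs,
                    band=cfg.ignition_band,
                    binarize_threshold=cfg.binarize_threshold,
                )
                profiles[level][(ts.subject_id, ts.session_label)] = prof
            ign_block[level] = {}
            for g in groups:
                subj = sorted({k[0] for k in profiles[level]
                               if fits[k]["ts"].group_label == g})
                pre = [profiles[level][(s, "pre")] for s in subj]
                postp = [profiles[level][(s, "post")] for s in subj]
                comp = ig.compare_ignition(pre, postp, paired=True)
                ign_block[level][g] = {
                    m: {"p_value": float(f"{c.p_value:.6g}"),
                        "direction": c.direction}
                    for m, c in comp.items()
                }
                ign_block[level][g]["mean_idmi_pre"] = round(float(
                    np.nanmean([p.mean_idmi() for p in pre])), 6)
                ign_block[level][g]["mean_idmi_post"] = round(float(
                    np.nanmean([p.mean_idmi() for p in postp])), 6)
                ign_block[level][g]["mean_metastability_pre"] = round(float(
                    np.nanmean([p.mean_metastability() for p in pre])), 6)
                ign_block[level][g]["mean_metastability_post"] = round(float(
                    np.nanmean([p.mean_metastability() for p in postp])), 6)
        report["ignition"] = ign_block
    except WbecError as exc:
        partial = out / "partial_report.json"
        partial.write_text(json.dumps(report, sort_keys=True, indent=1))
        raise WbecError(
            f"pipeline failed at stage {stage!r}: {exc} "
            f"(partial outputs in {partial})"
        ) from exc

    payload = json.dumps(report, sort_keys=True, indent=1)
    (out / "report.json").write_text(payload)
    marks = list(timings.items()) + [("end", time.perf_counter())]
    for (name, start), (_, nxt) in zip(marks, marks[1:]):
        logger.info("stage %-16s %6.1f s", name, nxt - start)
    logger.info("pipeline done in %.1f s (config %s, seed %d)",
                time.perf_counter() - t0, cfg.config_hash(), cfg.seed)
    return report
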