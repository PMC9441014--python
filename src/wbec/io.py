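"""Readers and writers for the package's on-disk formats.

All artifacts are plain text: time series as CSV with a region-label
header, structural matrices as header-free square CSV, parcellation tables
as TSV, fitted models as a pair of CSVs plus a JSON sidecar, cohorts as a
``cohort/<group>/<subject>/<session>.csv`` tree with a JSON ground-truth
manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MOUModel, ParcellatedTimeSeries, SCMask, StructuralMatrix
from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)


def write_timeseries(ts: ParcellatedTimeSeries, path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.region_labels)
    df.to_csv(path, index=False, float_format="%.10g")


def read_timeseries(
    path, parcellation: pd.DataFrame | None = None, tr_seconds: float = 2.0,
    subject_id: str = "", session_label: str = "", group_label: str = "",
) -> ParcellatedTimeSeries:
    """Read a time x region CSV, validating columns against a parcellation.

    If a parcellation table is given, the CSV's header must contain exactly
    its region names; columns in a different order are reordered to the
    parcellation order (logged).
    """
    df = pd.read_csv(path)
    if parcellation is not None:
        want = list(parcellation["name"])
        have = list(df.columns)
        if set(have) != set(want):
            missing = sorted(set(want) - set(have))
            extra = sorted(set(have) - set(want))
            raise SchemaError(
                f"{path}: columns do not match parcellation "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
        if have != want:
            logger.info("%s: reordering columns to parcellation order", path)
            df = df[want]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(np.argmax(bad.values)) if bad.any() else 0
            raise ParseError(f"{path}: non-numeric cell at row {row}, "
                             f"column {col!r}")
    if df.isna().any().any():
        col = df.columns[int(np.argmax(df.isna().any().values))]
        row = int(np.argmax(df[col].isna().values))
        raise ParseError(f"{path}: missing value at row {row}, column {col!r}")
    return ParcellatedTimeSeries(
        values=df.values, tr_seconds=tr_seconds,
        region_labels=list(df.columns), subject_id=subject_id,
        session_label=session_label, group_label=group_label,
    )


def write_sc_matrix(sc: StructuralMatrix | np.ndarray, path) -> None:
    m = sc.counts if isinstance(sc, StructuralMatrix) else np.asarray(sc)
    np.savetxt(path, m, delimiter=",", fmt="%.10g")


def read_sc_matrix(path) -> StructuralMatrix:
    m = np.loadtxt(path, delimiter=",")
    return StructuralMatrix(counts=m)


def write_parcellation(parcellation: pd.DataFrame, path) -> None:
    parcellation.to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"index", "name", "network", "compartment"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: parcellation must have columns {sorted(required)}"
        )
    return df


def save_model(model: MOUModel, report, directory, stem: str) -> None:
    """Write a fitted model as ``<stem>_ec.csv``, ``<stem>_sigma.csv`` and a
    JSON sidecar with tau and the fit report."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / f"{stem}_ec.csv", model.ec, delimiter=",", fmt="%.10g")
    np.savetxt(d / f"{stem}_sigma.csv", model.sigma, delimiter=",",
               fmt="%.10g")
    side = {
        "tau_seconds": model.tau_seconds,
        "iterations": getattr(report, "iterations", None),
        "best_pearson_r": getattr(report, "best_pearson_r", None),
        "converged": getattr(report, "converged", None),
        "final_error": (report.model_error_history[-1]
                        if getattr(report, "model_error_history", None)
                        else None),
    }
    (d / f"{stem}.json").write_text(json.dumps(side, sort_keys=True, indent=1))


def load_model(directory, stem: str, mask: SCMask | None = None) -> MOUModel:
    d = Path(directory)
    ec = np.loadtxt(d / f"{stem}_ec.csv", delimiter=",")
    sigma = np.loadtxt(d / f"{stem}_sigma.csv", delimiter=",")
    side = json.loads((d / f"{stem}.json").read_text())
    return MOUModel(ec=ec, sigma=sigma, tau_seconds=side["tau_seconds"],
                    mask=mask)


def write_cohort(dataset, truth, directory, parcellation=None) -> None:
    """Write a synthetic cohort as ``<group>/<subject>/<session>.csv`` plus a
    ground-truth manifest and parcellation table."""
    root = Path(directory)
    for ts in dataset:
        d = root / ts.group_label / ts.subject_id
        d.mkdir(parents=True, exist_ok=True)
        write_timeseries(ts, d / f"{ts.session_label}.csv")
    manifest = {
        "perturbed_edges": [list(e) for e in truth.perturbed_edges],
        "group_labels": truth.group_labels,
        "session_labels": truth.session_labels,
    }
    (root / "ground_truth.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    if truth.mask is not None:
        np.savetxt(root / "sc_mask.csv", truth.mask.mask.astype(int),
                   delimiter=",", fmt="%d")
    if parcellation is not None:
        write_parcellation(parcellation, root / "parcellation.tsv")
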