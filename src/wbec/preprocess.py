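"""Signal preparation: band-pass filtering, covariance pairs, time-constant
estimation, and structural-connectivity mask construction.

These are the steps between already-parcellated time series and the model
fit: the signals are narrow-band filtered, their zero-lag and lagged
covariances (FC0/FC1) computed, the nodal decay time constant estimated from
the autocovariance decay, and the structural matrices reduced to a binary
topology mask at a chosen edge density.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import CovPair, ParcellatedTimeSeries, SCMask, StructuralMatrix
from .errors import (
    EstimationError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

#: Model-fit band in Hz (broad resting-state band).
MODEL_BAND = (0.01, 0.07)
#: Ignition-analysis band in Hz (narrow band used for phase extraction).
IGNITION_BAND = (0.04, 0.07)


def _check_band(low_hz: float, high_hz: float, tr_seconds: float) -> None:
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise InvalidParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:g} Hz at TR={tr_seconds:g} s)"
        )


def bandpass(
    ts: ParcellatedTimeSeries, low_hz: float, high_hz: float
) -> ParcellatedTimeSeries:
    """Zero-phase band-pass filter applied per region.

    A second-order Butterworth filter run forward and backward
    (``sosfiltfilt``), so the output has no phase shift.  The series is
    demeaned first; the DC component is out of band anyway.
    """
    _check_band(low_hz, high_hz, ts.tr_seconds)
    x = ts.values - ts.values.mean(axis=0)
    sos = sps.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    y = sps.sosfiltfilt(sos, x, axis=0)
    return ts.replace_values(y)


def covariance_pair(ts: ParcellatedTimeSeries, lag_trs: int = 1) -> CovPair:
    """Empirical zero-lag (FC0) and lagged (FC1) covariance matrices.

    ``q0[j, k] = cov(x_j(t), x_k(t))`` and ``q1[j, k] = cov(x_j(t),
    x_k(t + lag))``; the series are demeaned per node and the sums
    normalized by (number of terms - 1).
    """
    if lag_trs < 1:
        raise InvalidParameterError("lag_trs must be >= 1")
    T = ts.n_volumes
    if T <= lag_trs + 2:
        raise InsufficientDataError(
            f"need more than lag_trs + 2 = {lag_trs + 2} time points, got {T}"
        )
    x = ts.values - ts.values.mean(axis=0)
    q0 = x.T @ x / (T - 1)
    q0 = 0.5 * (q0 + q0.T)
    q1 = x[:-lag_trs].T @ x[lag_trs:] / (T - lag_trs - 1)
    return CovPair(q0=q0, q1=q1, lag_trs=lag_trs)


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-node autocovariance at lags 0..max_lag, shape (max_lag+1, n)."""
    T, n = x.shape
    xc = x - x.mean(axis=0)
    out = np.empty((max_lag + 1, n))
    for k in range(max_lag + 1):
        if k == 0:
            out[k] = (xc * xc).sum(axis=0) / (T - 1)
        else:
            out[k] = (xc[:-k] * xc[k:]).sum(axis=0) / (T - k - 1)
    return out


def tau_from_autocovariances(ac: np.ndarray, tr_seconds: float) -> float:
    """Log-linear decay fit on per-node autocovariances.

    ``ac`` has shape (max_lag + 1, n_regions) with lag-0 in the first row;
    the slope of log autocovariance versus lag (seconds) is fitted per node
    over lags 1..max_lag for nodes whose used autocovariances are positive,
    and tau = -1/slope averaged over those nodes.
    """
    max_lag = ac.shape[0] - 1
    if max_lag < 2:
        raise InvalidParameterError("need autocovariances up to lag >= 2")
    lags_s = np.arange(1, max_lag + 1) * tr_seconds
    used = ac[1:]
    valid = np.all(used > 0, axis=0)
    if not np.any(valid):
        raise EstimationError(
            "autocovariance non-positive at a used lag for every node"
        )
    logac = np.log(used[:, valid])
    slopes = np.polyfit(lags_s, logac, 1)[0]
    slopes = slopes[slopes < 0]
    if slopes.size == 0:
        raise EstimationError("no node shows decaying autocovariance")
    taus = -1.0 / slopes
    return float(taus.mean())


def estimate_tau(ts: ParcellatedTimeSeries, max_lag_trs: int = 2) -> float:
    """Estimate the nodal decay time constant tau (seconds).

    For an OU node the autocovariance decays as ``a(k) = a(0) exp(-k tr /
    tau)``, so log a(k) is linear in the lag.  The slope of log
    autocovariance versus lag (in seconds) is fitted per node over lags
    1..max_lag_trs, restricted to nodes whose autocovariances at all used
    lags are positive, and tau = -1/slope averaged over those nodes.
    """
    if max_lag_trs < 2:
        raise InvalidParameterError("max_lag_trs must be >= 2 (a slope needs 2 lags)")
    if ts.n_volumes <= max_lag_trs + 2:
        raise InsufficientDataError("series too short for requested max_lag_trs")
    ac = _autocovariances(ts.values, max_lag_trs)
    return tau_from_autocovariances(ac, ts.tr_seconds)


def _average_mode_mask(sc_list: list[StructuralMatrix], density: float) -> np.ndarray:
    n = sc_list[0].n_regions
    mean_w = np.mean([sc.counts for sc in sc_list], axis=0)
    iu, ju = np.triu_indices(n, k=1)
    weights = mean_w[iu, ju]
    k = int(round(density * n * (n - 1) / 2))
    positive = weights > 0
    # order by descending weight; ties broken by the lexicographically
    # smallest (row, column) pair so the mask is deterministic
    order = np.lexsort((ju, iu, -weights))
    order = order[positive[order]]
    keep = order[: min(k, order.size)]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    return mask


def build_sc_mask(
    sc_list, density: float, mode: str = "average"
) -> SCMask:
    """Reduce structural matrices to a binary mask at a target density.

    ``mode='average'``: element-wise mean across the matrices in ``sc_list``,
    then keep the top ``density`` fraction of undirected pairs by weight
    (pairs with zero mean weight are never kept).

    ``mode='intersection'``: ``sc_list`` is a list of groups (each a list of
    :class:`StructuralMatrix`); an average-mode mask is built per group and
    their element-wise AND returned.  This retains only connections above
    threshold in every group, the variant used when comparing groups whose
    anatomy may differ.
    """
    if not 0 < density <= 1:
        raise InvalidParameterError("density must be in (0, 1]")
    if not sc_list:
        raise InvalidInputError("sc_list is empty")
    if mode == "average":
        sizes = {sc.n_regions for sc in sc_list}
        if len(sizes) != 1:
            raise InvalidInputError("all structural matrices must have the same size")
        return SCMask(_average_mode_mask(list(sc_list), density))
    if mode == "intersection":
        masks = []
        for group in sc_list:
            if not group:
                raise InvalidInputError("a group in sc_list is empty")
            masks.append(_average_mode_mask(list(group), density))
        out = masks[0]
        for m in masks[1:]:
            out = out & m
        return SCMask(out)
    raise InvalidParameterError(f"unknown mode {mode!r}")
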