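"""Intrinsic-ignition analysis of spatiotemporal dynamics.

An "event" is a rising crossing of one standard deviation in a region's
standardized narrow-band signal.  For each event, the network's phase-lock
matrix ``P_jk(t) = exp(-3 |phi_j(t) - phi_k(t)|)`` (circular distance) is
binarized over a short window following the event, and the size of the
largest connected component of the resulting graph — normalized by the
number of analyzed nodes — measures how broadly the event's activity is
integrated.  Per region, the mean of this integration over its events is
the Intrinsic-Driven Mean Integration (IDMI) and its standard deviation the
metastability: the tendency to switch between integration states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats

from .classify import ComparisonResult
from .containers import ParcellatedTimeSeries
from .errors import InvalidInputError, InvalidParameterError
from .preprocess import IGNITION_BAND, bandpass

DEFAULT_WINDOW_TRS = 4
DEFAULT_BINARIZE_THRESHOLD = 0.5
EVENT_THRESHOLD_SD = 1.0


@dataclass
class PhaseSeries:
    """Instantaneous phases (time x region), values in (-pi, pi]."""

    phases: np.ndarray
    band_hz: tuple[float, float]
    tr_seconds: float

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(self.phases > np.pi) or np.any(self.phases <= -np.pi):
            raise InvalidInputError("phases must lie in (-pi, pi]")

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_regions(self) -> int:
        return self.phases.shape[1]


@dataclass
class EventRaster:
    """Binary time x region raster of rising-edge threshold crossings."""

    events: np.ndarray
    threshold_sd: float
    flagged_regions: list[int] = field(default_factory=list)


@dataclass
class IgnitionProfile:
    """Per-region IDMI and metastability over a node subset.

    Regions with no events carry NaN IDMI; regions with fewer than two
    events carry NaN metastability.  Both are excluded from summaries via
    nan-aware aggregation.
    """

    idmi: np.ndarray
    metastability: np.ndarray
    node_subset: np.ndarray
    window_trs: int
    n_events: np.ndarray
    subject_id: str = ""
    session_label: str = ""
    group_label: str = ""

    def mean_idmi(self) -> float:
        return float(np.nanmean(self.idmi)) if np.any(
            np.isfinite(self.idmi)) else float("nan")

    def mean_metastability(self) -> float:
        return float(np.nanmean(self.metastability)) if np.any(
            np.isfinite(self.metastability)) else float("nan")


def instantaneous_phases(
    ts: ParcellatedTimeSeries, band: tuple[float, float] = IGNITION_BAND
) -> PhaseSeries:
    """Hilbert phases of the band-passed, demeaned signal."""
    filtered = bandpass(ts, band[0], band[1])
    x = filtered.values - filtered.values.mean(axis=0)
    phases = np.angle(hilbert(x, axis=0))
    # np.angle returns [-pi, pi]; fold the closed lower endpoint
    phases[phases == -np.pi] = np.pi
    return PhaseSeries(phases=phases, band_hz=tuple(band),
                       tr_seconds=ts.tr_seconds)


def phase_lock_value(phi_j, phi_k):
    """Pairwise phase-locking ``exp(-3 d)`` with d the circular distance.

    The raw phase difference is wrapped to [0, pi] before the exponential,
    so antiphase pairs score exp(-3 pi) and identical phases score 1.
    Accepts scalars or arrays (broadcast).
    """
    d = np.abs(np.mod(np.asarray(phi_j) - np.asarray(phi_k) + np.pi,
                      2 * np.pi) - np.pi)
    return np.exp(-3.0 * d)


def detect_events(ts: ParcellatedTimeSeries,
                  threshold_sd: float = EVENT_THRESHOLD_SD) -> EventRaster:
    """Rising-edge events of the standardized signal.

    Each region's series is z-scored; an event is marked at sample t when
    z crosses above the threshold from below (one event per excursion).
    Zero-variance regions are flagged and carry no events.
    """
    x = ts.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    flagged = np.where(sd == 0)[0].tolist()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd_safe
    above = z > threshold_sd
    events = np.zeros_like(above)
    events[1:] = above[1:] & ~above[:-1]
    events[:, flagged] = False
    return EventRaster(events=events, threshold_sd=threshold_sd,
                       flagged_regions=flagged)


def _largest_component_size(binary: np.ndarray) -> int:
    graph = csr_matrix(binary)
    n_comp, labels = connected_components(graph, directed=False)
    return int(np.bincount(labels).max())


def integration_for_event(
    phases: PhaseSeries,
    event_time: int,
    node_subset,
    window_trs: int = DEFAULT_WINDOW_TRS,
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> float:
    """Normalized integration elicited by one event.

    For each sample in ``[event_time, event_time + window_trs)`` the
    phase-lock matrix over ``node_subset`` is binarized at
    ``binarize_threshold`` and the largest connected component of the
    resulting undirected graph measured; the integration is the mean
    component size over the window divided by the subset size, in
    (0, 1].
    """
    nodes = np.asarray(node_subset, dtype=int)
    if nodes.size == 0:
        raise InvalidInputError("node_subset is empty")
    if event_time < 0 or event_time + window_trs > phases.n_volumes:
        raise InvalidParameterError(
            f"window [{event_time}, {event_time + window_trs}) does not fit "
            f"in a series of {phases.n_volumes} samples"
        )
    sizes = []
    for t in range(event_time, event_time + window_trs):
        phi = phases.phases[t, nodes]
        P = phase_lock_value(phi[:, None], phi[None, :])
        B = P >= binarize_threshold
        sizes.append(_largest_component_size(B))
    return float(np.mean(sizes) / nodes.size)


def ignition_profile(
    ts: ParcellatedTimeSeries,
    node_subset=None,
    window_trs: int = DEFAULT_WINDOW_TRS,
    band: tuple[float, float] = IGNITION_BAND,
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    event_threshold_sd: float = EVENT_THRESHOLD_SD,
) -> IgnitionProfile:
    """Per-region IDMI and metastability for one subject-session.

    Events are detected on the band-passed signal; for every event elicited
    by a region in ``node_subset`` (default: all regions), the integration
    within the following ``window_trs``-sample window is computed over the
    subset.  IDMI(r) is the mean and metastability(r) the standard
    deviation of region r's event-wise integrations.  Events whose window
    overruns the series are discarded.
    """
    nodes = (np.arange(ts.n_regions) if node_subset is None
             else np.asarray(sorted(node_subset), dtype=int))
    if np.any(nodes < 0) or np.any(nodes >= ts.n_regions):
        raise InvalidInputError("node_subset outside region range")
    if ts.n_volumes < window_trs:
        raise InvalidInputError("series shorter than one integration window")
    filtered = bandpass(ts, band[0], band[1])
    phases = instantaneous_phases(ts, band=band)
    raster = detect_events(filtered, threshold_sd=event_threshold_sd)

    idmi = np.full(nodes.size, np.nan)
    meta = np.full(nodes.size, np.nan)
    counts = np.zeros(nodes.size, dtype=int)
    for i, r in enumerate(nodes):
        times = np.nonzero(raster.events[:, r])[0]
        times = times[times + window_trs <= ts.n_volumes]
        if times.size == 0:
            continue
        vals = np.array([
            integration_for_event(phases, int(t), nodes, window_trs,
                                  binarize_threshold)
            for t in times
        ])
        counts[i] = vals.size
        idmi[i] = vals.mean()
        if vals.size >= 2:
            meta[i] = vals.std()
        elif vals.size == 1:
            meta[i] = np.nan  # undefined variability from a single event
    return IgnitionProfile(
        idmi=idmi, metastability=meta, node_subset=nodes,
        window_trs=window_trs, n_events=counts,
        subject_id=ts.subject_id, session_label=ts.session_label,
        group_label=ts.group_label,
    )


def compare_ignition(
    profiles_a: list[IgnitionProfile],
    profiles_b: list[IgnitionProfile],
    paired: bool = False,
) -> dict[str, ComparisonResult]:
    """Compare IDMI and metastability between two sets of profiles.

    Each profile is aggregated to its nan-mean over the node subset; the
    subject-level values are then compared with the Wilcoxon signed-rank
    test (paired, matching order required) or the rank-sum test
    (unpaired).  Returns one :class:`ComparisonResult` per measure.
    """
    if paired:
        if len(profiles_a) != len(profiles_b):
            raise InvalidInputError("paired comparison needs equal-length lists")
        for pa, pb in zip(profiles_a, profiles_b):
            if pa.subject_id and pb.subject_id and pa.subject_id != pb.subject_id:
                raise InvalidInputError(
                    f"paired profiles out of order: {pa.subject_id} vs "
                    f"{pb.subject_id}"
                )
    out = {}
    for measure, getter in (
        ("idmi", lambda p: p.mean_idmi()),
        ("metastability", lambda p: p.mean_metastability()),
    ):
        a = np.array([getter(p) for p in profiles_a])
        b = np.array([getter(p) for p in profiles_b])
        ok = np.isfinite(a) & np.isfinite(b) if paired else None
        if paired:
            a2, b2 = a[ok], b[ok]
            diffs = a2 - b2
            if diffs.size == 0 or np.all(diffs == 0):
                res = ComparisonResult(statistic=0.0, p_value=1.0,
                                       direction="equal")
            else:
                stat, p = stats.wilcoxon(a2, b2)
                res = ComparisonResult(
                    statistic=float(stat), p_value=float(p),
                    direction="a" if a2.mean() > b2.mean() else "b",
                )
        else:
            a2, b2 = a[np.isfinite(a)], b[np.isfinite(b)]
            if a2.size == 0 or b2.size == 0:
                raise InvalidInputError("no finite values to compare")
            stat, p = stats.ranksums(a2, b2)
            if a2.mean() == b2.mean():
                direction = "equal"
            else:
                direction = "a" if a2.mean() > b2.mean() else "b"
            res = ComparisonResult(statistic=float(stat), p_value=float(p),
                                   direction=direction)
        out[measure] = res
    return out
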