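"""Core in-memory containers shared across the analysis stages.

The pipeline moves a small set of objects between stages: parcellated
region x time signals (:class:`ParcellatedTimeSeries`), structural
connectivity and its binary mask (:class:`StructuralMatrix`,
:class:`SCMask`), the pair of zero-lag / lagged covariance matrices the
model is fitted to (:class:`CovPair`), and the generative model itself
(:class:`MOUModel`).  They are plain dataclasses over numpy arrays with
validation at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError


@dataclass
class ParcellatedTimeSeries:
    """One subject-session's region-parcellated signal.

    Parameters
    ----------
    values : ndarray, shape (n_volumes, n_regions)
        Signal samples, time on the first axis.
    tr_seconds : float
        Sampling interval (the fMRI repetition time, TR).
    region_labels : list of str
        One label per column.
    subject_id, session_label, group_label : str
        Cohort bookkeeping; empty strings when not applicable.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    session_label: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("time series must be a 2-D time x region array")
        if self.values.shape[1] < 2:
            raise InvalidInputError("need at least 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise InvalidParameterError("tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.values.shape[1])]
        if len(self.region_labels) != self.values.shape[1]:
            raise InvalidInputError(
                "region_labels length does not match number of columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "ParcellatedTimeSeries":
        """Return a copy with the same metadata and new sample values."""
        return ParcellatedTimeSeries(
            values=values,
            tr_seconds=self.tr_seconds,
            region_labels=list(self.region_labels),
            subject_id=self.subject_id,
            session_label=self.session_label,
            group_label=self.group_label,
        )


@dataclass
class StructuralMatrix:
    """Symmetric non-negative region x region structural connectivity.

    Entries are streamline-count-like weights; the diagonal is zero.  Raw
    tractography gives two directed counts per pair; upstream they are
    averaged into one symmetric value, which is what this container holds.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != m:
            raise InvalidInputError("structural matrix must be square")
        if np.any(self.counts < 0):
            raise InvalidInputError("structural weights must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise InvalidInputError("structural matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise InvalidInputError("structural matrix diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]


@dataclass
class SCMask:
    """Binary region x region connectivity skeleton (zero diagonal)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m = self.mask.shape
        if n != m:
            raise InvalidInputError("mask must be square")
        if np.any(np.diag(self.mask)):
            raise InvalidInputError("mask diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.mask.shape[0]

    @property
    def density(self) -> float:
        """Fraction of off-diagonal entries that are nonzero."""
        n = self.n_regions
        return float(self.mask.sum()) / (n * (n - 1))

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.mask, self.mask.T))

    def edge_list(self) -> list[tuple[int, int]]:
        """Directed (source, target) pairs in row-major order."""
        src, tgt = np.nonzero(self.mask)
        return list(zip(src.tolist(), tgt.tolist()))


@dataclass
class CovPair:
    """Zero-lag (FC0) and lagged (FC1) covariance matrices.

    ``q0[j, k]`` is the covariance of regions j and k at lag 0; ``q1[j, k]``
    is the covariance of region j at time t with region k at time
    t + lag_trs * TR.  q0 is symmetric; q1 in general is not.
    """

    q0: np.ndarray
    q1: np.ndarray
    lag_trs: int = 1

    def __post_init__(self):
        self.q0 = np.asarray(self.q0, dtype=float)
        self.q1 = np.asarray(self.q1, dtype=float)
        if self.q0.shape != self.q1.shape or self.q0.shape[0] != self.q0.shape[1]:
            raise InvalidInputError("q0 and q1 must be square matrices of equal size")
        if not np.allclose(self.q0, self.q0.T, atol=1e-10):
            raise InvalidInputError("q0 must be symmetric")
        if self.lag_trs < 0:
            raise InvalidParameterError("lag_trs must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.q0.shape[0]


@dataclass
class MOUModel:
    """Multivariate Ornstein-Uhlenbeck generative model.

    The dynamics of region i are
    ``dx_i = (-x_i / tau + sum_{j != i} C_ji x_j) dt + dB_i``
    where C is the directed effective-connectivity matrix stored as
    ``ec[source, target]`` (C_ji = ec[j, i]), ``tau_seconds`` the nodal decay
    time constant, and ``sigma`` the diagonal of the noise covariance.

    The Jacobian is ``J = -I/tau + ec.T`` (J[target, source] = ec[source,
    target]); stability requires every eigenvalue of J to have negative real
    part.
    """

    ec: np.ndarray
    sigma: np.ndarray
    tau_seconds: float
    mask: SCMask | None = None

    def __post_init__(self):
        self.ec = np.asarray(self.ec, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        n, m = self.ec.shape
        if n != m:
            raise InvalidInputError("ec must be square")
        if self.sigma.shape[0] != n:
            raise InvalidInputError("sigma length must match ec size")
        if np.any(self.sigma <= 0):
            raise InvalidInputError("sigma entries must be strictly positive")
        if self.tau_seconds <= 0:
            raise InvalidParameterError("tau_seconds must be positive")
        if np.any(self.ec < 0):
            raise InvalidInputError("ec weights must be non-negative")
        if np.any(np.diag(self.ec) != 0):
            raise InvalidInputError("ec diagonal must be zero")
        if self.mask is not None and np.any(self.ec[~self.mask.mask] != 0):
            raise InvalidInputError("ec has nonzero entries outside the SC mask")

    @property
    def n_regions(self) -> int:
        return self.ec.shape[0]

    def jacobian(self) -> np.ndarray:
        n = self.n_regions
        return -np.eye(n) / self.tau_seconds + self.ec.T

    def spectral_abscissa(self) -> float:
        """Largest real part among the Jacobian's eigenvalues."""
        return float(np.max(np.linalg.eigvals(self.jacobian()).real))

    def is_stable(self) -> bool:
        return self.spectral_abscissa() < 0

    def copy(self) -> "MOUModel":
        return MOUModel(
            ec=self.ec.copy(),
            sigma=self.sigma.copy(),
            tau_seconds=self.tau_seconds,
            mask=self.mask,
        )
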