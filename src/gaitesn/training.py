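"""Readout training: standard ridge regression and kernel-weighted variants.

The readout of an echo state network is fit in closed form from streaming
normal equations

    XXT = sum_p X_p P_p X_p^T,   YXT = sum_p Y_p P_p X_p^T,
    W_out = YXT (XXT + gamma I)^{-1}

where P_p is a diagonal per-sample importance matrix (identity for standard
training).  Kernel training fits a bank of readouts, each specialized to a
region of a gait temporal parameter (cycle duration, stance duration or
stance proportion): every sample of record p receives the weight
exp(-(v_p - c_k)^2 / (2 w^2)) with v_p the record's mean parameter value and
c_k the kernel centre.  At prediction time the readout whose centre is
nearest to the record's (predicted) parameter is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "NormalEquations",
    "KernelBank",
    "TrainedReadout",
    "accumulate_normal_equations",
    "solve_ridge",
    "kernel_importance",
    "train_standard",
    "train_kernel",
    "select_kernel",
    "default_centers",
    "RidgeReadout",
]

WEIGHTING_VARIABLES = ("cycle_duration", "stance_proportion", "stance_duration")


@dataclass
class NormalEquations:
    """Accumulated Gram and cross matrices of a (weighted) ridge problem."""

    xxt: np.ndarray  # (N, N)
    yxt: np.ndarray  # (N_out, N)
    n_samples: int = 0
    total_weight: float = 0.0

    @classmethod
    def empty(cls, n_states: int, n_outputs: int) -> "NormalEquations":
        return cls(
            xxt=np.zeros((n_states, n_states)),
            yxt=np.zeros((n_outputs, n_states)),
        )

    def add(self, states: np.ndarray, targets: np.ndarray,
            weights: np.ndarray | None = None) -> "NormalEquations":
        """Accumulate one record; ``states`` (N, T), ``targets`` (N_out, T)."""
        states = np.asarray(states, dtype=float)
        targets = np.asarray(targets, dtype=float)
        if states.shape[1] != targets.shape[1]:
            raise ValueError(
                f"states T={states.shape[1]} != targets T={targets.shape[1]}"
            )
        if weights is None:
            xw = states
            self.total_weight += states.shape[1]
        else:
            weights = np.asarray(weights, dtype=float).ravel()
            if weights.shape[0] != states.shape[1]:
                raise ValueError("one weight per sample is required")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")
            xw = states * weights
            self.total_weight += float(weights.sum())
        self.xxt += xw @ states.T
        self.yxt += targets @ xw.T
        self.n_samples += states.shape[1]
        return self


def accumulate_normal_equations(
    states_per_record,
    targets_per_record,
    weights_per_record=None,
) -> NormalEquations:
    """Sum the weighted normal equations over records without concatenating.

    Accumulation is order-independent (a plain sum over records).  Weights,
    when given, provide one non-negative importance value per sample.
    """
    states_per_record = list(states_per_record)
    targets_per_record = list(targets_per_record)
    if not states_per_record:
        raise ValueError("at least one record is required")
    if weights_per_record is None:
        weights_per_record = [None] * len(states_per_record)
    else:
        weights_per_record = list(weights_per_record)
    ne = NormalEquations.empty(
        states_per_record[0].shape[0], targets_per_record[0].shape[0]
    )
    for x, y, w in zip(states_per_record, targets_per_record, weights_per_record):
        ne.add(x, y, w)
    return ne


def solve_ridge(ne: NormalEquations, gamma: float) -> np.ndarray:
    """W_out = YXT (XXT + gamma I)^{-1} via a symmetric solve.

    Raises a LinAlgError naming the remedy when the unregularized system is
    singular.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = ne.xxt.shape[0]
    a = ne.xxt + gamma * np.eye(n)
    try:
        # A is symmetric PSD; solve A Z = YXT^T, W_out = Z^T
        z = sla.solve(a, ne.yxt.T, assume_a="pos")
    except (np.linalg.LinAlgError, sla.LinAlgError):
        raise np.linalg.LinAlgError(
            "normal equations are singular; use a regularization gamma > 0"
        ) from None
    return z.T


def kernel_importance(values, center: float, width: float) -> np.ndarray:
    """Gaussian sample importance exp(-(v - c)^2 / (2 w^2)).

    ``values`` holds the temporal-parameter value attached to each sample;
    within a record every sample shares the record's mean parameter value, so
    a record's weight is constant across its samples.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    v = np.asarray(values, dtype=float)
    return np.exp(-((v - center) ** 2) / (2.0 * width**2))


@dataclass
class KernelBank:
    """A bank of centre-specialized readout matrices."""

    weighting_variable: str
    centers: np.ndarray
    width: float
    readouts: list  # one (N_out, N) array per centre
    usable: np.ndarray = field(default=None)  # bool per centre

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if len(self.readouts) != self.centers.size:
            raise ValueError("one readout per centre is required")
        if self.usable is None:
            self.usable = np.ones(self.centers.size, dtype=bool)


@dataclass
class TrainedReadout:
    """A trained readout: a single matrix or a kernel bank."""

    mode: str  # "standard" | "kernel"
    w_out: np.ndarray | None = None
    bank: KernelBank | None = None
    gamma: float = 1e-6
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode == "standard" and self.w_out is None:
            raise ValueError("standard mode requires w_out")
        if self.mode == "kernel" and self.bank is None:
            raise ValueError("kernel mode requires a KernelBank")


def train_standard(
    states_per_record,
    targets_per_record,
    gamma: float = 1e-6,
    metadata: dict | None = None,
) -> TrainedReadout:
    """Single readout from unit-weight normal equations over all records."""
    ne = accumulate_normal_equations(states_per_record, targets_per_record)
    w_out = solve_ridge(ne, gamma)
    return TrainedReadout(
        mode="standard", w_out=w_out, gamma=gamma, metadata=metadata or {}
    )


def default_centers(values, n_centers: int = 5) -> np.ndarray:
    """Equally spaced centres over the [5th, 95th] percentile of ``values``."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [5.0, 95.0])
    if hi <= lo:
        # degenerate spread: spread centres minimally around the common value
        span = max(abs(lo) * 1e-3, 1e-6)
        lo, hi = lo - span, hi + span
    return np.linspace(lo, hi, n_centers)


_DEGENERATE_WEIGHT = 1e-12


def train_kernel(
    states_per_record,
    targets_per_record,
    record_parameters,
    variable: str,
    centers=None,
    width: float | None = None,
    gamma: float = 1e-6,
    n_centers: int = 5,
    metadata: dict | None = None,
) -> TrainedReadout:
    """Bank of Gaussian-weighted ridge readouts specialized by temporal parameter.

    Parameters
    ----------
    record_parameters:
        One mean parameter value per training record (seconds for durations,
        unitless for the stance proportion), as obtained from labeled gait
        events on the training split.
    variable:
        Which temporal parameter the bank is keyed on.
    centers, width:
        Kernel centres and Gaussian sd.  Defaults: ``n_centers`` centres
        equally spaced over the [5th, 95th] percentile range of the observed
        parameters, width = half the centre spacing.
    """
    if variable not in WEIGHTING_VARIABLES:
        raise ValueError(f"variable must be one of {WEIGHTING_VARIABLES}")
    states_per_record = list(states_per_record)
    targets_per_record = list(targets_per_record)
    params = np.asarray(record_parameters, dtype=float)
    if params.size != len(states_per_record):
        raise ValueError("one parameter value per record is required")
    if params.size < 2:
        raise ValueError("kernel training requires >= 2 records")
    if centers is None:
        centers = default_centers(params, n_centers)
    centers = np.asarray(centers, dtype=float)
    if centers.size < 2:
        raise ValueError("at least 2 centres are required")
    if width is None:
        width = float(np.mean(np.diff(centers))) / 2.0
    if width <= 0:
        raise ValueError("width must be positive")

    readouts = []
    usable = np.ones(centers.size, dtype=bool)
    for k, c in enumerate(centers):
        rec_weights = kernel_importance(params, c, width)
        if rec_weights.sum() < _DEGENERATE_WEIGHT:
            warnings.warn(
                f"kernel centre {c:g} has ~zero total weight; readout marked "
                "unusable", stacklevel=2,
            )
            usable[k] = False
            readouts.append(None)
            continue
        weights_per_record = [
            np.full(x.shape[1], wv) for x, wv in zip(states_per_record, rec_weights)
        ]
        ne = accumulate_normal_equations(
            states_per_record, targets_per_record, weights_per_record
        )
        readouts.append(solve_ridge(ne, gamma))
    bank = KernelBank(
        weighting_variable=variable, centers=centers, width=width,
        readouts=readouts, usable=usable,
    )
    return TrainedReadout(
        mode="kernel", bank=bank, gamma=gamma, metadata=metadata or {}
    )


def select_kernel(bank: KernelBank, record_parameter: float) -> np.ndarray:
    """Readout whose centre is nearest the record's parameter (ties: lower centre)."""
    if not np.isfinite(record_parameter):
        raise ValueError("record_parameter must be finite")
    if not np.any(bank.usable):
        raise RuntimeError("no usable kernel readout in the bank")
    dist = np.abs(bank.centers - record_parameter)
    dist[~bank.usable] = np.inf
    # argmin returns the first (= lowest-centre) index on ties
    return bank.readouts[int(np.argmin(dist))]


class RidgeReadout(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator for the linear ESN readout.

    ``fit(X, y, sample_weight=...)`` solves the (weighted) regularized normal
    equations with X of shape (T, n_states) and y of shape (T,) or
    (T, n_outputs); ``predict`` applies ``coef_``.  This is the estimator
    behind :func:`train_standard` / :func:`train_kernel`, exposed so the
    readout composes with sklearn pipelines after
    :class:`~gaitesn.reservoir.EchoStateTransformer`.
    """

    def __init__(self, gamma: float = 1e-6):
        self.gamma = gamma

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        ne = accumulate_normal_equations(
            [X.T], [y.T], None if sample_weight is None else [sample_weight]
        )
        self.coef_ = solve_ridge(ne, self.gamma)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("RidgeReadout is not fitted")
        out = np.asarray(X, dtype=float) @ self.coef_.T
        return out[:, 0] if out.shape[1] == 1 else out
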