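"""Leaky echo state network: fixed random weights, driven state trajectories.

An ESN maps an input sequence u(t) through a large fixed random recurrent
layer; only a linear readout is ever trained.  The state update is

    x~(t) = tanh(W_in u(t) + W x(t-1))
    x(t)  = alpha * x~(t) + (1 - alpha) * x(t-1)

with leak rate alpha in (0, 1] controlling the forgetting of past states.
The recurrent matrix W is sparse with a pinned spectral radius; the input
matrix W_in is dense uniform.  A variant update that retains the previous
state with coefficient (alpha - 1) instead of (1 - alpha) is available via
``leak_variant="printed"`` for comparison; it is not the default because it
flips the sign of the retained state and loses the fading-memory
interpretation at small alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EsnHyperparameters",
    "Reservoir",
    "DEFAULT_HYPERPARAMETERS",
    "build_reservoir",
    "run_reservoir",
    "readout",
    "EchoStateTransformer",
]


@dataclass(frozen=True)
class EsnHyperparameters:
    """Reservoir construction and update parameters.

    Defaults follow an optimization study for gait signals: 100 nodes, leak
    rate 0.1053, spectral radius 0.7471, recurrent sparsity 0.21 and ridge
    regularization 1e-6.
    """

    n_nodes: int = 100
    leak_rate: float = 0.1053
    spectral_radius: float = 0.7471
    sparsity: float = 0.21
    regularization: float = 1e-6
    input_scaling: float = 1.0
    seed: int = 0
    leak_variant: str = "standard"  # or "printed"

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0.0 < self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in (0, 1]")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be positive")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.leak_variant not in ("standard", "printed"):
            raise ValueError("leak_variant must be 'standard' or 'printed'")


DEFAULT_HYPERPARAMETERS = EsnHyperparameters()


@dataclass(frozen=True)
class Reservoir:
    """Fixed random weights of one ESN instance."""

    w_in: np.ndarray  # (N, N_in)
    w: np.ndarray  # (N, N)
    hyperparameters: EsnHyperparameters

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]


_MAX_RESAMPLE = 8


def build_reservoir(hp: EsnHyperparameters, n_inputs: int) -> Reservoir:
    """Sample reservoir weights from the hyperparameters.

    W has Bernoulli(sparsity) support with non-zero values uniform on
    [-1, 1], rescaled so its spectral radius equals ``hp.spectral_radius``
    exactly (within floating-point roundoff).  W_in is dense uniform on
    [-input_scaling, +input_scaling].  Construction is a pure function of
    (hp, n_inputs): the same seed reproduces the same weights bit-for-bit.
    """
    if n_inputs < 2:
        raise ValueError("n_inputs must be >= 2 (bias plus at least one axis)")
    rng = np.random.default_rng(hp.seed)
    n = hp.n_nodes
    w = None
    for _ in range(_MAX_RESAMPLE):
        mask = rng.random((n, n)) < hp.sparsity
        values = rng.uniform(-1.0, 1.0, (n, n))
        cand = np.where(mask, values, 0.0)
        radius = float(np.max(np.abs(np.linalg.eigvals(cand))))
        if radius > 0:
            w = cand * (hp.spectral_radius / radius)
            break
    if w is None:
        raise RuntimeError(
            "sampled recurrent matrix had zero spectral radius after "
            f"{_MAX_RESAMPLE} attempts; increase sparsity or n_nodes"
        )
    w_in = rng.uniform(-hp.input_scaling, hp.input_scaling, (n, n_inputs))
    return Reservoir(w_in=w_in, w=w, hyperparameters=hp)


def run_reservoir(
    res: Reservoir, u: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Drive the reservoir with an input sequence.

    Parameters
    ----------
    res:
        Built reservoir.
    u:
        (N_in, T) input sequence; by convention row 0 is the constant bias 1.
    x0:
        Initial state (N,), entries in [-1, 1]; zeros by default.

    Returns
    -------
    (N, T) array of states x(t); every entry lies in [-1, 1].
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[0] != res.n_inputs:
        raise ValueError(
            f"input has shape {u.shape}; expected ({res.n_inputs}, T)"
        )
    n, t_len = res.n_nodes, u.shape[1]
    if x0 is None:
        x = np.zeros(n)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (n,):
            raise ValueError(f"x0 must have shape ({n},)")
    alpha = res.hyperparameters.leak_rate
    retain = (1.0 - alpha) if res.hyperparameters.leak_variant == "standard" \
        else (alpha - 1.0)
    w, w_in = res.w, res.w_in
    drive = w_in @ u  # precompute input contribution for all t
    states = np.empty((n, t_len))
    for t in range(t_len):
        x = alpha * np.tanh(drive[:, t] + w @ x) + retain * x
        states[:, t] = x
    return states


def readout(w_out: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Linear readout y(t) = W_out x(t) applied to a whole trajectory."""
    w_out = np.asarray(w_out, dtype=float)
    states = np.asarray(states, dtype=float)
    if w_out.ndim != 2 or states.ndim != 2 or w_out.shape[1] != states.shape[0]:
        raise ValueError(
            f"dimension mismatch: W_out {w_out.shape} vs states {states.shape}"
        )
    return w_out @ states


class EchoStateTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer from acceleration channels to reservoir states.

    ``fit`` learns per-channel standardization statistics and builds the
    fixed random reservoir for ``n_features + 1`` inputs (a constant bias row
    is prepended internally).  ``transform`` standardizes, adds the bias and
    returns the (T, n_nodes) state trajectory.  All reservoir construction
    parameters are ordinary estimator params, so the transformer composes
    with sklearn pipelines and grid search.

    Parameters mirror :class:`EsnHyperparameters`; ``washout`` samples are
    run but callers may discard them from downstream fits.
    """

    def __init__(
        self,
        n_nodes: int = 100,
        leak_rate: float = 0.1053,
        spectral_radius: float = 0.7471,
        sparsity: float = 0.21,
        input_scaling: float = 1.0,
        seed: int = 0,
        leak_variant: str = "standard",
        standardize: bool = True,
    ):
        self.n_nodes = n_nodes
        self.leak_rate = leak_rate
        self.spectral_radius = spectral_radius
        self.sparsity = sparsity
        self.input_scaling = input_scaling
        self.seed = seed
        self.leak_variant = leak_variant
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (T, n_channels)")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            std = X.std(axis=0)
            std[std == 0] = 1.0
            self.scale_ = std
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        hp = EsnHyperparameters(
            n_nodes=self.n_nodes,
            leak_rate=self.leak_rate,
            spectral_radius=self.spectral_radius,
            sparsity=self.sparsity,
            input_scaling=self.input_scaling,
            seed=self.seed,
            leak_variant=self.leak_variant,
        )
        self.reservoir_ = build_reservoir(hp, n_inputs=X.shape[1] + 1)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "reservoir_"):
            raise RuntimeError("EchoStateTransformer is not fitted")
        X = np.asarray(X, dtype=float)
        z = (X - self.mean_) / self.scale_
        u = np.vstack([np.ones(z.shape[0]), z.T])
        return run_reservoir(self.reservoir_, u).T
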