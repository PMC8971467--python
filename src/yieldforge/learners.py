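"""The model zoo: batch ELM, online-sequential ELM (RLS), and an RF baseline.

An extreme learning machine (ELM) is a single-hidden-layer feed-forward
network whose hidden weights and biases are drawn once at random and never
retrained; only the hidden-to-output weights rho are solved, in closed form,
as the least-squares solution rho* = H^+ T with H the hidden-layer output
matrix and H^+ its Moore-Penrose pseudoinverse.

The online-sequential variant (OSELM) absorbs data chunk-by-chunk.  The
initial chunk gives

    P_0 = (H_0^T H_0)^{-1},   rho_0 = P_0 H_0^T T_0,

and each subsequent chunk (H_c, T_c) applies the recursive-least-squares
block update

    K = P H_c^T (I + H_c P H_c^T)^{-1}
    rho <- rho + K (T_c - H_c rho)
    P   <- P - K H_c P.

In exact arithmetic the final rho equals the batch solution regardless of
how the data were chunked; that equivalence is the module's headline
correctness property and its central test oracle.

The random-forest baseline delegates to scikit-learn: it exists only for
comparison and involves no bespoke tree mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ACTIVATIONS",
    "HiddenLayer",
    "ELMModel",
    "OSELMState",
    "hidden_map",
    "fit_elm",
    "fit_oselm_init",
    "oselm_update",
    "fit_oselm",
    "predict",
    "fit_rf_baseline",
]

ACTIVATIONS = ("sig", "sin", "hardlim", "rbf", "tanh")


class LearnerError(ValueError):
    pass


@dataclass(frozen=True)
class HiddenLayer:
    """Randomly drawn, frozen hidden layer of an (OS)ELM.

    For additive neurons (sig/sin/hardlim/tanh) ``weights`` are the input
    projections a_i ~ U(-1,1) and ``biases`` b_i ~ U(-1,1).  For rbf neurons
    ``weights`` are the centres a_i ~ U(-1,1) and ``biases`` the positive
    widths b_i ~ U(0.05, 1).
    """

    weights: np.ndarray  # (n_hidden, n_inputs)
    biases: np.ndarray  # (n_hidden,)
    activation: str
    seed: int

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def create(
        cls, n_inputs: int, n_hidden: int, activation: str, seed: int
    ) -> "HiddenLayer":
        if activation not in ACTIVATIONS:
            raise LearnerError(
                f"unknown activation {activation!r}; expected one of {ACTIVATIONS}"
            )
        if n_hidden < 1:
            raise LearnerError("n_hidden must be >= 1")
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1.0, 1.0, size=(n_hidden, n_inputs))
        if activation == "rbf":
            b = rng.uniform(0.05, 1.0, size=n_hidden)
        else:
            b = rng.uniform(-1.0, 1.0, size=n_hidden)
        return cls(weights=a, biases=b, activation=activation, seed=seed)


def hidden_map(layer: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H, shape (n_samples, n_hidden).

    H[j, i] = G(a_i, b_i, x_j) with G the layer's activation: logistic,
    sine, hard limiter or tanh of a.x + b, or the Gaussian kernel
    exp(-b ||x - a||^2) for rbf neurons.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.n_inputs:
        raise LearnerError(
            f"input dimension {X.shape[1]} != layer dimension {layer.n_inputs}"
        )
    if layer.activation == "rbf":
        sq = cdist(X, layer.weights, metric="sqeuclidean")
        return np.exp(-layer.biases[None, :] * sq)
    Z = X @ layer.weights.T + layer.biases[None, :]
    if layer.activation == "sig":
        return 1.0 / (1.0 + np.exp(-Z))
    if layer.activation == "sin":
        return np.sin(Z)
    if layer.activation == "hardlim":
        return (Z >= 0).astype(float)
    if layer.activation == "tanh":
        return np.tanh(Z)
    raise LearnerError(f"unknown activation {layer.activation!r}")


@dataclass(frozen=True)
class ELMModel:
    hidden: HiddenLayer
    output_weights: np.ndarray  # rho, shape (n_hidden,)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise LearnerError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise LearnerError("non-finite values in training data")
    return X, y


def fit_elm(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    activation: str = "sig",
    seed: int = 0,
    ridge: float = 0.0,
) -> ELMModel:
    """Batch ELM fit: rho* = H^+ y via SVD pseudoinverse.

    ``ridge`` adds optional Tikhonov damping (H^T H + ridge I) for badly
    conditioned hidden maps; the default 0 is the textbook pseudoinverse
    solution.
    """
    X, y = _check_xy(X, y)
    layer = HiddenLayer.create(X.shape[1], n_hidden, activation, seed)
    H = hidden_map(layer, X)
    if ridge > 0:
        A = H.T @ H + ridge * np.eye(n_hidden)
        rho = np.linalg.solve(A, H.T @ y)
    else:
        rho = np.linalg.pinv(H) @ y
    return ELMModel(hidden=layer, output_weights=rho)


@dataclass(frozen=True)
class OSELMState:
    """Running state of an online-sequential ELM."""

    hidden: HiddenLayer
    output_weights: np.ndarray  # rho_k
    rls_matrix: np.ndarray  # P_k = (H^T H)^{-1} over all absorbed data
    n_seen: int
    block_size: int = 100


def fit_oselm_init(
    X0: np.ndarray,
    y0: np.ndarray,
    n_hidden: int,
    activation: str = "sig",
    block_size: int = 100,
    seed: int = 0,
    ridge: float = 0.0,
) -> OSELMState:
    """Initialization stage: batch-solve the first chunk.

    The chunk must contain at least ``n_hidden`` samples so H_0^T H_0 is
    invertible (the rank condition of the sequential algorithm).  A positive
    ``ridge`` seeds the recursion with P_0 = (H_0^T H_0 + ridge I)^{-1};
    because RLS accumulates Gram blocks exactly, the final weights then
    coincide with the batch ridge solution over all absorbed data — useful
    when a single lag feature makes the hidden columns nearly collinear.
    """
    X0, y0 = _check_xy(X0, y0)
    if X0.shape[0] < n_hidden:
        raise LearnerError(
            f"initial chunk of {X0.shape[0]} samples < n_hidden={n_hidden}; "
            "enlarge the initialization block"
        )
    layer = HiddenLayer.create(X0.shape[1], n_hidden, activation, seed)
    H0 = hidden_map(layer, X0)
    G = H0.T @ H0
    if ridge > 0:
        G = G + ridge * np.eye(n_hidden)
    cond = np.linalg.cond(G)
    # beyond ~1e10 the explicit inverse that seeds the RLS recursion carries
    # no significant digits, so the state is treated as rank-deficient
    if not np.isfinite(cond) or cond > 1e10:
        raise LearnerError(
            "singular (or numerically singular) H0^T H0 at initialization; "
            "try a ridge term, another seed, or fewer hidden neurons"
        )
    P0 = np.linalg.inv(G)
    rho0 = P0 @ (H0.T @ y0)
    return OSELMState(
        hidden=layer,
        output_weights=rho0,
        rls_matrix=P0,
        n_seen=X0.shape[0],
        block_size=block_size,
    )


def oselm_update(state: OSELMState, Xc: np.ndarray, yc: np.ndarray) -> OSELMState:
    """Absorb one chunk via the RLS block update; the chunk is then discarded."""
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    yc = np.asarray(yc, dtype=float).ravel()
    if Xc.size == 0 or yc.size == 0:
        return state
    if Xc.shape[1] != state.hidden.n_inputs:
        raise LearnerError(
            f"chunk dimension {Xc.shape[1]} != layer dimension {state.hidden.n_inputs}"
        )
    Hc = hidden_map(state.hidden, Xc)
    P = state.rls_matrix
    S = np.eye(Hc.shape[0]) + Hc @ P @ Hc.T
    K = P @ Hc.T @ np.linalg.inv(S)
    rho = state.output_weights + K @ (yc - Hc @ state.output_weights)
    P_new = P - K @ Hc @ P
    P_new = 0.5 * (P_new + P_new.T)  # keep symmetry against roundoff
    return replace(
        state,
        output_weights=rho,
        rls_matrix=P_new,
        n_seen=state.n_seen + Xc.shape[0],
    )


def fit_oselm(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    activation: str = "sig",
    block_size: int = 100,
    seed: int = 0,
    ridge: float = 0.0,
) -> OSELMState:
    """Convenience: initialize on the first block, then stream the rest.

    The initialization chunk is the first ``block_size`` samples, enlarged
    to ``n_hidden`` if the block is smaller than the rank condition demands.
    """
    X, y = _check_xy(X, y)
    n0 = min(max(block_size, n_hidden), X.shape[0])
    state = fit_oselm_init(
        X[:n0], y[:n0], n_hidden, activation=activation,
        block_size=block_size, seed=seed, ridge=ridge,
    )
    for start in range(n0, X.shape[0], block_size):
        stop = start + block_size
        state = oselm_update(state, X[start:stop], y[start:stop])
    return state


def predict(model: ELMModel | OSELMState, X: np.ndarray) -> np.ndarray:
    """Evaluate H(X) . rho for a fitted batch or sequential model."""
    if isinstance(model, (ELMModel, OSELMState)):
        H = hidden_map(model.hidden, X)
        return H @ model.output_weights
    # duck-type anything else (e.g. the RF baseline) through .predict
    return np.asarray(model.predict(np.atleast_2d(X)))


def fit_rf_baseline(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 10_000,
    m_try: int = 2,
    seed: int = 0,
) -> RandomForestRegressor:
    """Bagged-regression-tree baseline (delegated to scikit-learn).

    ``m_try`` is capped at the input dimension; with the study's single
    lag-1 predictor the cap makes the published m_try = 2 degrade gracefully
    to 1.
    """
    X, y = _check_xy(X, y)
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(m_try, X.shape[1]),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model
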