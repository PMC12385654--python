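"""Surrogate models mapping normalized storage factors to quality responses.

Three families approximate the storage-quality relationship on the unit
cube:

* a Gaussian radial-basis-function network whose hidden layer holds one
  center per training sample and whose linear output weights are solved
  analytically (regularized least squares), with the kernel width chosen by
  leave-one-out cross-validation;
* an Elman recurrent network — a single nonlinear hidden layer fed both by
  the input and by a context layer holding the previous hidden state —
  trained by dynamic backpropagation with a one-step context gradient;
* a full second-order (quadratic) response surface fitted by ordinary least
  squares over the ten-term basis
  ``[1, x1, x2, x3, x1^2, x2^2, x3^2, x1 x2, x1 x3, x2 x3]``.

A reference coefficient set for the wolfberry storage responses ships as a
fixture (:func:`reference_rsm`); its hardness response is on the gram scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq, solve
from scipy.spatial.distance import cdist

from .metrics import FitMetrics, fit_metrics

__all__ = [
    "TrainProtocol",
    "RBFSurrogate",
    "ElmanSurrogate",
    "QuadraticRSM",
    "QUADRATIC_TERMS",
    "gaussian_basis",
    "rbf_train",
    "rbf_predict",
    "elman_forward",
    "elman_train",
    "elman_predict",
    "quadratic_basis",
    "fit_quadratic_rsm",
    "rsm_evaluate",
    "rsm_evaluate_batch",
    "reference_rsm",
    "evaluate_model",
    "train_test_split",
]


@dataclass(frozen=True)
class TrainProtocol:
    """Training hyper-parameters shared by the surrogate families.

    The defaults mirror the study protocol: an 80/20 random split, RBF width
    chosen by cross-validation over a fixed grid (which includes the extreme
    value 100), an Elman network with 10 hidden neurons trained for at most
    1000 epochs with error tolerance 1e-5 and gradient tolerance 1e-6.
    """

    train_fraction: float = 0.8
    split_seed: int = 0
    rbf_width_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0)
    rbf_regularization: float = 1e-10
    elman_hidden: int = 10
    elman_max_epochs: int = 1000
    elman_error_tol: float = 1e-5
    elman_grad_tol: float = 1e-6
    learning_rate: float = 0.01
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie strictly between 0 and 1")
        if self.elman_hidden < 1 or self.elman_max_epochs < 1:
            raise ValueError("hidden size and epoch cap must be positive")
        if min(self.elman_error_tol, self.elman_grad_tol, self.learning_rate) <= 0:
            raise ValueError("tolerances and learning rate must be positive")


def train_test_split(
    n: int, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split into train and test index arrays."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# RBF network


def gaussian_basis(x, c, width: float) -> float:
    """Gaussian radial basis ``exp(-||x - c||^2 / (2 width^2))``."""
    if width <= 0:
        raise ValueError("width must be positive")
    diff = np.asarray(x, dtype=float) - np.asarray(c, dtype=float)
    return float(np.exp(-np.dot(diff, diff) / (2.0 * width**2)))


def _kernel_matrix(X: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    return np.exp(-cdist(X, centers, "sqeuclidean") / (2.0 * width**2))


@dataclass(frozen=True)
class RBFSurrogate:
    """Trained Gaussian RBF network (centers, shared width, linear weights)."""

    centers: np.ndarray
    width: float
    weights: np.ndarray  # h x m
    response_names: tuple[str, ...]
    cv_scores: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if np.any(~np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.centers.shape[0] != self.weights.shape[0]:
            raise ValueError("one weight row per center is required")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _kernel_matrix(X, self.centers, self.width) @ self.weights


def rbf_predict(model: RBFSurrogate, x) -> np.ndarray:
    """Predicted response vector at one normalized point."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.centers.shape[1],):
        raise ValueError(
            f"expected a {model.centers.shape[1]}-vector, got shape {x.shape}"
        )
    return model.predict(x[None, :])[0]


def _solve_weights(K: np.ndarray, Y: np.ndarray, reg: float) -> np.ndarray:
    if K.shape[0] == K.shape[1]:
        # symmetric positive-definite kernel matrix: regularized direct solve
        return solve(K + reg * np.eye(K.shape[0]), Y, assume_a="pos")
    A = K.T @ K + reg * np.eye(K.shape[1])
    return solve(A, K.T @ Y, assume_a="pos")


def rbf_train(
    X: np.ndarray,
    Y: np.ndarray,
    protocol: TrainProtocol = TrainProtocol(),
    response_names: tuple[str, ...] | None = None,
) -> RBFSurrogate:
    """Fit an RBF network with one center per training sample.

    The kernel width is chosen from ``protocol.rbf_width_grid`` by
    leave-one-out cross-validation (errors z-scored per response before
    aggregation, so no response dominates by its units).  Output weights are
    solved by regularized least squares with a small floor regularization;
    at the floor the network interpolates the training data.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must have matching row counts")
    n = X.shape[0]
    if n < 2:
        raise ValueError("RBF training needs at least two samples")
    if response_names is None:
        response_names = tuple(f"y{j + 1}" for j in range(Y.shape[1]))

    reg = protocol.rbf_regularization
    if len(np.unique(X, axis=0)) < n:
        warnings.warn(
            "duplicate training inputs produce a singular kernel; raising regularization",
            RuntimeWarning,
        )
        reg = max(reg, 1e-8)

    y_scale = np.maximum(Y.std(axis=0), 1e-12)
    cv_scores: dict[float, float] = {}
    for width in protocol.rbf_width_grid:
        sq = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            K = _kernel_matrix(X[keep], X[keep], width)
            try:
                w = _solve_weights(K, Y[keep], reg)
            except np.linalg.LinAlgError:
                sq = np.inf
                break
            pred = _kernel_matrix(X[i : i + 1], X[keep], width) @ w
            sq += float(np.sum(((pred[0] - Y[i]) / y_scale) ** 2))
        cv_scores[width] = sq / n
    best_width = min(protocol.rbf_width_grid, key=lambda w: cv_scores[w])

    K = _kernel_matrix(X, X, best_width)
    weights = _solve_weights(K, Y, reg)
    return RBFSurrogate(
        centers=X.copy(),
        width=float(best_width),
        weights=weights,
        response_names=tuple(response_names),
        cv_scores=cv_scores,
    )


# ---------------------------------------------------------------------------
# Elman recurrent network


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda x: 1.0 - x**2),  # derivative in terms of output
    "identity": (lambda a: a, lambda x: np.ones_like(x)),
}


@dataclass
class ElmanSurrogate:
    """Elman recurrent network with a context (state) layer.

    The context layer memorizes the hidden state of the previous step and
    feeds it back into the hidden layer, so the hidden recursion is
    ``x(k) = f(W_ctx x_c(k) + W_in u(k))`` with ``x_c(k) = x(k-1)``.
    ``y_offset`` / ``y_scale`` destandardize the linear outputs back to
    response units (identity for hand-constructed networks).
    """

    w_context_to_hidden: np.ndarray  # h x h
    w_input_to_hidden: np.ndarray  # h x d
    w_hidden_to_output: np.ndarray  # m x h
    context_state: np.ndarray
    hidden_activation: str = "tanh"
    output_activation: str = "identity"
    response_names: tuple[str, ...] = ()
    y_offset: np.ndarray | None = None
    y_scale: np.ndarray | None = None
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = self.w_context_to_hidden.shape[0]
        if self.w_context_to_hidden.shape != (h, h):
            raise ValueError("context-to-hidden weights must be square")
        if self.w_input_to_hidden.shape[0] != h or self.w_hidden_to_output.shape[1] != h:
            raise ValueError("inconsistent hidden-layer shapes")
        if self.context_state.shape != (h,) or np.any(~np.isfinite(self.context_state)):
            raise ValueError("context state must be a finite h-vector")


def elman_forward(model: ElmanSurrogate, input_sequence) -> list[np.ndarray]:
    """Run the Elman recursion over an input sequence.

    The context is re-initialized to zeros at the start of the sequence and,
    per the recursion, the context used at step ``k`` is the hidden state of
    step ``k - 1``; after the run the model stores the context of the final
    step (the penultimate hidden state).  Outputs are in the network's
    internal scale (no destandardization).
    """
    f, _ = _ACTIVATIONS[model.hidden_activation]
    g, _ = _ACTIVATIONS[model.output_activation]
    h = model.w_context_to_hidden.shape[0]
    xc = np.zeros(h)
    prev_hidden = None
    outputs = []
    for u in input_sequence:
        if prev_hidden is not None:
            xc = prev_hidden
        u = np.atleast_1d(np.asarray(u, dtype=float))
        hidden = f(model.w_context_to_hidden @ xc + model.w_input_to_hidden @ u)
        outputs.append(g(model.w_hidden_to_output @ hidden))
        prev_hidden = hidden
    model.context_state = xc
    return outputs


def elman_predict(model: ElmanSurrogate, X: np.ndarray) -> np.ndarray:
    """Predict responses for rows of ``X`` presented as one sequence."""
    raw = np.array(elman_forward(model, np.atleast_2d(np.asarray(X, dtype=float))))
    if model.y_scale is not None:
        raw = raw * model.y_scale + model.y_offset
    return raw


def elman_train(
    X: np.ndarray,
    Y: np.ndarray,
    protocol: TrainProtocol = TrainProtocol(),
    response_names: tuple[str, ...] | None = None,
) -> ElmanSurrogate:
    """Train an Elman network by dynamic backpropagation.

    Targets are z-scored internally (responses have disparate units); rows
    are presented as one ordered sequence per epoch with the context reset
    to zeros at each epoch start.  Weights are updated by plain stochastic
    gradient descent with a one-step context gradient (the context is
    treated as a constant input at each step).  Training stops at the epoch
    cap, when the standardized training MSE falls below the error tolerance,
    or when the epoch-mean gradient norm falls below the gradient tolerance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, d = X.shape
    m = Y.shape[1]
    if n < 2:
        raise ValueError("Elman training needs at least two samples")
    if response_names is None:
        response_names = tuple(f"y{j + 1}" for j in range(m))
    h = protocol.elman_hidden
    lr = protocol.learning_rate
    rng = np.random.default_rng(protocol.init_seed)
    W1 = rng.uniform(-0.5, 0.5, (h, h))
    W2 = rng.uniform(-0.5, 0.5, (h, d))
    W3 = rng.uniform(-0.5, 0.5, (m, h))

    y_offset = Y.mean(axis=0)
    y_scale = np.maximum(Y.std(axis=0), 1e-12)
    T = (Y - y_offset) / y_scale

    mse_history: list[float] = []
    stop_reason = "max_epochs"
    for epoch in range(protocol.elman_max_epochs):
        xc = np.zeros(h)
        prev = None
        sq = 0.0
        grad_sq = 0.0
        for u, t in zip(X, T):
            if prev is not None:
                xc = prev
            hidden = np.tanh(W1 @ xc + W2 @ u)
            err = W3 @ hidden - t
            sq += float(err @ err)
            dW3 = np.outer(err, hidden)
            dhid = (W3.T @ err) * (1.0 - hidden**2)
            dW1 = np.outer(dhid, xc)
            dW2 = np.outer(dhid, u)
            W3 -= lr * dW3
            W1 -= lr * dW1
            W2 -= lr * dW2
            grad_sq += float((dW3**2).sum() + (dW1**2).sum() + (dW2**2).sum())
            prev = hidden
        mse = sq / (n * m)
        if not np.isfinite(mse):
            raise FloatingPointError(f"Elman training diverged at epoch {epoch}")
        mse_history.append(mse)
        if mse < protocol.elman_error_tol:
            stop_reason = "error_tol"
            break
        if np.sqrt(grad_sq / n) < protocol.elman_grad_tol:
            stop_reason = "grad_tol"
            break

    return ElmanSurrogate(
        w_context_to_hidden=W1,
        w_input_to_hidden=W2,
        w_hidden_to_output=W3,
        context_state=np.zeros(h),
        response_names=tuple(response_names),
        y_offset=y_offset,
        y_scale=y_scale,
        history={
            "mse": mse_history,
            "initial_mse": mse_history[0],
            "final_mse": mse_history[-1],
            "epochs": len(mse_history),
            "stop_reason": stop_reason,
        },
    )


# ---------------------------------------------------------------------------
# quadratic response surface


QUADRATIC_TERMS = (
    "1",
    "x1",
    "x2",
    "x3",
    "x1^2",
    "x2^2",
    "x3^2",
    "x1*x2",
    "x1*x3",
    "x2*x3",
)


def quadratic_basis(X: np.ndarray) -> np.ndarray:
    """Ten-term full second-order basis over three factors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 3:
        raise ValueError("quadratic basis is defined over exactly three factors")
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    return np.column_stack(
        [np.ones_like(x1), x1, x2, x3, x1**2, x2**2, x3**2, x1 * x2, x1 * x3, x2 * x3]
    )


@dataclass(frozen=True)
class QuadraticRSM:
    """Per-response coefficient vectors over the ten-term quadratic basis."""

    coefficients: np.ndarray  # m x 10
    response_names: tuple[str, ...]
    r2: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        C = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if C.shape[1] != len(QUADRATIC_TERMS):
            raise ValueError(f"expected {len(QUADRATIC_TERMS)} coefficients per response")
        if np.any(~np.isfinite(C)):
            raise ValueError("coefficients must be finite")
        if C.shape[0] != len(self.response_names):
            raise ValueError("one coefficient row per response is required")
        object.__setattr__(self, "coefficients", C)


def fit_quadratic_rsm(
    X: np.ndarray,
    Y: np.ndarray,
    response_names: tuple[str, ...] | None = None,
) -> QuadraticRSM:
    """Ordinary least squares over the ten-term quadratic basis."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] < len(QUADRATIC_TERMS):
        raise ValueError("fitting the quadratic surface needs at least 10 points")
    B = quadratic_basis(X)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise np.linalg.LinAlgError(
            "quadratic basis is rank-deficient on these design points"
        )
    coef, _, _, _ = lstsq(B, Y)
    if response_names is None:
        response_names = tuple(f"y{j + 1}" for j in range(Y.shape[1]))
    fitted = B @ coef
    ss_res = np.sum((Y - fitted) ** 2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    r2 = tuple(float(1 - a / b) if b > 0 else float("nan") for a, b in zip(ss_res, ss_tot))
    return QuadraticRSM(coef.T, tuple(response_names), r2=r2)


def rsm_evaluate(rsm: QuadraticRSM, x) -> np.ndarray:
    """Evaluate the surface at one normalized point (warn outside [0, 1]³)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {x.shape}")
    if np.any(x < 0.0) or np.any(x > 1.0):
        warnings.warn(
            f"evaluating the response surface outside the unit cube at {x}",
            RuntimeWarning,
        )
    return rsm.coefficients @ quadratic_basis(x[None, :])[0]


def rsm_evaluate_batch(rsm: QuadraticRSM, X: np.ndarray) -> np.ndarray:
    """Vectorized surface evaluation over rows of ``X``."""
    return quadratic_basis(X) @ rsm.coefficients.T


def reference_rsm() -> QuadraticRSM:
    """Reference quadratic coefficients for the wolfberry storage responses.

    Coefficient order follows :data:`QUADRATIC_TERMS`.  The hardness response
    is on the gram scale (unlike the newton-scale 40-run table); the pure
    quadratic terms are attached to ``x1^2, x2^2, x3^2`` in that order.
    """
    coefficients = np.array(
        [
            # hardness (g)
            [2335.8, -2578.0, 816.4, -53.13, 1253.2, -864.08, 184.21, 344.77, 297.58, -533.94],
            # SSC (%)
            [11.157, 8.859, 9.233, -11.724, -5.8784, -6.5147, 12.646, 0.57922, 5.3007, -6.2718],
            # TA (%)
            [1.8548, -1.7579, 0.3851, 2.1481, 2.4077, -1.9714, -1.5817, -0.10174, -3.2872, 2.1514],
            # Vc (mg/100 g)
            [12.415, 10.573, 9.0241, -4.5248, -3.0938, 6.1445, 4.0587, -16.788, -2.3267, -3.5507],
        ]
    )
    return QuadraticRSM(coefficients, ("hardness", "ssc", "ta", "vc"))


# ---------------------------------------------------------------------------
# model evaluation


def evaluate_model(
    predict, X_test: np.ndarray, Y_test: np.ndarray, response_names: tuple[str, ...]
) -> dict[str, FitMetrics]:
    """Per-response fit metrics of a batch predictor on a held-out set."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    if X_test.shape[0] == 0:
        raise ValueError("test set is empty")
    P = np.atleast_2d(np.asarray(predict(X_test), dtype=float))
    return {
        name: fit_metrics(Y_test[:, j], P[:, j]) for j, name in enumerate(response_names)
    }
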