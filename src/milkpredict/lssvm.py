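"""Least-squares support vector machine with an RBF kernel.

The LSSVM replaces the SVM's inequality constraints with equality
constraints and a squared-error loss, so training reduces to one linear
solve. With kernel matrix ``O`` (Omega), labels ``y`` in {+1, -1} and
regularization ``C > 0``, the dual variables ``(b, alpha)`` solve the
bordered Karush-Kuhn-Tucker system::

    [ 0    1^T        ] [ b     ]   [ 0 ]
    [ 1    O + I_N/C  ] [ alpha ] = [ y ]

and the decision function is ``sgn( sum_i alpha_i K(x_i, x) + b )`` with
the radial basis kernel ``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))``.

The stationarity conditions give ``sum_i alpha_i = 0`` and
``alpha_i = C e_i`` where ``e_i`` is the residual of sample ``i``; both
are exposed as checkable invariants of a trained model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import get_lapack_funcs, lu_factor, lu_solve
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "LSSVMModel",
    "rbf_kernel",
    "kernel_matrix",
    "train_lssvm",
    "decision_value",
    "decision_values",
    "predict",
    "save_model",
    "load_model",
]

#: warn when the estimated condition number of the KKT system exceeds this
COND_WARN_THRESHOLD = 1e10

#: accept a solution only if the KKT residual inf-norm is below this times
#: the label inf-norm (which is 1 for +/-1 labels)
RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel width factor sigma (> 0)."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma!r}")


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """K(xi, xj) = exp(-||xi - xj||^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    sq = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-sq / (2.0 * sigma**2)))


def kernel_matrix(
    X: np.ndarray, sigma: float, Y: np.ndarray | None = None
) -> np.ndarray:
    """RBF Gram matrix. With ``Y`` given, the cross-kernel K(X_i, Y_j).

    The self-Gram is symmetric with unit diagonal and is positive
    semi-definite (Mercer kernel).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    other = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    sq = cdist(X, other, metric="sqeuclidean")
    K = np.exp(-sq / (2.0 * sigma**2))
    if Y is None:
        # enforce exact symmetry / unit diagonal against rounding
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return K


@dataclass
class LSSVMModel:
    """Trained LSSVM: dual coefficients plus the stored training set."""

    alphas: np.ndarray
    bias: float
    train_X: np.ndarray
    train_y: np.ndarray
    C: float
    kernel: KernelParams
    feature_names: tuple[str, ...] | None = None
    normalization_means: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.train_X = np.atleast_2d(np.asarray(self.train_X, dtype=float))
        self.train_y = np.asarray(self.train_y, dtype=float)
        n = self.train_X.shape[0]
        if not (self.alphas.shape == (n,) == self.train_y.shape):
            raise ValueError("alphas, train_X and train_y lengths disagree")
        if self.C <= 0:
            raise ValueError("C must be > 0")

    @property
    def sigma(self) -> float:
        return self.kernel.sigma

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return decision_values(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def train_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    sigma: float,
    feature_names: tuple[str, ...] | None = None,
    normalization_means: np.ndarray | None = None,
) -> LSSVMModel:
    """Fit an LSSVM by solving the bordered KKT linear system.

    Raises
    ------
    ValueError
        Fewer than two samples, one-class labels, or invalid C/sigma.
    numpy.linalg.LinAlgError
        Singular system, or the solution fails the residual check.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C!r}")
    kernel = KernelParams(sigma=sigma)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two training samples")
    if y.shape != (n,):
        raise ValueError("y length must match number of rows of X")
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be +1 or -1")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")

    K = kernel_matrix(X, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / C
    rhs = np.concatenate(([0.0], y))

    lu, piv = lu_factor(A)
    if not np.isfinite(lu).all() or np.abs(np.diag(lu)).min() == 0.0:
        raise np.linalg.LinAlgError("singular KKT system (zero pivot)")
    # reciprocal 1-norm condition estimate from the LU factors (LAPACK gecon)
    gecon = get_lapack_funcs(("gecon",), (A,))[0]
    anorm = np.abs(A).sum(axis=0).max()
    rcond, info = gecon(lu, anorm)
    cond_est = np.inf if rcond == 0 else 1.0 / rcond
    logger.debug("KKT system size %d, condition estimate %.3e", n + 1, cond_est)
    if cond_est > COND_WARN_THRESHOLD:
        warnings.warn(
            f"ill-conditioned KKT system (condition estimate {cond_est:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    sol = lu_solve((lu, piv), rhs)
    residual = np.abs(A @ sol - rhs).max()
    if not residual <= RESIDUAL_TOL * max(np.abs(y).max(), 1.0):
        raise np.linalg.LinAlgError(
            f"KKT solve failed the residual check ({residual:.2e}); "
            f"condition estimate {cond_est:.2e}"
        )
    return LSSVMModel(
        alphas=sol[1:],
        bias=float(sol[0]),
        train_X=X,
        train_y=y,
        C=float(C),
        kernel=kernel,
        feature_names=feature_names,
        normalization_means=(
            None
            if normalization_means is None
            else np.asarray(normalization_means, dtype=float)
        ),
    )


def decision_values(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Pre-sign decision sums  sum_i alpha_i K(x_i, x) + b  for rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"query dimension {X.shape[1]} != model dimension "
            f"{model.train_X.shape[1]}"
        )
    K = kernel_matrix(model.train_X, model.sigma, X)
    return model.alphas @ K + model.bias


def decision_value(model: LSSVMModel, x: np.ndarray) -> float:
    """Decision sum for a single p-vector."""
    return float(decision_values(model, np.asarray(x, dtype=float).reshape(1, -1))[0])


def predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Class labels sgn(decision); a decision value of exactly 0 maps to +1."""
    dv = decision_values(model, X)
    return np.where(dv >= 0, 1, -1).astype(int)


def save_model(model: LSSVMModel, path: str | Path) -> None:
    """Serialize a trained model (including training rows) to JSON."""
    doc = {
        "alphas": model.alphas.tolist(),
        "bias": model.bias,
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
        "C": model.C,
        "sigma": model.sigma,
        "feature_names": (
            None if model.feature_names is None else list(model.feature_names)
        ),
        "normalization_means": (
            None
            if model.normalization_means is None
            else model.normalization_means.tolist()
        ),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> LSSVMModel:
    doc = json.loads(Path(path).read_text())
    return LSSVMModel(
        alphas=np.asarray(doc["alphas"], dtype=float),
        bias=float(doc["bias"]),
        train_X=np.asarray(doc["train_X"], dtype=float),
        train_y=np.asarray(doc["train_y"], dtype=float),
        C=float(doc["C"]),
        kernel=KernelParams(sigma=float(doc["sigma"])),
        feature_names=(
            None
            if doc.get("feature_names") is None
            else tuple(doc["feature_names"])
        ),
        normalization_means=(
            None
            if doc.get("normalization_means") is None
            else np.asarray(doc["normalization_means"], dtype=float)
        ),
    )
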