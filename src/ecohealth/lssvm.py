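"""Least-squares support vector regression (LS-SVM) with an RBF kernel.

Training solves the dual KKT system

    [ 0   1^T         ] [ b     ]   [ 0 ]
    [ 1   Omega + I/g ] [ alpha ] = [ y ]

where Omega_ij = K(x_i, x_j) is the kernel Gram matrix and g (gamma) is the
regularization parameter; prediction is y(x) = sum_i alpha_i K(x, x_i) + b.
The system is solved by block elimination on the symmetric positive-definite
matrix A = Omega + I/gamma: with A nu = 1 and A eta = y,

    b = (1^T eta) / (1^T nu),    alpha = eta - b nu.

The fit stores KKT residual diagnostics; residuals and the bias constraint
sum(alpha) = 0 are checked to hold to 1e-8 relative tolerance.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

#: 2-norm condition estimate above which a conditioning warning is emitted
CONDITION_WARN = 1e12


class LSSVMValidationError(ValueError):
    """Raised for dimension mismatches or invalid hyperparameters."""


class LSSVMNumericalError(RuntimeError):
    """Raised when the KKT system cannot be solved reliably."""


@dataclass(frozen=True)
class KernelParams:
    """RBF width ``sigma`` and regularization ``gamma``; both strictly positive."""

    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("sigma", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise LSSVMValidationError(f"{name} must be positive and finite, got {v}")


def rbf_kernel(x, x2, sigma: float):
    """Gaussian kernel exp(-||x - x'||^2 / (2 sigma^2)).

    Accepts single vectors or 2-D arrays of row vectors and returns a
    scalar or the corresponding Gram matrix.  Values lie in (0, 1] and
    equal 1 exactly when the arguments coincide.
    """
    if sigma <= 0 or not np.isfinite(sigma):
        raise LSSVMValidationError(f"sigma must be positive, got {sigma}")
    a = np.atleast_2d(np.asarray(x, dtype=float))
    b = np.atleast_2d(np.asarray(x2, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise LSSVMValidationError(
            f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    sq = cdist(a, b, metric="sqeuclidean")
    K = np.exp(-sq / (2.0 * sigma**2))
    if np.ndim(x) == 1 and np.ndim(x2) == 1:
        return float(K[0, 0])
    return K


@dataclass
class LSSVMModel:
    """A fitted LS-SVM: dual coefficients, bias, stored training inputs."""

    alphas: np.ndarray
    bias: float
    train_inputs: np.ndarray
    params: KernelParams
    kkt_residual: float = 0.0
    condition_estimate: float = field(default=np.nan)

    def predict(self, inputs) -> np.ndarray:
        return predict(self, inputs)

    # plain-text round trip, for reproducibility manifests
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"sigma {float(self.params.sigma)!r}\n")
        buf.write(f"gamma {float(self.params.gamma)!r}\n")
        buf.write(f"bias {float(self.bias)!r}\n")
        buf.write("alphas " + " ".join(repr(float(a)) for a in self.alphas) + "\n")
        for row in self.train_inputs:
            buf.write("x " + " ".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LSSVMModel":
        fields: dict[str, list[str]] = {}
        xs = []
        for line in text.strip().splitlines():
            key, *vals = line.split()
            if key == "x":
                xs.append([float(v) for v in vals])
            else:
                fields[key] = vals
        return cls(
            alphas=np.array([float(v) for v in fields["alphas"]]),
            bias=float(fields["bias"][0]),
            train_inputs=np.asarray(xs, dtype=float),
            params=KernelParams(float(fields["sigma"][0]), float(fields["gamma"][0])),
        )


def _as_matrix(inputs) -> np.ndarray:
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise LSSVMValidationError("inputs must be a vector list or 2-D array")
    if not np.all(np.isfinite(X)):
        raise LSSVMValidationError("inputs must be finite")
    return X


def fit(inputs, targets, params: KernelParams) -> LSSVMModel:
    """Fit the LS-SVM dual system for the given hyperparameters.

    Raises :class:`LSSVMNumericalError` when the regularized Gram matrix is
    numerically singular; emits a warning when its condition estimate
    exceeds ``CONDITION_WARN``.
    """
    X = _as_matrix(inputs)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise LSSVMValidationError(f"targets must have shape ({n},), got {y.shape}")
    if n < 2:
        raise LSSVMValidationError("at least 2 training samples are required")
    if not np.all(np.isfinite(y)):
        raise LSSVMValidationError("targets must be finite")

    K = rbf_kernel(X, X, params.sigma)
    A = K + np.eye(n) / params.gamma
    try:
        factor = cho_factor(A, lower=True)
        sols = cho_solve(factor, np.column_stack([np.ones(n), y]))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological inputs
        raise LSSVMNumericalError(f"KKT system is numerically singular: {exc}") from exc
    nu, eta = sols[:, 0], sols[:, 1]
    denom = float(np.sum(nu))
    if abs(denom) < 1e-300:
        raise LSSVMNumericalError("bias equation degenerate: 1^T A^-1 1 ~ 0")
    b = float(np.sum(eta) / denom)
    alpha = eta - b * nu

    # KKT residual of the full bordered system, relative to the target scale
    res_top = abs(np.sum(alpha))
    res_main = np.linalg.norm(b + A @ alpha - y)
    scale = max(1.0, float(np.linalg.norm(y)))
    kkt_residual = float(max(res_top, res_main) / scale)

    cond = float(np.linalg.cond(A))
    if cond > CONDITION_WARN:
        warnings.warn(
            f"LS-SVM KKT matrix is ill-conditioned (cond~{cond:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return LSSVMModel(
        alphas=alpha,
        bias=b,
        train_inputs=X,
        params=params,
        kkt_residual=kkt_residual,
        condition_estimate=cond,
    )


def loo_residuals(inputs, targets, params: KernelParams) -> np.ndarray:
    """Exact leave-one-out residuals y_i - yhat_i^(-i) in closed form.

    For the LS-SVM bordered KKT matrix M, the leave-one-out residual of
    sample i equals alpha_i / (M^{-1})_{ii} (Cawley & Talbot), so a single
    factorization replaces n refits.  The explicit refit path exists in the
    test suite as the independent oracle for this shortcut.
    """
    X = _as_matrix(inputs)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise LSSVMValidationError("leave-one-out needs at least 3 samples")
    K = rbf_kernel(X, X, params.sigma)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / params.gamma
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise LSSVMNumericalError(f"KKT system is numerically singular: {exc}") from exc
    alpha = Minv[1:] @ np.concatenate(([0.0], y))
    return alpha / np.diag(Minv)[1:]


def predict(model: LSSVMModel, inputs) -> np.ndarray:
    """Evaluate y(x) = sum_i alpha_i K(x, x_i) + b at each input row."""
    X = _as_matrix(inputs)
    if X.shape[1] != model.train_inputs.shape[1]:
        raise LSSVMValidationError(
            f"input dimension {X.shape[1]} does not match "
            f"training dimension {model.train_inputs.shape[1]}"
        )
    K = rbf_kernel(X, model.train_inputs, model.params.sigma)
    return K @ model.alphas + model.bias
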