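"""Least-squares support vector machine with an RBF kernel.

The classifier minimises the regularised squared training error

    R = gamma * sum_i eps_i^2 + (1/2) ||w||^2,    eps_i = y_i - f(x_i),

over f(x) = w . phi(x) + b, with phi induced by the Gaussian kernel
K(x, y) = exp(-||x - y||^2 / (2 sigma^2)). Setting the Lagrangian's
derivatives to zero reduces training to one symmetric linear system in the
dual coefficients a and the bias b:

    [ 0   1^T            ] [ b ]   [ 0 ]
    [ 1   K + I/(2 gamma)] [ a ] = [ y ],

after which the decision score is f(x) = sum_j a_j K(x_j, x) + b. The
stationarity conditions sum_i a_i = 0 and a_i = 2 gamma eps_i are exposed
as fit diagnostics and enforced to a relative residual of 1e-8.

Labels are coded {+1, -1}; the score is a margin-style quantity, not a
calibrated probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist

__all__ = ["rbf_kernel", "rbf_kernel_matrix", "median_heuristic_sigma",
           "LSSVM", "LSSVMResults", "fit"]

#: Relative residual above which a solve is rejected as numerically singular.
KKT_TOL = 1e-8


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x - y||^2 / (2 sigma^2)) of two vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    sq = float(np.dot(x - y, x - y))
    return float(np.exp(-sq / (2.0 * sigma * sigma)))


def rbf_kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel matrix K[i, j] = exp(-||X_i - Y_j||^2 / (2 sigma^2))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    sq = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma * sigma))


def median_heuristic_sigma(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the training points.

    Falls back to the mean positive distance when the median is zero
    (more than half the points coincide) and to 1.0 when all points
    coincide.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    med = float(np.median(d))
    if med > 0:
        return med
    pos = d[d > 0]
    return float(pos.mean()) if pos.size else 1.0


class LSSVM:
    """Least-squares SVM binary classifier (RBF kernel).

    Parameters
    ----------
    X : (n, p) array
        Training feature vectors (rows).
    y : (n,) array
        Labels in {+1, -1}; both classes must be present and n >= 2.
    gamma : float
        Regularization weight on the squared empirical risk. Larger gamma
        fits the training labels more tightly (gamma -> inf interpolates).
    sigma : float, optional
        RBF kernel width. Default: median pairwise distance of X.
    """

    def __init__(self, X, y, gamma: float = 1.0, sigma: float | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise ValueError("labels must be coded +1 / -1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in y")
        if not gamma > 0:
            raise ValueError("gamma must be positive")
        if sigma is None:
            sigma = median_heuristic_sigma(X)
        if not sigma > 0:
            raise ValueError("sigma must be positive")
        self.X = X
        self.y = y
        self.gamma = float(gamma)
        self.sigma = float(sigma)
        self.n, self.p = X.shape

    def fit(self, gene_ids=None, dimensions=None) -> "LSSVMResults":
        """Solve the KKT system for (a, b).

        ``gene_ids`` / ``dimensions`` optionally attach the training gene
        identifiers and feature-column names so the fitted model can be
        serialised and applied by id.
        """
        n = self.n
        K = rbf_kernel_matrix(self.X, self.X, self.sigma)
        A = K + np.eye(n) / (2.0 * self.gamma)
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = A
        rhs = np.concatenate(([0.0], self.y))
        import warnings
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                lu, piv = scipy.linalg.lu_factor(M)
                sol = scipy.linalg.lu_solve((lu, piv), rhs)
                if np.isfinite(sol).all():
                    # one step of iterative refinement tightens the residual
                    sol += scipy.linalg.lu_solve((lu, piv), rhs - M @ sol)
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise np.linalg.LinAlgError(
                "KKT system is singular; increase the 1/(2*gamma) diagonal "
                "by choosing a smaller gamma, or perturb duplicate points"
            ) from exc
        residual = float(np.max(np.abs(M @ sol - rhs)))
        scale = float(np.max(np.abs(rhs)))
        if not np.isfinite(residual) or residual > KKT_TOL * max(scale, 1.0):
            raise np.linalg.LinAlgError(
                f"KKT solve failed: relative residual {residual / max(scale, 1.0):.3g} "
                "exceeds 1e-8; the system is numerically singular — a smaller "
                "gamma enlarges the 1/(2*gamma) diagonal and stabilises it"
            )
        b = float(sol[0])
        a = sol[1:]
        return LSSVMResults(
            model=self,
            a=a,
            b=b,
            kkt_residual=residual / max(scale, 1.0),
            sum_a=float(a.sum()),
            gene_ids=list(gene_ids) if gene_ids is not None else None,
            dimensions=list(dimensions) if dimensions is not None else None,
        )


@dataclass
class LSSVMResults:
    """Fitted LS-SVM: dual coefficients, bias and KKT diagnostics."""

    model: LSSVM
    a: np.ndarray
    b: float
    kkt_residual: float
    sum_a: float
    gene_ids: list[str] | None = None
    dimensions: list[str] | None = None
    _K_train: np.ndarray | None = field(default=None, repr=False)

    @property
    def gamma(self) -> float:
        return self.model.gamma

    @property
    def sigma(self) -> float:
        return self.model.sigma

    def decision(self, X) -> np.ndarray | float:
        """Decision score f(x) = sum_j a_j K(x_j, x) + b.

        Accepts a single vector (returns a float) or a matrix of rows
        (returns a vector). Larger scores mean more likely positive class.
        """
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.model.p:
            raise ValueError(
                f"feature dimension {X2.shape[1]} does not match the "
                f"training dimension {self.model.p}"
            )
        K = rbf_kernel_matrix(X2, self.model.X, self.sigma)
        f = K @ self.a + self.b
        return float(f[0]) if single else f

    def predict(self, X, threshold: float = 0.0) -> np.ndarray | int:
        """Class labels sign(f(x) - threshold); scores equal to the
        threshold go to +1."""
        f = self.decision(X)
        if np.isscalar(f):
            return 1 if f >= threshold else -1
        return np.where(np.asarray(f) >= threshold, 1, -1)

    def fitted_values(self) -> np.ndarray:
        """Decision scores at the training points."""
        return self.decision(self.model.X)

    def residuals(self) -> np.ndarray:
        """Training errors eps_i = y_i - f(x_i); equal to a_i / (2 gamma)."""
        return self.model.y - self.fitted_values()

    def summary(self) -> str:
        m = self.model
        train_acc = float(np.mean(self.predict(m.X) == m.y))
        lines = [
            "LS-SVM (RBF kernel) fit",
            "=" * 38,
            f"{'n training points':<24}{m.n:>14d}",
            f"{'feature dimension':<24}{m.p:>14d}",
            f"{'positives / negatives':<24}"
            f"{int((m.y > 0).sum()):>7d}{int((m.y < 0).sum()):>7d}",
            f"{'kernel width sigma':<24}{m.sigma:>14.6g}",
            f"{'regularization gamma':<24}{m.gamma:>14.6g}",
            f"{'bias b':<24}{self.b:>14.6g}",
            f"{'sum of coefficients':<24}{self.sum_a:>14.3e}",
            f"{'KKT rel. residual':<24}{self.kkt_residual:>14.3e}",
            f"{'training accuracy':<24}{train_acc:>14.4f}",
        ]
        return "\n".join(lines)


def fit(X, y, gamma: float = 1.0, sigma: float | None = None, **kwargs) -> LSSVMResults:
    """Convenience wrapper: ``LSSVM(X, y, gamma, sigma).fit()``."""
    return LSSVM(X, y, gamma=gamma, sigma=sigma).fit(**kwargs)
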