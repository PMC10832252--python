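"""The general latent-variable projection algorithm and its criteria.

Every model in this package is built from one four-step primitive applied to
a column-centered matrix X_a:

1. choose a unit-length weight vector w_a;
2. score   t_a = X_a w_a;
3. loading p_a = X_a^T t_a / (t_a^T t_a);
4. deflate X_{a+1} = X_a - t_a p_a^T.

The criterion that picks w_a defines the method:

* PCA   — iterate w <- p/||p|| to convergence (power iteration on X^T X);
* PLS1  — w_a = X_a^T y / ||X_a^T y|| (normalized covariances with the
          outcome; y itself is never deflated);
* TP    — a single pass with w_TP = b/||b||, the normalized PLS regression
          vector, collecting all predictive variance in one component;
* CP    — a single pass with an indicator weight on one column of an
          augmented matrix [y Z X], residualizing every column on that
          covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "LatentModel",
    "PLSModel",
    "TPModel",
    "project_component",
    "pca",
    "pls1",
    "target_projection",
    "covariate_project_matrix",
    "DegenerateComponentError",
]


class DegenerateComponentError(ValueError):
    """The requested weight produces a numerically zero score vector."""


@dataclass
class LatentModel:
    """Ordered component set (weights, scores, loadings) plus provenance.

    ``weights``, ``scores`` and ``loadings`` hold one column per component.
    ``explained_ss`` is the sum of squares removed from X by each deflation
    step.  ``degenerate_subspace`` flags PCA components whose explained SS
    ties the next component's (eigenvalue multiplicity), where the
    individual directions are arbitrary within their span.
    """

    weights: np.ndarray  # V x A
    scores: np.ndarray  # N x A
    loadings: np.ndarray  # V x A
    criterion: str
    explained_ss: np.ndarray = field(default_factory=lambda: np.zeros(0))
    degenerate_subspace: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "weights": self.weights.tolist(),
            "scores": self.scores.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_ss": np.asarray(self.explained_ss).tolist(),
        }


@dataclass
class PLSModel:
    """PLS1 model: a LatentModel plus inner coefficients and b.

    ``inner_coefficients`` (q) are the per-component regressions of the
    outcome on each score; ``b`` is the length-V regression vector mapping
    centered predictors to fitted outcome values, X b = T q.
    """

    latent: LatentModel
    inner_coefficients: np.ndarray  # length A
    b: np.ndarray  # length V
    y_total_ss: float

    @property
    def n_components(self) -> int:
        return self.latent.n_components

    def fitted(self, X: np.ndarray | None = None) -> np.ndarray:
        if X is None:
            return self.latent.scores @ self.inner_coefficients
        return np.asarray(X) @ self.b

    @property
    def explained_y_fraction(self) -> float:
        """Fraction of the outcome's (centered) SS captured by the fit."""
        yhat = self.fitted()
        return float(yhat @ yhat / self.y_total_ss)

    def to_dict(self) -> dict:
        d = self.latent.to_dict()
        d.update(
            inner_coefficients=self.inner_coefficients.tolist(),
            b=self.b.tolist(),
            y_total_ss=self.y_total_ss,
        )
        return d


@dataclass
class TPModel:
    """Single predictive component along the normalized regression vector."""

    weight: np.ndarray  # w_TP, unit length V
    score: np.ndarray  # t_TP, length N
    loading: np.ndarray  # p_TP, length V
    q: float  # inner coefficient of y on t_TP
    explained_y_fraction: float
    explained_X_fraction: float

    def fitted_y(self) -> np.ndarray:
        return self.score * self.q

    def explained_X_per_variable(self) -> np.ndarray:
        """SS captured by the target component in each x-variable."""
        return float(self.score @ self.score) * self.loading**2

    def to_dict(self) -> dict:
        return {
            "criterion": "tp",
            "weight": self.weight.tolist(),
            "score": self.score.tolist(),
            "loading": self.loading.tolist(),
            "q": self.q,
            "explained_y_fraction": self.explained_y_fraction,
            "explained_X_fraction": self.explained_X_fraction,
        }


def project_component(
    X_a: np.ndarray, w: np.ndarray, rel_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One pass of steps 2-4: score, loading, deflated matrix.

    Raises DegenerateComponentError when the score is numerically zero,
    i.e. the weight is orthogonal to the column space of X_a.
    """
    X_a = np.asarray(X_a, dtype=float)
    w = np.asarray(w, dtype=float)
    t = X_a @ w
    tt = float(t @ t)
    scale = float(np.sum(X_a**2))
    if tt <= rel_tol * max(scale, np.finfo(float).tiny):
        raise DegenerateComponentError(
            "weight vector is orthogonal to the column space (zero score)"
        )
    p = X_a.T @ t / tt
    X_next = X_a - np.outer(t, p)
    return t, p, X_next


def _pca_start(X: np.ndarray) -> np.ndarray:
    """Deterministic start: unit vector along the column with largest SS."""
    ss = np.sum(X**2, axis=0)
    w = np.zeros(X.shape[1])
    w[int(np.argmax(ss))] = 1.0
    return w


def pca(
    X: np.ndarray,
    A: int,
    tol: float = 1e-13,
    max_iter: int = 20000,
) -> LatentModel:
    """Principal components by the projection algorithm (power iteration).

    For each component, steps 2-3 are iterated with w <- p/||p|| until the
    normalized loading reproduces the weight (change < ``tol``), then the
    component is deflated.  One w-update is a multiplication by the Gram
    matrix X_a^T X_a, which is precomputed per component so the (possibly
    many, for nearly tied singular values) iterations stay cheap.
    Components match the truncated SVD up to sign; the sign convention
    makes the largest-magnitude loading entry positive.
    """
    X = np.asarray(X, dtype=float)
    n, v = X.shape
    if A > min(n - 1, v):
        raise ValueError(f"A={A} exceeds min(N-1, V)={min(n - 1, v)}")
    W = np.zeros((v, A))
    T = np.zeros((n, A))
    P = np.zeros((v, A))
    ss = np.zeros(A)
    X_a = X.copy()
    for a in range(A):
        w = _pca_start(X_a)
        C = X_a.T @ X_a  # steps 2-3 combined: p propto C w
        converged = False
        for _ in range(max_iter):
            p = C @ w
            norm_p = np.linalg.norm(p)
            if norm_p == 0.0:
                raise DegenerateComponentError(
                    f"component {a + 1}: zero score during power iteration"
                )
            w_new = p / norm_p
            # convergence is up to sign
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < tol:
                w = w_new
                converged = True
                break
            w = w_new
        if not converged:
            raise RuntimeError(
                f"PCA power iteration did not converge for component {a + 1} "
                f"within {max_iter} iterations"
            )
        t, p, X_a = project_component(X_a, w)
        # orient: largest-|loading| entry positive
        flip = np.sign(p[int(np.argmax(np.abs(p)))]) or 1.0
        W[:, a], T[:, a], P[:, a] = flip * w, flip * t, flip * p
        ss[a] = float(T[:, a] @ T[:, a])
    degen = np.zeros(A, dtype=bool)
    for a in range(A - 1):
        if ss[a] > 0 and abs(ss[a] - ss[a + 1]) < 1e-6 * ss[a]:
            degen[a] = degen[a + 1] = True
    return LatentModel(
        weights=W,
        scores=T,
        loadings=P,
        criterion="pca",
        explained_ss=ss,
        degenerate_subspace=degen,
    )


def pls1(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    rel_tol: float = 1e-12,
) -> PLSModel:
    """PLS1 regression by the projection algorithm; y is never deflated.

    Component weights are the normalized covariances of the deflated
    predictors with the outcome.  Extraction stops early, with a warning,
    when X_a^T y vanishes (relative to its initial norm): the remaining
    components carry no predictive covariance.  The regression vector is
    recovered as b = W (P^T W)^{-1} q, where P^T W is unit upper triangular
    in this deflation scheme.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A < 1:
        raise ValueError("A must be >= 1")
    n, v = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    cov0 = np.linalg.norm(X.T @ y)
    if cov0 == 0.0:
        raise ValueError("X^T y is identically zero; no PLS direction exists")
    W, T, P, q, ss = [], [], [], [], []
    X_a = X.copy()
    for a in range(A):
        c = X_a.T @ y
        norm_c = np.linalg.norm(c)
        if norm_c <= rel_tol * cov0:
            warnings.warn(
                f"predictive covariance exhausted after {a} of {A} components",
                stacklevel=2,
            )
            break
        w = c / norm_c
        t, p, X_a = project_component(X_a, w)
        W.append(w)
        T.append(t)
        P.append(p)
        q.append(float(y @ t / (t @ t)))
        ss.append(float(t @ t) * float(p @ p))
    W = np.column_stack(W)
    T = np.column_stack(T)
    P = np.column_stack(P)
    q = np.asarray(q)
    # P^T W is unit upper triangular for PLS1 with X-only deflation
    PtW = P.T @ W
    b = W @ solve_triangular(PtW, q, lower=False)
    latent = LatentModel(
        weights=W,
        scores=T,
        loadings=P,
        criterion="pls",
        explained_ss=np.asarray(ss),
    )
    return PLSModel(
        latent=latent,
        inner_coefficients=q,
        b=b,
        y_total_ss=float(y @ y),
    )


def target_projection(model: PLSModel, X: np.ndarray) -> TPModel:
    """Collapse a PLS model into one component along w_TP = b/||b||.

    The target score is X b/||b||, proportional to the PLS fitted values,
    so the single component preserves the model's explained y-variance
    exactly.  The score is oriented so that it correlates positively with
    the fitted outcome, making downstream selectivity signs stable.
    """
    X = np.asarray(X, dtype=float)
    b_norm = np.linalg.norm(model.b)
    if b_norm == 0.0:
        raise ValueError("PLS regression vector is zero; no target direction")
    w_tp = model.b / b_norm
    t_tp, p_tp, _ = project_component(X, w_tp)
    yhat = X @ model.b
    if float(t_tp @ yhat) < 0:  # defensive; t_tp = yhat/||b|| in exact arithmetic
        t_tp, p_tp, w_tp = -t_tp, -p_tp, -w_tp
    tt = float(t_tp @ t_tp)
    # inner coefficient of y on t_tp: y^T t_tp = yhat^T t_tp because yhat is
    # the orthogonal projection of y onto span(T) which contains t_tp
    q_tp = float(yhat @ t_tp) / tt
    yhat_tp = t_tp * q_tp
    explained_y = float(yhat_tp @ yhat_tp) / model.y_total_ss
    explained_X = tt * float(p_tp @ p_tp) / float(np.sum(X**2))
    return TPModel(
        weight=w_tp,
        score=t_tp,
        loading=p_tp,
        q=q_tp,
        explained_y_fraction=explained_y,
        explained_X_fraction=explained_X,
    )


def covariate_project_matrix(
    M: np.ndarray, col: int, rel_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One covariate projection on column ``col`` of an augmented matrix.

    Equivalent to one projection pass with an indicator weight: every
    column c becomes c - z (z^T c)/(z^T z), and the covariate's own
    residual column is set exactly to zero.  Returns (score z, loading,
    residual matrix).
    """
    M = np.asarray(M, dtype=float)
    z = M[:, col]
    zz = float(z @ z)
    col_scale = float(np.mean(np.sum(M**2, axis=0)))
    if zz <= rel_tol * max(col_scale, np.finfo(float).tiny):
        raise DegenerateComponentError(
            f"covariate column {col} has (numerically) zero variance"
        )
    w = np.zeros(M.shape[1])
    w[col] = 1.0
    t, p, M_next = project_component(M, w)
    M_next[:, col] = 0.0  # exact zero for the projected covariate itself
    return t, p, M_next
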