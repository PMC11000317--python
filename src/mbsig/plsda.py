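"""Single-block models: PCA and NIPALS PLS-DA with Q2 validity gating.

PLS-DA regresses a centered two-column class-indicator matrix Y on the
(scaled) feature matrix X by NIPALS: each latent component maximizes the
covariance of a unit-norm X-weight direction with the Y scores, X is deflated
by regression on the component scores, and Y is left intact. Predictive
ability is measured by Q2 from stratified k-fold cross-validation using the
cumulative formulation

    Q2cum(h) = 1 - prod_{a<=h} PRESS(a) / SS(a-1)

where PRESS(a) pools squared held-out Y residuals after a components and
SS(a-1) is the in-sample residual sum of squares of Y after a-1 components
(SS(0) is the total centered SS). A model is declared valid only when its
best cumulative Q2 exceeds the 0.4 gate — on this study's single blocks the
gate is expected to fail, which is the negative result the pipeline encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .data import DataError

logger = logging.getLogger("mbsig")

__all__ = [
    "fit_pca",
    "PLSDA",
    "PLSDAResults",
    "fit_plsda",
    "cross_validate_q2",
    "Q2Result",
    "q2_valid",
    "stratified_folds",
]


# ---------------------------------------------------------------------------
# PCA


def fit_pca(matrix: np.ndarray, n_components: int):
    """PCA by SVD of the column-centered matrix.

    Returns ``(scores, loadings, explained_fraction)`` with components
    ordered by variance and orthonormal loadings (columns).
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise DataError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    return scores, loadings, frac[:n_components]


# ---------------------------------------------------------------------------
# helpers shared with the multiblock model


def indicator_matrix(y: np.ndarray) -> np.ndarray:
    """Centered two-column class-indicator matrix (column k = class k)."""
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError(f"need exactly two classes, found {classes.size}")
    Y = np.zeros((y.size, 2))
    for k, cls in enumerate(classes):
        Y[y == cls, k] = 1.0
    return Y - Y.mean(axis=0)


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified fold assignment; every training split keeps both
    classes provided ``n_folds`` <= smallest class size."""
    y = np.asarray(y)
    smallest = min(np.sum(y == c) for c in np.unique(y))
    if n_folds > smallest:
        raise DataError(
            f"{n_folds}-fold stratified CV infeasible: smallest class has "
            f"{smallest} samples"
        )
    # one global permutation, dealt round-robin within each class: the fold
    # assignment is then invariant to relabeling the two classes
    order = rng.permutation(y.size)
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = order[y[order] == cls]
        assignment[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(assignment == f) for f in range(n_folds)]


# ---------------------------------------------------------------------------
# NIPALS PLS-DA


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: per-component weights/loadings/scores and fit metrics.

    ``q2`` and ``valid`` are populated by :func:`cross_validate_q2`.
    """

    n_components: int
    x_weights: np.ndarray  # (p, H), unit columns
    x_loadings: np.ndarray  # (p, H)
    y_loadings: np.ndarray  # (2, H)
    scores: np.ndarray  # (n, H)
    r2y: np.ndarray  # cumulative explained Y variance per component
    x_mean: np.ndarray
    classes: np.ndarray
    class_sizes: np.ndarray
    q2: np.ndarray | None = None
    valid: bool | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B with Y_hat = (X - x_mean) B + y_mean."""
        W, P, C = self.x_weights, self.x_loadings, self.y_loadings
        R = W @ np.linalg.inv(P.T @ W)
        return R @ C.T

    def predict_indicator(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels; ties break toward the larger training
        class."""
        Yh = self.predict_indicator(X)
        larger = int(np.argmax(self.class_sizes))
        pick = np.where(Yh[:, 0] == Yh[:, 1], larger, np.argmax(Yh, axis=1))
        return self.classes[pick]

    def summary(self) -> str:
        lines = ["PLS-DA (NIPALS)", f"components: {self.n_components}"]
        for h in range(self.n_components):
            q = "" if self.q2 is None else f"  Q2cum={self.q2[h]: .3f}"
            lines.append(f"  comp {h + 1}: R2Ycum={self.r2y[h]: .3f}{q}")
        if self.valid is not None:
            lines.append(f"valid (Q2 > 0.4): {self.valid}")
        return "\n".join(lines)


class PLSDA:
    """Two-class PLS-DA model on a scaled feature matrix.

    Parameters
    ----------
    y : class labels (any two-level coding).
    X : (n, p) scaled feature matrix.
    n_components : number of latent components to extract.
    """

    def __init__(self, y, X, n_components: int = 1):
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes = np.unique(y)
        if self.classes.size != 2:
            raise DataError("PLS-DA requires exactly two classes")
        for cls in self.classes:
            if np.sum(y == cls) < 2:
                raise DataError(f"class {cls!r} has fewer than 2 samples")
        self.y = y
        if n_components > self.X.shape[0] - 1:
            raise DataError("n_components must be <= n - 1")
        self.n_components = n_components

    def fit(self, tol: float = 1e-10, max_iter: int = 500) -> PLSDAResults:
        X = self.X.copy()
        x_mean = X.mean(axis=0)
        X -= x_mean
        Y = indicator_matrix(np.searchsorted(self.classes, self.y))
        n, p = X.shape
        H = self.n_components
        W = np.zeros((p, H))
        P = np.zeros((p, H))
        C = np.zeros((2, H))
        T = np.zeros((n, H))
        ssy_total = float(np.sum(Y**2))
        r2y = np.zeros(H)
        Yhat = np.zeros_like(Y)
        for h in range(H):
            u = Y[:, 0].copy()
            for _ in range(max_iter):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise DataError("degenerate (all-zero) deflated matrix")
                w /= nw
                t = X @ w
                c = Y.T @ t / (t @ t)
                u_new = Y @ c / (c @ c)
                if np.max(np.abs(u_new - u)) < tol:
                    u = u_new
                    break
                u = u_new
            p_h = X.T @ t / (t @ t)
            X -= np.outer(t, p_h)
            W[:, h], P[:, h], C[:, h], T[:, h] = w, p_h, c, t
            Yhat += np.outer(t, c)
            r2y[h] = 1.0 - np.sum((Y - Yhat) ** 2) / ssy_total
        sizes = np.array([np.sum(self.y == cls) for cls in self.classes])
        return PLSDAResults(
            n_components=H,
            x_weights=W,
            x_loadings=P,
            y_loadings=C,
            scores=T,
            r2y=r2y,
            x_mean=x_mean,
            classes=self.classes,
            class_sizes=sizes,
        )


def fit_plsda(matrix, groups, n_components: int = 1) -> PLSDAResults:
    """Functional wrapper over :class:`PLSDA`."""
    return PLSDA(groups, matrix, n_components).fit()


# ---------------------------------------------------------------------------
# Q2 cross-validation


def q2_valid(q2_max: float, threshold: float = 0.4) -> bool:
    """The validity gate: strictly greater than the threshold."""
    return q2_max > threshold


@dataclass
class Q2Result:
    q2_cumulative: np.ndarray  # per component count
    q2_individual: np.ndarray
    press: np.ndarray
    ss_prev: np.ndarray
    n_components: int  # argmax of cumulative Q2 (1-based)
    valid: bool
    threshold: float = 0.4


def cross_validate_q2(
    matrix,
    groups,
    max_components: int = 5,
    folds: int = 7,
    seed: int = 0,
    threshold: float = 0.4,
) -> Q2Result:
    """Cumulative Q2 by stratified k-fold CV, and the model validity verdict.

    Per fold, a PLS-DA is trained on the remaining samples (centered on the
    training rows only) and the held-out indicator residuals after each
    component count are pooled into PRESS.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(groups)
    classes = np.unique(y)
    yi = np.searchsorted(classes, y)
    n, p = X.shape
    H = int(min(max_components, p))
    rng = substream(seed, "plsda-cv")
    fold_idx = stratified_folds(yi, folds, rng)
    H = min(H, min(n - len(f) for f in fold_idx) - 1)
    if H < 1:
        raise DataError("no components fit within the fold sizes")

    Yfull = indicator_matrix(yi)
    press = np.zeros(H)
    for heldout in fold_idx:
        train = np.setdiff1d(np.arange(n), heldout)
        res = PLSDA(yi[train], X[train], H).fit()
        # held-out Y relative to the training class means
        Ytr_raw = np.zeros((train.size, 2))
        Ytr_raw[np.arange(train.size), yi[train]] = 1.0
        y_mean = Ytr_raw.mean(axis=0)
        Yho = np.zeros((heldout.size, 2))
        Yho[np.arange(heldout.size), yi[heldout]] = 1.0
        Yho -= y_mean
        Xho = X[heldout] - res.x_mean
        W, P, C = res.x_weights, res.x_loadings, res.y_loadings
        R = W @ np.linalg.inv(P.T @ W)
        Tho = Xho @ R
        Yhat = np.zeros_like(Yho)
        for h in range(H):
            Yhat += np.outer(Tho[:, h], C[:, h])
            press[h] += np.sum((Yho - Yhat) ** 2)

    # in-sample residual SS after h-1 components, from the full-data fit
    full = PLSDA(yi, X, H).fit()
    ss_prev = np.zeros(H)
    ss_prev[0] = np.sum(Yfull**2)
    Yhat = np.zeros_like(Yfull)
    for h in range(H - 1):
        Yhat += np.outer(full.scores[:, h], full.y_loadings[:, h])
        ss_prev[h + 1] = np.sum((Yfull - Yhat) ** 2)

    ratio = press / ss_prev
    q2_ind = 1.0 - ratio
    q2_cum = 1.0 - np.cumprod(ratio)
    best = int(np.argmax(q2_cum))
    valid = q2_valid(float(q2_cum[best]), threshold)
    logger.info(
        "Q2 CV: best ncomp=%d, Q2cum=%.3f, valid=%s", best + 1, q2_cum[best], valid
    )
    return Q2Result(
        q2_cumulative=q2_cum,
        q2_individual=q2_ind,
        press=press,
        ss_prev=ss_prev,
        n_components=best + 1,
        valid=valid,
        threshold=threshold,
    )
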