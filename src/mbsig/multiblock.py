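"""Multiblock sparse PLS-DA: design-weighted covariance maximization with
per-block cardinality-constrained (soft-thresholded) loadings.

The model finds, per latent component, one unit-norm sparse weight vector per
block so that the block scores t_b = X_b a_b covary with each other and with
the outcome scores t_Y = Y c, with the rewarded covariances set by a design
matrix over blocks plus the outcome. Exactly ``keepX`` features per block
carry nonzero weight; soft thresholding at the (keepX+1)-th largest absolute
entry enforces the cardinality. After convergence each block matrix is
deflated by regression on its own scores; the outcome indicator is reused for
every component (Y is not deflated). Class prediction is by nearest training
centroid in each block's score space, aggregated over blocks by a vote
weighted by how well each block's scores track the outcome scores.

Performance is summarized by the balanced error rate (BER), the mean of the
two per-class misclassification rates, which is insensitive to the 12:8
class imbalance of the study design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import DataError, MultiBlockDataset
from .plsda import indicator_matrix
from .preprocess import pareto_scale

logger = logging.getLogger("mbsig")

__all__ = [
    "soft_threshold_keep",
    "make_design",
    "MultiblockSPLSDA",
    "MultiblockSPLSDAResults",
    "fit_block_splsda",
    "predict_block_splsda",
    "ConfusionCounts",
    "balanced_error_rate",
]


def _unit(v: np.ndarray) -> np.ndarray:
    """L2-normalize, rescaling by the max magnitude first so subnormal
    entries cannot underflow the squared norm to zero."""
    m = np.max(np.abs(v))
    v = v / m
    return v / np.sqrt(v @ v)


def soft_threshold_keep(weights: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold a weight vector to exactly ``keep`` nonzeros, then
    L2-normalize.

    The threshold is the (keep+1)-th largest absolute value (0 when
    ``keep == len``). Ties at the threshold are resolved deterministically in
    favor of the lowest feature index; the promoted entries receive half the
    smallest surviving magnitude (unit magnitude if none survive) so the
    cardinality contract holds exactly whenever the input has at least
    ``keep`` nonzero entries (zero weights never enter the support).
    """
    w = np.asarray(weights, dtype=float)
    if keep < 1:
        raise DataError("keep must be >= 1")
    if keep > w.size:
        raise DataError(f"keep={keep} exceeds vector length {w.size}")
    aw = np.abs(w)
    if keep < w.size:
        # fast path: partition instead of a full sort; fall back to the
        # stable sort only when ties at the threshold need the index rule
        part = np.argpartition(aw, w.size - keep - 1)
        lam = aw[part[w.size - keep - 1]]
        sel = part[w.size - keep:]
        v = np.zeros_like(w)
        v[sel] = np.sign(w[sel]) * (aw[sel] - lam)
        if np.count_nonzero(v) == keep:
            return _unit(v)
    order = np.argsort(-aw, kind="stable")  # stable: ties -> lowest index first
    sel = order[:keep]
    lam = 0.0 if keep == w.size else aw[order[keep]]
    v = np.zeros_like(w)
    v[sel] = np.sign(w[sel]) * np.maximum(aw[sel] - lam, 0.0)
    nz = np.count_nonzero(v)
    if nz < keep:
        # promote entries genuinely tied at the threshold (lowest index
        # first); zero weights stay out of the support, so keep > nnz(w)
        # yields the smaller support
        tied = sel[(aw[sel] <= lam) & (aw[sel] > 0)]
        if tied.size:
            surviving = np.abs(v[v != 0])
            eps = surviving.min() / 2.0 if surviving.size else 1.0
            v[tied] = np.sign(w[tied]) * eps
            logger.debug("soft_threshold_keep: tie at lambda=%g, promoted %s",
                         lam, tied.tolist())
    if not np.any(v):
        raise DataError("soft thresholding produced a zero vector")
    return _unit(v)


def make_design(
    block_names: list[str], between: float = 1.0, to_outcome: float = 1.0
) -> np.ndarray:
    """Design matrix over blocks + outcome (last row/column is the outcome).

    The default "full" design connects every block to every other and to the
    outcome with weight 1.
    """
    if not (0 <= between <= 1) or not (0 <= to_outcome <= 1):
        raise DataError("design weights must lie in [0, 1]")
    if to_outcome <= 0:
        raise DataError("every block must connect to the outcome with weight > 0")
    B = len(block_names)
    D = np.full((B + 1, B + 1), between)
    D[:, -1] = D[-1, :] = to_outcome
    np.fill_diagonal(D, 0.0)
    return D


def _check_design(D: np.ndarray, n_blocks: int) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (n_blocks + 1, n_blocks + 1):
        raise DataError(f"design must be {(n_blocks + 1, n_blocks + 1)}")
    if not np.allclose(D, D.T):
        raise DataError("design matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise DataError("design diagonal must be zero")
    if np.any((D < 0) | (D > 1)):
        raise DataError("design entries must lie in [0, 1]")
    if np.any(D[:-1, -1] <= 0):
        raise DataError("every block must connect to the outcome (weight > 0)")
    return D


@dataclass
class ConfusionCounts:
    """Two-class confusion totals: per-class sample counts and error counts."""

    totals: dict
    errors: dict

    def __post_init__(self) -> None:
        for cls, e in self.errors.items():
            if e > self.totals.get(cls, 0):
                raise DataError(f"class {cls!r}: errors exceed total")

    def add(self, other: "ConfusionCounts") -> "ConfusionCounts":
        totals = dict(self.totals)
        errors = dict(self.errors)
        for cls in other.totals:
            totals[cls] = totals.get(cls, 0) + other.totals[cls]
            errors[cls] = errors.get(cls, 0) + other.errors[cls]
        return ConfusionCounts(totals, errors)

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        totals, errors = {}, {}
        for cls in np.unique(y_true):
            mask = y_true == cls
            totals[cls] = int(mask.sum())
            errors[cls] = int(np.sum(y_pred[mask] != cls))
        return ConfusionCounts(totals, errors)


def balanced_error_rate(confusion: ConfusionCounts) -> float:
    """BER = mean over classes of (errors / class total)."""
    rates = []
    for cls, total in confusion.totals.items():
        if total == 0:
            raise DataError(f"class {cls!r} is empty")
        rates.append(confusion.errors.get(cls, 0) / total)
    if len(rates) < 2:
        raise DataError("need both classes to compute BER")
    return float(np.mean(rates))


@dataclass
class MultiblockSPLSDAResults:
    """Fitted multiblock sparse PLS-DA.

    Per block: sparse weights ``a`` (p_b x H, unit columns with exactly
    keepX nonzeros), deflation loadings ``p``, training scores ``t``
    (n x H), class centroids in score space, and the training scaling
    parameters. ``vote_weights`` holds each block's |corr(t_b, t_Y)| per
    component, used to weight the prediction vote.
    """

    block_names: list[str]
    feature_ids: dict
    weights: dict  # name -> (p, H)
    loadings: dict  # name -> (p, H)
    scores: dict  # name -> (n, H)
    y_scores: np.ndarray  # (n, H)
    y_loadings: np.ndarray  # (2, H)
    centroids: dict  # name -> (2, H), row per class
    scalers: dict  # name -> ScalingParams | None
    keepx: dict  # name -> tuple per component
    design: np.ndarray
    classes: np.ndarray
    class_sizes: np.ndarray
    vote_weights: dict  # name -> (H,)
    converged: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.y_scores.shape[1]

    def selected_features(self, n_components: int | None = None) -> dict:
        """Per block, the feature ids with nonzero weight in any of the
        first ``n_components`` components."""
        H = n_components or self.n_components
        out = {}
        for name in self.block_names:
            nz = np.any(self.weights[name][:, :H] != 0, axis=1)
            out[name] = [f for f, m in zip(self.feature_ids[name], nz) if m]
        return out

    def _rotation(self, name: str, H: int) -> np.ndarray:
        cache = self.__dict__.setdefault("_rot_cache", {})
        key = (name, H)
        if key not in cache:
            W = self.weights[name][:, :H]
            P = self.loadings[name][:, :H]
            cache[key] = W @ np.linalg.inv(P.T @ W)
        return cache[key]

    def transform(self, new_blocks: dict, n_components: int | None = None) -> dict:
        """Project new samples into each block's score space (training
        scaling reapplied; deflation-aware rotation, so training rows
        reproduce their training scores).

        A pandas DataFrame block is aligned to the training feature ids by
        column name; a plain array must already share the training column
        order."""
        H = n_components or self.n_components
        out = {}
        for name in self.block_names:
            if name not in new_blocks:
                raise DataError(f"block {name!r} missing from new data")
            X = new_blocks[name]
            if hasattr(X, "columns"):  # DataFrame: align by feature id
                missing = [f for f in self.feature_ids[name]
                           if f not in set(map(str, X.columns))]
                if missing:
                    raise DataError(
                        f"block {name!r}: missing feature ids {missing[:5]}"
                    )
                X = X[self.feature_ids[name]].to_numpy(dtype=float)
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_ids[name]):
                raise DataError(
                    f"block {name!r}: {X.shape[1]} features, expected "
                    f"{len(self.feature_ids[name])}"
                )
            scaler = self.scalers[name]
            if scaler is not None:
                X = scaler.apply(X)
            out[name] = X @ self._rotation(name, H)
        return out

    def predict(
        self, new_blocks: dict, n_components: int | None = None
    ) -> dict:
        """Nearest-centroid class per block plus the weighted aggregate vote.

        Returns a dict with ``per_block`` (name -> labels), ``aggregate``
        (labels), and ``scores`` (name -> (m, H) projected scores).
        """
        H = n_components or self.n_components
        scores = self.transform(new_blocks, H)
        m = next(iter(scores.values())).shape[0]
        per_block = {}
        votes = np.zeros((m, 2))
        block_w = {}
        for name in self.block_names:
            cent = self.centroids[name][:, :H]  # (2, H)
            d = np.linalg.norm(scores[name][:, None, :] - cent[None], axis=2)
            # equidistant -> lowest class index (argmin breaks ties that way)
            cls_idx = np.argmin(d, axis=1)
            per_block[name] = self.classes[cls_idx]
            w = float(np.mean(self.vote_weights[name][:H]))
            block_w[name] = w
            votes[np.arange(m), cls_idx] += w
        agg_idx = np.argmax(votes, axis=1)
        ties = votes[:, 0] == votes[:, 1]
        if np.any(ties):
            best = max(self.block_names, key=lambda b: block_w[b])
            best_idx = np.searchsorted(self.classes, per_block[best][ties])
            agg_idx[ties] = best_idx
        return {
            "per_block": per_block,
            "aggregate": self.classes[agg_idx],
            "scores": scores,
        }

    def to_dict(self) -> dict:
        """JSON-serializable bundle of the fitted model (arrays as nested
        lists)."""
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "block_names": list(self.block_names),
            "feature_ids": {k: list(v) for k, v in self.feature_ids.items()},
            "weights": {k: arr(v) for k, v in self.weights.items()},
            "loadings": {k: arr(v) for k, v in self.loadings.items()},
            "scores": {k: arr(v) for k, v in self.scores.items()},
            "y_scores": arr(self.y_scores),
            "y_loadings": arr(self.y_loadings),
            "centroids": {k: arr(v) for k, v in self.centroids.items()},
            "scalers": {
                k: None if s is None else
                {"mean": arr(s.mean), "sd": arr(s.sd), "kind": s.kind}
                for k, s in self.scalers.items()
            },
            "keepx": {k: list(v) for k, v in self.keepx.items()},
            "design": arr(self.design),
            "classes": arr(self.classes),
            "class_sizes": arr(self.class_sizes),
            "vote_weights": {k: arr(v) for k, v in self.vote_weights.items()},
            "converged": list(self.converged),
        }

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "MultiblockSPLSDAResults":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        from .preprocess import ScalingParams

        return cls(
            block_names=d["block_names"],
            feature_ids=d["feature_ids"],
            weights={k: np.array(v) for k, v in d["weights"].items()},
            loadings={k: np.array(v) for k, v in d["loadings"].items()},
            scores={k: np.array(v) for k, v in d["scores"].items()},
            y_scores=np.array(d["y_scores"]),
            y_loadings=np.array(d["y_loadings"]),
            centroids={k: np.array(v) for k, v in d["centroids"].items()},
            scalers={
                k: None if s is None else ScalingParams(
                    mean=np.array(s["mean"]), sd=np.array(s["sd"]),
                    kind=s["kind"],
                )
                for k, s in d["scalers"].items()
            },
            keepx={k: tuple(v) for k, v in d["keepx"].items()},
            design=np.array(d["design"]),
            classes=np.array(d["classes"]),
            class_sizes=np.array(d["class_sizes"]),
            vote_weights={k: np.array(v) for k, v in d["vote_weights"].items()},
            converged=d["converged"],
        )

    def summary(self) -> str:
        lines = [
            "Multiblock sparse PLS-DA",
            f"blocks: {self.block_names}, components: {self.n_components}",
        ]
        for name in self.block_names:
            lines.append(
                f"  {name}: keepX={list(self.keepx[name])}, "
                f"vote weight={np.round(self.vote_weights[name], 3).tolist()}"
            )
        sel = self.selected_features()
        for name in self.block_names:
            lines.append(f"  {name} selected: {sel[name]}")
        return "\n".join(lines)


class MultiblockSPLSDA:
    """Multiblock sparse PLS-DA model.

    Parameters
    ----------
    y : two-class labels, length n.
    blocks : mapping block name -> (n, p_b) matrix, or a
        :class:`~mbsig.data.MultiBlockDataset`.
    keepx : per block, an int (same for all components) or a sequence per
        component. Defaults to all features (no sparsity).
    n_components : number of latent components.
    design : (B+1, B+1) design matrix (blocks + outcome last); defaults to
        the full design.
    scale : standardize each block on the training rows (default True). Pass
        False when the caller supplies already-scaled matrices.
    scale_kind : "unit-variance" (default, as the reference multiblock
        implementation standardizes internally), "pareto" or "center-only".
    """

    def __init__(
        self,
        y,
        blocks,
        keepx=None,
        n_components: int = 1,
        design: np.ndarray | None = None,
        scale: bool = True,
        scale_kind: str = "unit-variance",
        feature_ids: dict | None = None,
        tol: float = 1e-6,
        max_iter: int = 100,
        track_objective: bool = False,
        warn_nonconvergence: bool = True,
    ):
        if isinstance(blocks, MultiBlockDataset):
            feature_ids = {b.name: list(b.feature_ids) for b in blocks.blocks}
            blocks = {b.name: b.matrix for b in blocks.blocks}
        self.block_names = list(blocks.keys())
        self.matrices = {k: np.asarray(v, dtype=float) for k, v in blocks.items()}
        y = np.asarray(y)
        self.classes = np.unique(y)
        if self.classes.size != 2:
            raise DataError("multiblock sPLS-DA requires exactly two classes")
        self.y = y
        n = y.size
        for name, X in self.matrices.items():
            if X.shape[0] != n:
                raise DataError(f"block {name!r}: row count != n samples")
            if not np.any(X):
                raise DataError(f"block {name!r}: all-zero matrix")
        if n_components > n - 1:
            raise DataError("n_components must be <= n - 1")
        self.n_components = n_components
        self.feature_ids = feature_ids or {
            name: [f"{name}:{j}" for j in range(X.shape[1])]
            for name, X in self.matrices.items()
        }
        self.keepx = self._normalize_keepx(keepx)
        D = (
            make_design(self.block_names)
            if design is None
            else np.asarray(design, dtype=float)
        )
        self.design = _check_design(D, len(self.block_names))
        self.scale = scale
        self.scale_kind = scale_kind
        self.track_objective = track_objective
        self.objective_trace: list[list[float]] = []
        self.warn_nonconvergence = warn_nonconvergence
        self.tol = tol
        self.max_iter = max_iter

    def _normalize_keepx(self, keepx) -> dict:
        out = {}
        for name, X in self.matrices.items():
            p = X.shape[1]
            if keepx is None:
                val = (p,) * self.n_components
            else:
                k = keepx[name] if isinstance(keepx, dict) else keepx
                if np.isscalar(k):
                    val = (int(k),) * self.n_components
                else:
                    val = tuple(int(v) for v in k)
                    if len(val) != self.n_components:
                        raise DataError(
                            f"keepx for {name!r} must have one value per component"
                        )
            for v in val:
                if not (1 <= v <= p):
                    raise DataError(
                        f"keepx={v} outside [1, {p}] for block {name!r}"
                    )
            out[name] = val
        return out

    def fit(self) -> MultiblockSPLSDAResults:
        names = self.block_names
        yi = np.searchsorted(self.classes, self.y)
        Y = indicator_matrix(yi)
        n = Y.shape[0]
        H = self.n_components
        D = self.design
        b_of = {name: i for i, name in enumerate(names)}

        Xs, scalers = {}, {}
        for name in names:
            if self.scale:
                Xs[name], scalers[name] = pareto_scale(
                    self.matrices[name], kind=self.scale_kind
                )
            else:
                Xs[name] = self.matrices[name].copy()
                scalers[name] = None

        W = {name: np.zeros((Xs[name].shape[1], H)) for name in names}
        P = {name: np.zeros((Xs[name].shape[1], H)) for name in names}
        T = {name: np.zeros((n, H)) for name in names}
        TY = np.zeros((n, H))
        C = np.zeros((2, H))
        converged = []

        for h in range(H):
            a = {}
            t = {}
            for name in names:
                M = Xs[name].T @ Y  # (p, 2)
                u, _, _ = np.linalg.svd(M, full_matrices=False)
                a[name] = soft_threshold_keep(u[:, 0], self.keepx[name][h])
                t[name] = Xs[name] @ a[name]
            c = Y.T @ sum(D[b_of[name], -1] * t[name] for name in names)
            c /= np.sqrt(c @ c)
            tY = Y @ c
            ok = False
            obj_trace: list[float] = []

            def objective() -> float:
                val = 0.0
                for i, a_name in enumerate(names):
                    for j in range(i + 1, len(names)):
                        val += D[i, j] * abs(t[a_name] @ t[names[j]])
                    val += D[i, -1] * abs(t[a_name] @ tY)
                return val

            for it in range(self.max_iter):
                prev = np.concatenate([t[name] for name in names] + [tY])
                for name in names:
                    i = b_of[name]
                    target = D[i, -1] * tY
                    for other in names:
                        if other != name:
                            target = target + D[i, b_of[other]] * t[other]
                    w = Xs[name].T @ target
                    a[name] = soft_threshold_keep(w, self.keepx[name][h])
                    t[name] = Xs[name] @ a[name]
                c = Y.T @ sum(D[b_of[name], -1] * t[name] for name in names)
                nc = np.sqrt(c @ c)
                if nc == 0:
                    raise DataError("degenerate outcome loadings (zero norm)")
                c /= nc
                tY = Y @ c
                if self.track_objective:
                    obj_trace.append(objective())
                cur = np.concatenate([t[name] for name in names] + [tY])
                if np.max(np.abs(cur - prev)) < self.tol:
                    ok = True
                    break
            if not ok:
                log = logger.warning if self.warn_nonconvergence else logger.debug
                log(
                    "component %d: no convergence after %d iterations "
                    "(last max score change %.2e)",
                    h + 1, self.max_iter, float(np.max(np.abs(cur - prev))),
                )
            converged.append(ok)
            if self.track_objective:
                self.objective_trace.append(obj_trace)
            for name in names:
                tt = t[name] @ t[name]
                p_h = Xs[name].T @ t[name] / tt
                Xs[name] -= np.outer(t[name], p_h)
                W[name][:, h] = a[name]
                P[name][:, h] = p_h
                T[name][:, h] = t[name]
            TY[:, h] = tY
            C[:, h] = c

        centroids = {}
        vote_w = {}
        for name in names:
            cent = np.vstack([T[name][yi == k].mean(axis=0) for k in range(2)])
            centroids[name] = cent
            vw = np.zeros(H)
            for h in range(H):
                sd = T[name][:, h].std() * TY[:, h].std()
                vw[h] = (
                    0.0
                    if sd == 0
                    else abs(np.corrcoef(T[name][:, h], TY[:, h])[0, 1])
                )
            vote_w[name] = vw

        sizes = np.array([np.sum(yi == k) for k in range(2)])
        return MultiblockSPLSDAResults(
            block_names=names,
            feature_ids=self.feature_ids,
            weights=W,
            loadings=P,
            scores=T,
            y_scores=TY,
            y_loadings=C,
            centroids=centroids,
            scalers=scalers,
            keepx=self.keepx,
            design=self.design,
            classes=self.classes,
            class_sizes=sizes,
            vote_weights=vote_w,
            converged=converged,
        )


def fit_block_splsda(
    y, blocks, keepx=None, n_components: int = 1, design=None, scale: bool = True,
    scale_kind: str = "unit-variance", feature_ids=None,
) -> MultiblockSPLSDAResults:
    """Functional wrapper over :class:`MultiblockSPLSDA`."""
    return MultiblockSPLSDA(
        y, blocks, keepx=keepx, n_components=n_components, design=design,
        scale=scale, scale_kind=scale_kind, feature_ids=feature_ids,
    ).fit()


def predict_block_splsda(model: MultiblockSPLSDAResults, new_blocks: dict, **kw):
    """Functional wrapper over :meth:`MultiblockSPLSDAResults.predict`."""
    return model.predict(new_blocks, **kw)
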