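"""Model performance: per-block ROC/AUC with rank-based p-values, the
repeated 2-fold CV optimism (bias) estimate, and the clustered image map.

AUC is computed by the rank (Mann-Whitney) formulation with midranks for
ties; its p-value is the two-sided Mann-Whitney test of the per-sample
scores between classes — exact enumeration for small tie-free samples,
normal approximation with tie correction otherwise. The ROC scores are the
per-block latent scores of component 1, oriented so the Decline class has
the higher mean (orientation is logged), as in a one-component discriminant
model.

The optimism estimate repeats stratified 2-fold CV ten times: the final
model's hyperparameters are refitted on each half and the held-out halves
scored; bias = mean cross-validated AUC - apparent (full-data) AUC. A small
negative bias indicates mild overfitting of the apparent AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from ._rng import substream
from .data import DataError, MultiBlockDataset
from .multiblock import MultiblockSPLSDA, MultiblockSPLSDAResults, make_design
from .plsda import stratified_folds

logger = logging.getLogger("mbsig")

__all__ = [
    "roc_auc_with_p",
    "repeated_cv_auc_bias",
    "clustered_image_map",
    "block_roc_scores",
    "EvaluationReport",
    "CimArtifact",
]


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p-value: exact enumeration for tie-free
    samples with n_x * n_y <= 400, midrank normal approximation with tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size * y.size <= 400:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def roc_auc_with_p(scores, labels) -> dict:
    """AUC (rank formulation, midranks for ties), two-sided Mann-Whitney
    p-value, and the ROC curve points.

    ``labels`` must be two-class; the positive class is the one with the
    higher mean score unless labels are the package's Decline/NoDecline
    strings, in which case Decline is positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    classes = np.unique(labels)
    if classes.size != 2:
        raise DataError("labels must have exactly two classes")
    if "Decline" in classes and "NoDecline" in classes:
        pos = "Decline"
    else:
        pos = max(classes, key=lambda c: scores[labels == c].mean())
    pos_scores = scores[labels == pos]
    neg_scores = scores[labels != pos]
    n1, n0 = pos_scores.size, neg_scores.size

    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels == pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    p = mann_whitney_p(pos_scores, neg_scores)

    thresholds = np.concatenate(([np.inf], np.sort(np.unique(scores))[::-1]))
    tpr = [np.mean(pos_scores >= t) for t in thresholds]
    fpr = [np.mean(neg_scores >= t) for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return {"auc": float(auc), "p_value": p, "curve": curve, "positive": pos}


def block_roc_scores(
    model: MultiblockSPLSDAResults, blocks: dict, y
) -> dict:
    """Component-1 score per block, oriented so the Decline/positive class
    (higher label) has the higher mean score."""
    y = np.asarray(y)
    scores = model.transform(blocks, n_components=model.n_components)
    pos = model.classes[-1]
    out = {}
    for name, t in scores.items():
        s = t[:, 0].copy()
        if s[y == pos].mean() < s[y != pos].mean():
            s = -s
            logger.info("block %s: score orientation flipped", name)
        out[name] = s
    return out


def repeated_cv_auc_bias(
    data: MultiBlockDataset,
    keepx,
    n_components: int = 1,
    repeats: int = 10,
    folds: int = 2,
    seed: int = 0,
    design: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apparent vs cross-validated AUC per block; bias = cv - apparent.

    Stratified ``folds``-fold CV repeated ``repeats`` times; per held-out
    fold the training-half model scores the held-out samples and their AUC
    is recorded; the cv AUC is the mean of the repeats x folds values.
    """
    y = data.y()
    blocks = {b.name: b.matrix for b in data.blocks}
    if design is None:
        design = make_design(list(blocks.keys()))

    full = MultiblockSPLSDA(
        y, blocks, keepx=keepx, n_components=n_components, design=design
    ).fit()
    apparent = {}
    for name, s in block_roc_scores(full, blocks, y).items():
        apparent[name] = roc_auc_with_p(s, y)["auc"]

    rng = substream(seed, "cv-auc")
    held = {name: [] for name in blocks}
    for _ in range(repeats):
        fold_idx = stratified_folds(y, folds, rng)
        for ho in fold_idx:
            tr = np.setdiff1d(np.arange(y.size), ho)
            m = MultiblockSPLSDA(
                y[tr], {k: v[tr] for k, v in blocks.items()}, keepx=keepx,
                n_components=n_components, design=design,
            ).fit()
            t = m.transform({k: v[ho] for k, v in blocks.items()})
            t_tr = m.scores
            pos = m.classes[-1]
            for name in blocks:
                s = t[name][:, 0].copy()
                if t_tr[name][y[tr] == pos, 0].mean() < t_tr[name][
                    y[tr] != pos, 0
                ].mean():
                    s = -s  # orientation from the training half
                held[name].append(roc_auc_with_p(s, y[ho])["auc"])
    rows = []
    for name in blocks:
        vals = np.array(held[name])
        rows.append(
            {
                "block": name,
                "apparent_auc": apparent[name],
                "cv_auc": vals.mean(),
                "bias": vals.mean() - apparent[name],
                "n_cv_values": vals.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CimArtifact:
    """Clustered image map: display matrix plus deterministic row/column
    orders and the linkage trees."""

    matrix: pd.DataFrame  # samples x features, reordered
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_groups: list = field(default_factory=list)


def clustered_image_map(
    matrix,
    labels,
    sample_ids=None,
    feature_ids=None,
    metric: str = "euclidean",
    method: str = "complete",
) -> CimArtifact:
    """Hierarchically cluster samples (rows) and selected features (columns)
    of a scaled matrix; Euclidean distance and complete linkage by default,
    deterministic leaf order (scipy's, ties by index)."""
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if p < 2:
        raise DataError("clustered image map needs >= 2 selected features")
    labels = list(np.asarray(labels))
    sample_ids = list(sample_ids) if sample_ids is not None else list(range(n))
    feature_ids = list(feature_ids) if feature_ids is not None else list(range(p))
    row_link = linkage(X, method=method, metric=metric)
    col_link = linkage(X.T, method=method, metric=metric)
    row_order = leaves_list(row_link).tolist()
    col_order = leaves_list(col_link).tolist()
    ordered = pd.DataFrame(
        X[np.ix_(row_order, col_order)],
        index=[sample_ids[i] for i in row_order],
        columns=[feature_ids[j] for j in col_order],
    )
    return CimArtifact(
        matrix=ordered,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        row_groups=[labels[i] for i in row_order],
    )


@dataclass
class EvaluationReport:
    """Per-block ROC/AUC/p, the optimism table, and the CIM artifact."""

    roc: dict  # block -> {"auc", "p_value", "curve", "positive"}
    bias: pd.DataFrame
    cim: CimArtifact | None = None

    def summary(self) -> str:
        lines = ["Model evaluation"]
        for name, r in self.roc.items():
            lines.append(
                f"  {name}: AUC={r['auc']:.4f}  p={r['p_value']:.4g}"
            )
        for _, row in self.bias.iterrows():
            lines.append(
                f"  {row['block']}: apparent AUC={row['apparent_auc']:.3f} "
                f"cv AUC={row['cv_auc']:.3f} bias={row['bias']:+.3f}"
            )
        return "\n".join(lines)


def evaluate_model(
    data: MultiBlockDataset,
    model: MultiblockSPLSDAResults,
    signature_features: dict | None = None,
    repeats: int = 10,
    folds: int = 2,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full evaluation report for a fitted final model."""
    y = data.y()
    blocks = {b.name: b.matrix for b in data.blocks}
    roc = {}
    for name, s in block_roc_scores(model, blocks, y).items():
        roc[name] = roc_auc_with_p(s, data.samples.group.to_numpy())
    bias = repeated_cv_auc_bias(
        data, keepx=model.keepx, n_components=model.n_components,
        repeats=repeats, folds=folds, seed=seed, design=model.design,
    )
    cim = None
    sel = signature_features or model.selected_features()
    cols, mats = [], []
    for b in data.blocks:
        ids = [f for f in sel.get(b.name, []) if f in b.feature_ids]
        if ids:
            sub = b.subset_features(ids)
            m = sub.matrix
            m = (m - m.mean(axis=0)) / np.where(
                m.std(axis=0, ddof=1) == 0, 1, m.std(axis=0, ddof=1)
            )
            mats.append(m)
            cols.extend(ids)
    if mats and sum(m.shape[1] for m in mats) >= 2:
        cim = clustered_image_map(
            np.hstack(mats),
            data.samples.group.to_numpy(),
            sample_ids=data.samples.sample_ids,
            feature_ids=cols,
        )
    return EvaluationReport(roc=roc, bias=bias, cim=cim)
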