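"""Bootstrap stability selection of the multiblock model's hyperparameters
and of the metabolite signature.

The procedure mirrors the study's tuning protocol. For each stratified
bootstrap replicate (resampling within class, preserving the 12:8 class
sizes):

1. choose the number of latent components from 1-5, with all features kept,
   by minimizing the balanced error rate (BER) under stratified 4-fold CV;
2. with the component count fixed, choose keepX per block over the published
   grids (1-9 step 1, then 10 up to the block size step 5) again by 4-fold-CV
   BER — blockwise-sequentially by default (first block optimized with the
   second at full, then the second at the first's optimum), exhaustively over
   the joint grid on request; ties always go to the smaller value;
3. refit on the whole bootstrap sample with the chosen hyperparameters and
   record which features carry nonzero loadings.

One methodological detail: CV folds inside a bootstrap replicate are
*grouped* — all copies of one original sample land in the same fold, so a
duplicated sample can never sit on both sides of a split, which would reward
overfitting and bias the component count upward.

Aggregation over replicates yields modal hyperparameters and per-feature
selection frequencies. The final model is fitted on the entire sample with
the modal hyperparameters; the reported signature is the metabolite-level
set of final-model variables whose selection frequency reaches the 60%
threshold — "the most frequently selected variables of the final model".

"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


from ._rng import substream
from .data import MultiBlockDataset, PipelineConfig
from .multiblock import (
    ConfusionCounts,
    MultiblockSPLSDA,
    MultiblockSPLSDAResults,
    balanced_error_rate,
    make_design,
)
from .plsda import stratified_folds
from .preprocess import fold_change, pareto_scale

logger = logging.getLogger("mbsig")

__all__ = ["cv_ber", "tune_bootstrap", "fit_final_model", "TuningResult"]


def _grouped_folds(groups, y, n_folds, rng):
    """Stratified fold assignment over *unique* group labels; every row of a
    group inherits its group's fold. With groups == arange(n) this is plain
    stratified assignment."""
    groups = np.asarray(groups)
    assign: dict = {}
    for cls in np.unique(y):
        uniq = np.unique(groups[y == cls])
        uniq = uniq[rng.permutation(uniq.size)]
        for i, u in enumerate(uniq):
            assign[u] = i % n_folds
    fold_of = np.array([assign[g] for g in groups])
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def _scaled_folds(y, blocks, folds, seed, scale_kind, groups=None):
    """Precompute per-fold train/test matrices with train-only scaling.

    Returns a list of (y_train, y_test, scaled_train, scaled_test) tuples so
    that many hyperparameter candidates can be evaluated on the same folds
    without re-scaling. ``groups`` keeps duplicated samples (bootstrap
    copies) inside a single fold.
    """
    rng = substream(seed, "cv-ber")
    if groups is None:
        fold_idx = stratified_folds(y, folds, rng)
    else:
        fold_idx = _grouped_folds(groups, y, folds, rng)
    n = y.size
    out = []
    for heldout in fold_idx:
        train = np.setdiff1d(np.arange(n), heldout)
        tr, te = {}, {}
        for name, X in blocks.items():
            tr[name], params = pareto_scale(X[train], kind=scale_kind)
            te[name] = params.apply(X[heldout])
        out.append((y[train], y[heldout], tr, te))
    return out


def _ber_over_folds(prepared, keepx, n_components, design, max_ncomp=None,
                    tol=1e-6, max_iter=100):
    """Pooled-confusion BER (and per-fold BERs) for one candidate on
    precomputed folds.

    When ``max_ncomp`` is given, the model is fitted once per fold with that
    many components and evaluated at every truncation 1..max_ncomp (the
    deflation is sequential, so the first k components of a deeper fit equal
    the k-component fit). Returns ``(pooled, per_fold)`` where ``pooled`` has
    one BER per evaluated component count (a scalar pooled BER in the
    fixed-ncomp case) and ``per_fold`` is (n_folds, n_evaluated).
    """
    H = max_ncomp or n_components
    pooled = [None] * H
    per_fold = np.zeros((len(prepared), H))
    for i, (y_tr, y_te, tr, te) in enumerate(prepared):
        model = MultiblockSPLSDA(
            y_tr, tr, keepx=keepx, n_components=H, design=design, scale=False,
            tol=tol, max_iter=max_iter, warn_nonconvergence=max_iter >= 100,
        ).fit()
        for k in range(1, H + 1):
            pred = model.predict(te, n_components=k)
            cc = ConfusionCounts.from_predictions(y_te, pred["aggregate"])
            per_fold[i, k - 1] = balanced_error_rate(cc)
            pooled[k - 1] = cc if pooled[k - 1] is None else pooled[k - 1].add(cc)
    bers = np.array([balanced_error_rate(cc) for cc in pooled])
    if max_ncomp:
        return bers, per_fold
    return float(bers[n_components - 1]), per_fold[:, n_components - 1]


def _pick_min(candidates, pooled, per_fold=None):
    """Minimum pooled BER; ties resolve to the smaller (earlier) candidate.

    Returns (candidate, pooled BER at candidate, index).
    """
    pooled = np.asarray(pooled, dtype=float)
    idx = int(np.argmin(pooled))  # first occurrence: ties -> smaller
    return candidates[idx], float(pooled[idx]), idx


def cv_ber(
    data: MultiBlockDataset | tuple,
    keepx=None,
    n_components: int = 1,
    folds: int = 4,
    seed: int = 0,
    design: np.ndarray | None = None,
    scale_kind: str = "unit-variance",
) -> float:
    """Mean balanced error rate of a multiblock sPLS-DA under stratified
    k-fold CV (scaling learned on each training split; confusion counts
    pooled over folds).

    ``data`` is a :class:`MultiBlockDataset` with group labels, or a
    ``(y, blocks_dict)`` pair.
    """
    if isinstance(data, MultiBlockDataset):
        y = data.y()
        blocks = {b.name: b.matrix for b in data.blocks}
    else:
        y, blocks = data
        y = np.asarray(y)
    if design is None:
        design = make_design(list(blocks.keys()))
    prepared = _scaled_folds(y, blocks, folds, seed, scale_kind)
    ber, _ = _ber_over_folds(prepared, keepx, n_components, design)
    return ber


@dataclass
class TuningResult:
    """Evidence base of the signature: per-replicate choices and aggregated
    selection frequencies."""

    replicates: pd.DataFrame  # replicate, ncomp, ber, keepx_<block>...
    frequencies: pd.DataFrame  # block, feature_id, metabolite, frequency
    trace: pd.DataFrame  # replicate, stage, candidate, ber
    modal_ncomp: int
    modal_keepx: dict
    n_bootstrap: int
    keepx_grids: dict = field(default_factory=dict)

    def metabolite_frequencies(self) -> pd.DataFrame:
        """Selection frequency collapsed to metabolite level: a metabolite
        counts as selected in a replicate when any of its features is."""
        reps = self._met_sets
        counts: Counter = Counter()
        for mets in reps:
            counts.update(mets)
        rows = [
            {"metabolite": m, "frequency": c / self.n_bootstrap}
            for m, c in counts.items()
        ]
        return (
            pd.DataFrame(rows, columns=["metabolite", "frequency"])
            .sort_values("frequency", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    def frequent_metabolites(self, threshold: float = 0.60) -> pd.DataFrame:
        """Metabolites whose selection frequency reaches ``threshold``."""
        mf = self.metabolite_frequencies()
        return mf[mf["frequency"] >= threshold].reset_index(drop=True)

    def summary(self) -> str:
        sig = self.frequent_metabolites()
        lines = [
            "Bootstrap stability selection",
            f"replicates: {self.n_bootstrap}",
            f"modal components: {self.modal_ncomp}",
            f"modal keepX: {self.modal_keepx}",
            f"metabolites at frequency >= 0.60: {sig['metabolite'].tolist()}",
        ]
        return "\n".join(lines)


def tune_bootstrap(
    data: MultiBlockDataset,
    config: PipelineConfig,
    exhaustive: bool = False,
) -> TuningResult:
    """Run the bootstrap stability-selection procedure (see module docs)."""
    y = data.y()
    blocks = {b.name: b.matrix for b in data.blocks}
    names = list(blocks.keys())
    annotation = {
        b.name: {f: b.metabolite_of(f) for f in b.feature_ids} for b in data.blocks
    }
    feature_ids = {b.name: list(b.feature_ids) for b in data.blocks}
    grids = {b.name: config.keepx_grid_for(b) for b in data.blocks}
    design = make_design(names, to_outcome=config.design_weight)
    ncomp_grid = [
        k for k in config.ncomp_grid if k <= y.size - 1
    ]
    max_ncomp = max(ncomp_grid)

    rep_rows, trace_rows = [], []
    sel_counts = {name: np.zeros(len(feature_ids[name])) for name in names}
    met_sets: list[set] = []

    boot_rng = substream(config.seed, "bootstrap")
    class_idx = [np.flatnonzero(y == c) for c in np.unique(y)]
    # looser solver settings on the CV path: candidate ranking is stable well
    # before the 1e-6 score tolerance of the final fits
    cv_kw = {"tol": 1e-4, "max_iter": 30}

    for r in range(config.n_bootstrap):
        # stratified bootstrap; redraw in the (vanishingly rare) event a
        # class collapses to a single unique sample, which would make
        # grouped CV impossible
        while True:
            idx = np.concatenate(
                [ci[boot_rng.integers(0, ci.size, ci.size)] for ci in class_idx]
            )
            yb = y[idx]
            assert np.unique(yb).size == 2, "stratified resampling lost a class"
            n_unique = min(np.unique(idx[yb == c]).size for c in np.unique(yb))
            if n_unique >= 2:
                break
        sub = {name: X[idx] for name, X in blocks.items()}
        fold_seed = int(boot_rng.integers(2**31))
        n_folds = min(config.cv_folds_tuning, n_unique)
        prepared = _scaled_folds(
            yb, sub, n_folds, fold_seed, "unit-variance", groups=idx
        )

        # stage 1: number of components at keepX = all
        bers, folds_ber = _ber_over_folds(
            prepared, None, None, design, max_ncomp=max_ncomp, **cv_kw
        )
        stage1 = [bers[k - 1] for k in ncomp_grid]
        pf1 = [folds_ber[:, k - 1] for k in ncomp_grid]
        ncomp, _, _ = _pick_min(ncomp_grid, stage1, pf1)
        for k in ncomp_grid:
            trace_rows.append((r, "ncomp", str(k), float(bers[k - 1])))
        logger.debug("replicate %d: ncomp=%d (BER %.3f)", r, ncomp,
                     bers[ncomp - 1])

        # stage 2: keepX per block over the grids
        if exhaustive and len(names) == 2:
            cands, pooled, per_fold = [], [], []
            for k1 in grids[names[0]]:
                for k2 in grids[names[1]]:
                    cand = {names[0]: k1, names[1]: k2}
                    ber, pf = _ber_over_folds(prepared, cand, ncomp, design,
                                              **cv_kw)
                    trace_rows.append((r, "keepx", f"{k1},{k2}", ber))
                    cands.append(dict(cand))
                    pooled.append(ber)
                    per_fold.append(pf)
            keepx, final_ber, _ = _pick_min(cands, pooled, per_fold)
        else:
            current = {name: sub[name].shape[1] for name in names}
            final_ber = None
            for name in names:
                pooled, per_fold = [], []
                for k in grids[name]:
                    ber, pf = _ber_over_folds(
                        prepared, {**current, name: k}, ncomp, design, **cv_kw
                    )
                    trace_rows.append((r, f"keepx_{name}", str(k), ber))
                    pooled.append(ber)
                    per_fold.append(pf)
                current[name], final_ber, _ = _pick_min(
                    list(grids[name]), pooled, per_fold
                )
            keepx = current

        # refit on the whole bootstrap sample, record selections
        model = MultiblockSPLSDA(
            yb, sub, keepx=keepx, n_components=ncomp, design=design,
            feature_ids=feature_ids,
        ).fit()
        sel = model.selected_features()
        mets = set()
        for name in names:
            fid_pos = {f: i for i, f in enumerate(feature_ids[name])}
            for f in sel[name]:
                sel_counts[name][fid_pos[f]] += 1
                mets.add(annotation[name][f])
        met_sets.append(mets)
        row = {"replicate": r, "ncomp": ncomp, "ber": final_ber}
        row.update({f"keepx_{name}": keepx[name] for name in names})
        rep_rows.append(row)
        logger.info(
            "replicate %d: ncomp=%d keepX=%s BER=%.3f", r, ncomp, keepx, final_ber
        )

    replicates = pd.DataFrame(rep_rows)
    modal_ncomp = int(
        replicates["ncomp"].value_counts().sort_index().idxmax()
    )
    modal_keepx = {
        name: int(replicates[f"keepx_{name}"].value_counts().sort_index().idxmax())
        for name in names
    }
    freq_rows = []
    for name in names:
        for f, cnt in zip(feature_ids[name], sel_counts[name]):
            freq_rows.append(
                {
                    "block": name,
                    "feature_id": f,
                    "metabolite": annotation[name][f],
                    "frequency": cnt / config.n_bootstrap,
                }
            )
    frequencies = pd.DataFrame(freq_rows)
    trace = pd.DataFrame(
        trace_rows, columns=["replicate", "stage", "candidate", "ber"]
    )
    result = TuningResult(
        replicates=replicates,
        frequencies=frequencies,
        trace=trace,
        modal_ncomp=modal_ncomp,
        modal_keepx=modal_keepx,
        n_bootstrap=config.n_bootstrap,
        keepx_grids=grids,
    )
    result._met_sets = met_sets  # type: ignore[attr-defined]
    logger.info("tuning done: %s", result.summary().replace("\n", "; "))
    return result


def fit_final_model(
    data: MultiBlockDataset,
    tuning: TuningResult,
    config: PipelineConfig,
) -> tuple[MultiblockSPLSDAResults, pd.DataFrame]:
    """Fit the final model on all samples with the modal hyperparameters and
    assemble the signature table.

    The signature is the metabolite-level intersection of (a) the variables
    the final model selects and (b) the metabolites whose bootstrap selection
    frequency reaches the threshold — the "most frequently selected variables
    of the final model". Several buckets of one metabolite collapse to a
    single signature row. Fold changes are on the normalized intensity scale.
    """
    y = data.y()
    blocks = {b.name: b.matrix for b in data.blocks}
    feature_ids = {b.name: list(b.feature_ids) for b in data.blocks}
    design = make_design(list(blocks.keys()), to_outcome=config.design_weight)
    model = MultiblockSPLSDA(
        y, blocks, keepx=tuning.modal_keepx, n_components=tuning.modal_ncomp,
        design=design, feature_ids=feature_ids,
    ).fit()

    fcs = []
    groups = data.samples.group.to_numpy()
    annotation = {b.name: {f: b.metabolite_of(f) for f in b.feature_ids}
                  for b in data.blocks}
    for b in data.blocks:
        fc = fold_change(b, groups)
        fc.insert(0, "block", b.name)
        fcs.append(fc)
    fc_all = pd.concat(fcs, ignore_index=True)
    met_fc = fc_all.groupby("metabolite", as_index=False)["fold_change"].mean()

    selected = model.selected_features()
    final_mets = {
        annotation[name][f] for name in selected for f in selected[name]
    }
    frequent = tuning.frequent_metabolites(config.frequency_threshold)
    sig = frequent[frequent["metabolite"].isin(final_mets)].reset_index(drop=True)
    feat_freq = tuning.frequencies
    sig_feats = feat_freq[
        feat_freq["metabolite"].isin(sig["metabolite"])
    ][["metabolite", "block", "feature_id", "frequency"]]
    table = sig.merge(met_fc, on="metabolite", how="left")
    table["features"] = table["metabolite"].map(
        sig_feats.groupby("metabolite")["feature_id"].apply(list)
    )
    return model, table
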