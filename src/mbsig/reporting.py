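"""Result tables and figures: selection frequencies, signature, tuning
trace, ROC points; score plot, loading plot, ROC curves and the clustered
image map. All figures use the non-interactive Agg backend."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import DataError, MultiBlockDataset
from .evaluation import EvaluationReport
from .multiblock import MultiblockSPLSDAResults
from .tuning import TuningResult

logger = logging.getLogger("mbsig")

__all__ = ["write_results"]

_GROUP_COLORS = {"Decline": "#d95f02", "NoDecline": "#1b9e77"}


def _score_plot(model: MultiblockSPLSDAResults, groups, path: Path) -> None:
    fig, axes = plt.subplots(
        1, len(model.block_names), figsize=(4.5 * len(model.block_names), 4)
    )
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, model.block_names):
        t = model.scores[name]
        y2 = t[:, 1] if t.shape[1] > 1 else model.y_scores[:, 0]
        for gname in np.unique(groups):
            m = groups == gname
            ax.scatter(t[m, 0], y2[m], label=str(gname),
                       color=_GROUP_COLORS.get(str(gname)))
        ax.set_xlabel("component 1")
        ax.set_ylabel("component 2" if t.shape[1] > 1 else "outcome score")
        ax.set_title(name)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _loading_plot(model: MultiblockSPLSDAResults, path: Path, top: int = 15):
    fig, axes = plt.subplots(
        1, len(model.block_names), figsize=(5 * len(model.block_names), 4.5)
    )
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, model.block_names):
        w = model.weights[name][:, 0]
        nz = np.flatnonzero(w)
        order = nz[np.argsort(np.abs(w[nz]))][-top:]
        ids = [model.feature_ids[name][j] for j in order]
        ax.barh(range(len(order)), np.abs(w[order]), color="#4477aa")
        ax.set_yticks(range(len(order)), ids, fontsize=7)
        ax.set_xlabel("|loading|, component 1")
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _roc_plot(report: EvaluationReport, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, r in report.roc.items():
        ax.plot(r["curve"]["fpr"], r["curve"]["tpr"],
                label=f"{name}: AUC={r['auc']:.4f} (p={r['p_value']:.3g})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cim_plot(report: EvaluationReport, path: Path) -> None:
    cim = report.cim
    fig, (ax_strip, ax) = plt.subplots(
        1, 2, figsize=(8, 5), width_ratios=[0.04, 1], sharey=True
    )
    m = cim.matrix.to_numpy()
    vmax = np.nanmax(np.abs(m)) or 1.0
    ax.pcolormesh(m, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(np.arange(m.shape[1]) + 0.5, cim.matrix.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(np.arange(m.shape[0]) + 0.5, cim.matrix.index, fontsize=7)
    strip = np.array(
        [[1.0 if g == "Decline" else 0.0] for g in cim.row_groups]
    )
    ax_strip.pcolormesh(strip, cmap="PiYG")
    ax_strip.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_results(
    out_dir: str | Path,
    data: MultiBlockDataset,
    tuning: TuningResult,
    model: MultiblockSPLSDAResults,
    signature: pd.DataFrame,
    report: EvaluationReport,
    overwrite: bool = False,
    config=None,
) -> list[str]:
    """Write all result tables and figures; returns the manifest (list of
    file names written). Refuses to overwrite an existing manifest unless
    ``overwrite=True``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise DataError(f"{manifest_path} exists; pass overwrite=True to rerun")

    written: list[str] = []

    def table(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    table(tuning.frequencies, "selection_frequencies.csv")
    sig = signature.copy()
    if "features" in sig.columns:
        sig["features"] = sig["features"].apply(
            lambda v: ";".join(v) if isinstance(v, list) else v
        )
    table(sig, "signature.csv")
    table(tuning.trace, "tuning_trace.csv")
    table(tuning.replicates, "tuning_replicates.csv")
    roc_rows = []
    for name, r in report.roc.items():
        c = r["curve"].copy()
        c.insert(0, "block", name)
        roc_rows.append(c)
    table(pd.concat(roc_rows, ignore_index=True), "roc_points.csv")
    table(report.bias, "auc_bias.csv")
    if report.cim is not None:
        cim_df = report.cim.matrix.copy()
        cim_df.insert(0, "group", report.cim.row_groups)
        cim_df.to_csv(out / "cim_matrix.csv")
        written.append("cim_matrix.csv")

    model.save(out / "final_model.json")
    written.append("final_model.json")
    if config is not None:
        (out / "run_config.json").write_text(json.dumps(config.to_dict(),
                                                        indent=1))
        written.append("run_config.json")

    groups = data.samples.group.to_numpy()
    _score_plot(model, groups, out / "score_plot.png")
    written.append("score_plot.png")
    _loading_plot(model, out / "loading_plot.png")
    written.append("loading_plot.png")
    _roc_plot(report, out / "roc.png")
    written.append("roc.png")
    if report.cim is not None:
        _cim_plot(report, out / "cim.png")
        written.append("cim.png")

    manifest_path.write_text(json.dumps(written, indent=1))
    written.append("manifest.json")
    logger.info("wrote %d files to %s", len(written), out)
    return written
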