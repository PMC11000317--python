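"""Normalization, scaling, decliner labeling and fold changes.

NMR bucket tables are normalized to total intensity (each spectrum divided by
its summed bucket area) so that overall-concentration differences between
plasma samples drop out. All blocks are then Pareto scaled — centered and
divided by the square root of the per-feature standard deviation — which
damps the dominance of high-intensity features without inflating noise the
way unit-variance scaling does. Scaling parameters are always learned on
training rows only and reapplied verbatim to held-out rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DECLINE, NO_DECLINE, DataError, OmicsBlock, SampleTable

logger = logging.getLogger("mbsig")

__all__ = [
    "ScalingParams",
    "total_intensity_normalize",
    "pareto_scale",
    "label_decliners",
    "fold_change",
]


@dataclass
class ScalingParams:
    """Frozen per-feature scaling learned on a training set."""

    mean: np.ndarray
    sd: np.ndarray
    kind: str = "pareto"  # pareto | unit-variance | center-only

    def divisor(self) -> np.ndarray:
        if self.kind == "pareto":
            d = np.sqrt(self.sd)
        elif self.kind == "unit-variance":
            d = self.sd.copy()
        elif self.kind == "center-only":
            d = np.ones_like(self.sd)
        else:
            raise ValueError(f"unknown scaling kind {self.kind!r}")
        d[d == 0] = 1.0  # constant feature -> centered only
        return d

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.divisor()


def pareto_scale(
    matrix: np.ndarray,
    params: ScalingParams | None = None,
    kind: str = "pareto",
) -> tuple[np.ndarray, ScalingParams]:
    """Scale a samples x features matrix; x' = (x - mean) / sqrt(sd).

    When ``params`` is supplied it is reapplied without re-learning (the
    held-out path). SDs use the n-1 denominator. Zero-SD features are centered
    to 0 with a logged warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if params is None:
        if matrix.shape[0] < 2:
            raise DataError("need >= 2 rows to learn scaling parameters")
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        if np.any(sd == 0):
            idx = np.flatnonzero(sd == 0)
            logger.warning("constant features at columns %s set to 0 after scaling",
                           idx.tolist())
        params = ScalingParams(mean=mean, sd=sd, kind=kind)
    return params.apply(matrix), params


def total_intensity_normalize(block: OmicsBlock) -> OmicsBlock:
    """Divide each sample's row by its total intensity (row sums become 1)."""
    m = block.matrix
    if np.any(m < 0):
        raise DataError(f"block {block.name!r}: negative intensities")
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.flatnonzero(sums <= 0)
        raise DataError(
            f"block {block.name!r}: all-zero spectrum at sample row(s) {bad.tolist()}"
        )
    return OmicsBlock(block.name, list(block.feature_ids), m / sums[:, None],
                      dict(block.annotation))


def label_decliners(
    samples: SampleTable,
    threshold: int = 2,
    rule: str = "first-to-last",
) -> SampleTable:
    """Apply the decliner rule: a drop of >= ``threshold`` MMSE points across
    the follow-up labels a sample Decline, otherwise NoDecline.

    ``rule`` selects how the drop is measured: ``"first-to-last"`` (default)
    or ``"baseline-to-minimum"``.
    """
    if samples.mmse_series is None:
        raise DataError("sample table has no MMSE series")
    labels = {}
    for sid in samples.sample_ids:
        series = samples.mmse_series.get(sid, [])
        if len(series) < 2:
            raise DataError(f"sample {sid!r}: need >= 2 MMSE time points")
        ordered = sorted(series, key=lambda ts: ts[0])
        scores = [s for _, s in ordered]
        if rule == "first-to-last":
            drop = scores[0] - scores[-1]
        elif rule == "baseline-to-minimum":
            drop = scores[0] - min(scores)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        labels[sid] = DECLINE if drop >= threshold else NO_DECLINE
    group = pd.Series([labels[s] for s in samples.sample_ids],
                      index=pd.Index(samples.sample_ids))
    return SampleTable(
        list(samples.sample_ids),
        group=group,
        mmse_series=samples.mmse_series,
        covariates=samples.covariates,
    )


def fold_change(block: OmicsBlock, groups: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-feature fold change: mean(Decline) / mean(NoDecline).

    Computed on normalized, un-scaled intensities — ratios on the intensity
    scale, as in a fold-change table. A zero NoDecline mean yields NaN (an
    explicit undefined marker), never infinity.
    """
    g = np.asarray(groups)
    decl = block.matrix[g == DECLINE]
    nodecl = block.matrix[g == NO_DECLINE]
    if decl.shape[0] == 0 or nodecl.shape[0] == 0:
        raise DataError("fold change needs both classes non-empty")
    num = decl.mean(axis=0)
    den = nodecl.mean(axis=0)
    fc = np.where(den == 0, np.nan, num / np.where(den == 0, 1.0, den))
    return pd.DataFrame(
        {
            "feature_id": block.feature_ids,
            "metabolite": [block.metabolite_of(f) for f in block.feature_ids],
            "mean_decline": num,
            "mean_no_decline": den,
            "fold_change": fc,
        }
    )
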