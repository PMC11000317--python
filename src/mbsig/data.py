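"""Core data containers: omics blocks, the sample table, and run configuration.

The central object is :class:`MultiBlockDataset` — two (or more) feature
blocks measured on the same samples (here an NMR bucket table and a lipid
intensity table) plus a clinical sample table carrying the two-class outcome
(cognitive decline vs no decline) and covariates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mbsig")

DECLINE = "Decline"
NO_DECLINE = "NoDecline"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class OmicsBlock:
    """One feature block: samples x features intensity matrix.

    Parameters
    ----------
    name : short label, e.g. ``"nmr"`` or ``"lipid"``.
    feature_ids : ordered unique feature labels. Chemical-shift strings such
        as ``"2.4237"`` and lipid names such as ``"d18.1_C26.0"`` are kept as
        opaque strings, never parsed as numbers.
    matrix : (n_samples, n_features) array of finite intensities/integrals.
    annotation : optional map feature_id -> metabolite name (several NMR
        buckets may map to the same metabolite).
    """

    name: str
    feature_ids: list[str]
    matrix: np.ndarray
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError(f"block {self.name!r}: duplicate feature ids")
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_ids):
            raise DataError(
                f"block {self.name!r}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.feature_ids)} feature ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise DataError(f"block {self.name!r}: non-finite values in matrix")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = None if sample_ids is None else pd.Index(sample_ids, name="sample_id")
        return pd.DataFrame(self.matrix, index=idx, columns=self.feature_ids)

    def metabolite_of(self, feature_id: str) -> str:
        """Metabolite-level label of a feature (the feature id itself when
        unannotated)."""
        return self.annotation.get(feature_id, feature_id)

    def subset_features(self, ids: Sequence[str]) -> "OmicsBlock":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise DataError(f"block {self.name!r}: unknown feature ids {missing}")
        cols = [pos[f] for f in ids]
        return OmicsBlock(
            self.name,
            list(ids),
            self.matrix[:, cols],
            {f: self.annotation[f] for f in ids if f in self.annotation},
        )


@dataclass
class SampleTable:
    """Per-sample clinical information.

    ``mmse_series`` holds per-sample ordered (time_in_years, score) pairs;
    scores live on the 0-30 MMSE scale. ``group`` is the two-level outcome
    (Decline / NoDecline) and may be absent until the decliner rule is applied.
    """

    sample_ids: list[str]
    group: pd.Series | None = None
    mmse_series: dict[str, list[tuple[float, float]]] | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise DataError(f"duplicated sample ids: {dupes}")
        if self.group is not None:
            self.group = pd.Series(self.group, index=pd.Index(self.sample_ids))
            levels = self.group.dropna().unique()
            if len(levels) > 2:
                raise DataError(
                    f"group must have at most two levels, found {sorted(map(str, levels))}"
                )
        if self.mmse_series is not None:
            for sid, series in self.mmse_series.items():
                for _, score in series:
                    if not (0.0 <= score <= 30.0):
                        raise DataError(
                            f"sample {sid!r}: MMSE score {score} outside [0, 30]"
                        )
        if self.covariates is not None:
            self.covariates = self.covariates.loc[list(self.sample_ids)]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_sizes(self) -> dict[str, int]:
        if self.group is None:
            raise DataError("no group labels present")
        return self.group.value_counts().to_dict()


@dataclass
class MultiBlockDataset:
    """Aligned per-sample blocks plus the sample table."""

    samples: SampleTable
    blocks: list[OmicsBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataError("at least one block required")
        n = self.samples.n_samples
        for b in self.blocks:
            if b.n_samples != n:
                raise DataError(
                    f"block {b.name!r} has {b.n_samples} rows, expected {n} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.n_samples

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def y(self) -> np.ndarray:
        """Outcome as 0/1 (1 = Decline); requires group labels."""
        if self.samples.group is None:
            raise DataError("class labels must be present before a supervised fit")
        return (self.samples.group.to_numpy() == DECLINE).astype(int)


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with the study's defaults.

    The hyperparameter grids follow the published tuning protocol: models with
    1-5 latent components; keepX grids of 1-9 (step 1) then 10-100 (step 5)
    for the NMR block and 1-9 (step 1) then 10-290 (step 5) for the lipid
    block; BER minimised by 4-fold CV inside each bootstrap replicate;
    single-block PLS-DA validity gated at Q2 > 0.4 from 7-fold CV.
    """

    seed: int = 0
    n_bootstrap: int = 100
    ncomp_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    keepx_grids: dict[str, tuple[int, ...]] | None = None
    cv_folds_tuning: int = 4
    cv_folds_plsda: int = 7
    q2_threshold: float = 0.4
    frequency_threshold: float = 0.60
    decline_threshold: int = 2
    normalize_blocks: tuple[str, ...] = ("nmr",)
    design_weight: float = 1.0
    sequential_keepx: bool = True

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if any(k < 1 for k in self.ncomp_grid):
            raise ValueError("ncomp_grid values must be >= 1")
        if not (0 < self.frequency_threshold <= 1):
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.cv_folds_tuning < 2 or self.cv_folds_plsda < 2:
            raise ValueError("CV folds must be >= 2")

    def keepx_grid_for(self, block: OmicsBlock) -> tuple[int, ...]:
        """keepX candidate list for a block, clipped to its feature count."""
        if self.keepx_grids and block.name in self.keepx_grids:
            grid = self.keepx_grids[block.name]
        else:
            grid = default_keepx_grid(block.n_features)
        bad = [k for k in grid if k < 1 or k > block.n_features]
        if bad:
            raise ValueError(
                f"keepX values {bad} outside [1, {block.n_features}] for block "
                f"{block.name!r}"
            )
        return tuple(grid)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ncomp_grid"] = list(self.ncomp_grid)
        return d


def default_keepx_grid(p: int) -> tuple[int, ...]:
    """The published keepX grid: 1-9 step 1, then 10-p step 5.

    For p = 100 this yields 28 candidates and for p = 290 it yields 66.
    """
    fine = [k for k in range(1, 10) if k <= p]
    coarse = [k for k in range(10, p + 1, 5)]
    return tuple(fine + coarse)


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype={0: str})


def read_sample_table(path: str | Path, delimiter: str | None = None) -> SampleTable:
    """Read the clinical sample CSV/TSV.

    Expected columns: optional ``group``; optional wide MMSE columns named
    ``mmse_<time>`` (time in years, e.g. ``mmse_0``, ``mmse_1``); everything
    else is treated as a covariate.
    """
    df = _read_table(path, delimiter)
    df.index = df.index.astype(str)
    group = None
    if "group" in df.columns:
        g = df["group"].dropna()
        if len(g) == len(df):
            group = df["group"].astype(str)
    mmse_cols = sorted(
        (c for c in df.columns if c.startswith("mmse_")),
        key=lambda c: float(c.split("_", 1)[1]),
    )
    mmse = None
    if mmse_cols:
        mmse = {}
        for sid, row in df[mmse_cols].iterrows():
            series = [
                (float(c.split("_", 1)[1]), float(v))
                for c, v in row.items()
                if pd.notna(v)
            ]
            mmse[str(sid)] = series
    cov_cols = [c for c in df.columns if c != "group" and not c.startswith("mmse_")]
    cov = df[cov_cols] if cov_cols else None
    return SampleTable(list(df.index), group=group, mmse_series=mmse, covariates=cov)


def read_block(
    path: str | Path,
    name: str,
    delimiter: str | None = None,
    transposed: bool = False,
    annotation_path: str | Path | None = None,
) -> OmicsBlock:
    """Read one block file (samples in rows by default; ``transposed=True``
    for features-in-rows exports)."""
    df = _read_table(path, delimiter)
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"block {name!r}: duplicated sample ids {dupes}")
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, col in enumerate(df.columns):
            colvals = pd.to_numeric(df[col], errors="coerce")
            if colvals.isna().any() and not df[col].isna().any():
                row = df.index[colvals.isna().argmax()]
                raise DataError(
                    f"block {name!r}: non-numeric cell at sample {row!r}, "
                    f"feature {col!r}"
                ) from None
        raise
    annotation: dict[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        annotation = dict(
            zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str))
        )
    block = OmicsBlock(name, [str(c) for c in df.columns], mat, annotation)
    block._sample_ids = list(df.index)  # type: ignore[attr-defined]
    return block


def read_dataset(
    block_paths: Mapping[str, str | Path],
    sample_path: str | Path,
    delimiter: str | None = None,
    transposed: bool = False,
    annotation_paths: Mapping[str, str | Path] | None = None,
) -> MultiBlockDataset:
    """Read block files plus the sample table and align everything to the
    sample-table order.

    Raises :class:`DataError` naming the offending sample when a block is
    missing a sample or carries an unknown one.
    """
    samples = read_sample_table(sample_path, delimiter)
    order = samples.sample_ids
    blocks = []
    for name, path in block_paths.items():
        ann = None if annotation_paths is None else annotation_paths.get(name)
        block = read_block(path, name, delimiter, transposed, ann)
        block_sids: list[str] = block._sample_ids  # type: ignore[attr-defined]
        missing = [s for s in order if s not in set(block_sids)]
        extra = [s for s in block_sids if s not in set(order)]
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing from block {name!r}: {missing}")
            if extra:
                parts.append(f"unknown to sample table in block {name!r}: {extra}")
            raise DataError("sample mismatch — " + "; ".join(parts))
        pos = {s: i for i, s in enumerate(block_sids)}
        block.matrix = block.matrix[[pos[s] for s in order]]
        blocks.append(block)
    logger.info(
        "read dataset: %d samples, blocks %s",
        len(order),
        {b.name: b.n_features for b in blocks},
    )
    return MultiBlockDataset(samples, blocks)
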