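"""Atlas ROI aggregation: voxel metric maps -> per-subject feature vectors.

A parcellation is an integer label volume (0 = background, 1..R regions).
Each region's feature is the arithmetic mean of the metric map over the
region's in-mask voxels; with the default 132-region atlas and the three
metrics this yields the 396-column cohort feature table used downstream.

Feature columns are named ``<metric>__<region_index>__<region_name>`` so that
selected-feature frequency reports are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .voxmetrics import VoxelMap

METRICS = ("fALFF", "LCOR", "ICC")

__all__ = [
    "Parcellation",
    "FeatureTable",
    "roi_means",
    "assemble_feature_table",
    "feature_name",
    "region_of_feature",
]


@dataclass
class Parcellation:
    """Integer label volume with region names; labels 1..R, 0 = background."""

    labels: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = np.unique(self.labels)
        present = present[present > 0]
        r = int(present.max()) if present.size else 0
        if r == 0:
            raise ValueError("atlas contains no region labels")
        missing = sorted(set(range(1, r + 1)) - set(int(p) for p in present))
        if missing:
            raise ValueError(f"atlas labels 1..{r} must all be present; missing {missing}")
        if not self.region_names:
            self.region_names = [f"region_{i:03d}" for i in range(1, r + 1)]
        if len(self.region_names) != r:
            raise ValueError(
                f"{len(self.region_names)} region names for {r} labels"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary labels (HC = 0, MCI = 1)."""

    data: pd.DataFrame  # index: subject ids; columns: feature names
    labels: pd.Series  # aligned to data.index, values in {0, 1}

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            missing = list(self.data.index[self.labels.isna()])
            raise ValueError(f"label missing for subject(s) {missing}")
        self.labels = self.labels.astype(int)
        if set(self.labels.unique()) != {0, 1}:
            raise ValueError("labels must contain both classes (0 = HC, 1 = MCI)")
        self.data.index.name = "subject_id"
        self.labels.index.name = "subject_id"
        const = self.data.columns[self.data.nunique() <= 1]
        self.constant_columns = list(const)

    @property
    def x(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="subject_id")
        labels = frame.pop("label")
        return cls(data=frame, labels=labels)


def feature_name(metric: str, region_index: int, region_name: str) -> str:
    return f"{metric}__{region_index:03d}__{region_name}"


def region_of_feature(name: str) -> int:
    """Region index (1-based) encoded in a feature name."""
    return int(str(name).split("__")[1])


def roi_means(vmap: VoxelMap, atlas: Parcellation) -> pd.Series:
    """Per-region mean of an in-mask metric map; errors on empty regions."""
    if vmap.values.shape != atlas.labels.shape:
        raise ValueError(
            f"map grid {vmap.values.shape} does not match atlas grid {atlas.labels.shape}"
        )
    r = atlas.n_regions
    labels = atlas.labels[vmap.mask]
    values = vmap.values[vmap.mask]
    keep = labels > 0
    counts = np.bincount(labels[keep], minlength=r + 1)[1:]
    empty = np.nonzero(counts == 0)[0] + 1
    if empty.size:
        raise ValueError(
            f"region(s) {[int(e) for e in empty]} have no in-mask voxels; cannot take ROI means"
        )
    sums = np.bincount(labels[keep], weights=values[keep], minlength=r + 1)[1:]
    means = sums / counts
    names = [feature_name(vmap.metric, i + 1, atlas.region_names[i]) for i in range(r)]
    return pd.Series(means, index=names, name=vmap.metric)


def assemble_feature_table(
    subject_maps: dict[str, dict[str, VoxelMap]],
    atlas: Parcellation,
    labels: dict[str, int] | pd.Series,
    metrics: tuple[str, ...] = METRICS,
) -> FeatureTable:
    """Build the cohort table from per-subject {metric: VoxelMap} dicts.

    Rows are ordered by subject id; columns metric-major then region index,
    so three metrics over a 132-region atlas give exactly 396 columns.
    """
    if not metrics:
        raise ValueError("at least one metric required")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metric(s) {sorted(unknown)}")
    labels = pd.Series(labels)
    rows = {}
    for sid in sorted(subject_maps):
        if sid not in labels.index:
            raise ValueError(f"label missing for subject {sid!r}")
        parts = []
        for metric in metrics:
            if metric not in subject_maps[sid]:
                raise ValueError(f"subject {sid!r} lacks a {metric} map")
            parts.append(roi_means(subject_maps[sid][metric], atlas))
        rows[sid] = pd.concat(parts)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.sort_index()
    return FeatureTable(data=frame, labels=labels.loc[frame.index])
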