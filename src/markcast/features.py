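"""Binary overlap featurization of labeled region sets.

A region's feature vector records, per peak dataset, the presence (1) or
absence (0) of an overlapping peak — the featurization used when asking
whether histone marks observed in one cellular context carry information
about regulatory activity in another. Features are deliberately binary:
no coverage fractions, no signal strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EvaluationError, SelectionError
from .intervals import RegionSet, overlap_flags
from .manifest import ContextMeta


@dataclass
class LabeledFeatureMatrix:
    """Binary region x dataset overlap matrix with 0/1 activity labels.

    Rows follow region order (positives then negatives, as built);
    columns follow manifest order. ``meta[j]`` describes column
    ``dataset_ids[j]``.
    """

    region_ids: list[str]
    features: np.ndarray  # uint8, shape (n_regions, n_datasets)
    labels: np.ndarray  # uint8, shape (n_regions,)
    dataset_ids: list[str]
    meta: list[ContextMeta]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        n, m = self.features.shape
        if not set(np.unique(self.features)) <= {0, 1}:
            raise ValueError("feature entries must be 0/1")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if n != len(self.region_ids) or n != len(self.labels):
            raise ValueError("row count mismatch between ids, features, labels")
        if m != len(self.dataset_ids) or m != len(self.meta):
            raise ValueError("column count mismatch between ids and meta")

    @property
    def n_regions(self) -> int:
        return self.features.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.features.shape[1]

    def require_two_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise EvaluationError("labels must contain both classes")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, index=self.region_ids, columns=self.dataset_ids
        )
        df.insert(0, "label", self.labels)
        df.index.name = "region_id"
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, meta: Sequence[ContextMeta]) -> "LabeledFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        labels = df.pop("label").to_numpy()
        by_id = {m.dataset_id: m for m in meta}
        try:
            col_meta = [by_id[c] for c in df.columns]
        except KeyError as e:
            raise ConfigurationError(f"dataset {e} missing from manifest") from None
        return cls(
            [str(i) for i in df.index],
            df.to_numpy(),
            labels,
            list(df.columns),
            col_meta,
        )


def _region_id(r, fallback: str) -> str:
    return r.name if r.name is not None else fallback


def build_feature_matrix(
    positives: RegionSet,
    negatives: RegionSet,
    peak_sets: Mapping[str, RegionSet],
    meta: Sequence[ContextMeta],
    min_bp: int = 1,
) -> LabeledFeatureMatrix:
    """Overlap-featurize positives (label 1) and negatives (label 0).

    Cell ``(r, c)`` is 1 iff region ``r`` overlaps dataset ``c``'s peaks
    by at least ``min_bp`` bases. Row order is positives then negatives;
    column order is manifest order. A dataset listed in ``meta`` but
    absent from ``peak_sets`` is a configuration error; an empty peak set
    yields an all-zero column, which is retained.
    """
    missing = [m.dataset_id for m in meta if m.dataset_id not in peak_sets]
    if missing:
        raise ConfigurationError(f"peak sets missing for datasets: {missing}")
    regions = list(positives) + list(negatives)
    region_ids = [
        _region_id(r, f"{'pos' if i < len(positives) else 'neg'}_{i}")
        for i, r in enumerate(regions)
    ]
    cols = []
    for m in meta:
        cols.append(overlap_flags(regions, peak_sets[m.dataset_id], min_bp=min_bp))
    features = (
        np.column_stack(cols).astype(np.uint8)
        if cols
        else np.zeros((len(regions), 0), dtype=np.uint8)
    )
    labels = np.concatenate(
        [np.ones(len(positives), dtype=np.uint8),
         np.zeros(len(negatives), dtype=np.uint8)]
    )
    return LabeledFeatureMatrix(
        region_ids, features, labels, [m.dataset_id for m in meta], list(meta)
    )


def select_features(
    matrix: LabeledFeatureMatrix, predicate: Callable[[ContextMeta], bool]
) -> LabeledFeatureMatrix:
    """Restrict to columns whose :class:`ContextMeta` satisfies ``predicate``.

    Rows and labels are unchanged; raises :class:`SelectionError` if no
    column matches.
    """
    keep = [j for j, m in enumerate(matrix.meta) if predicate(m)]
    if not keep:
        raise SelectionError("feature predicate matched no columns")
    return LabeledFeatureMatrix(
        list(matrix.region_ids),
        matrix.features[:, keep],
        matrix.labels.copy(),
        [matrix.dataset_ids[j] for j in keep],
        [matrix.meta[j] for j in keep],
    )
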