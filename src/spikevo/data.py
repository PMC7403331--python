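"""Tabular dataset loading, splitting and synthetic generation.

Handles UCI-style CSV tables (numeric feature columns, one label column,
``?`` as the conventional missing marker), stratified train/test splits,
and a synthetic Gaussian-cluster generator so the whole pipeline can be
exercised offline.  The generator's defaults mirror an Iris-shaped
problem: 3 classes x 50 instances, 4 features, well-separated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = ["TabularDataset", "SplitSpec", "load_csv", "split", "make_synthetic"]


@dataclass
class TabularDataset:
    """Numeric feature matrix plus class labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list
    class_names: list

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on instance count")
        if len(self.class_names) < 2:
            raise ValueError("need at least two classes")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split request: a fraction or explicit counts."""

    train_fraction: float | None = 0.5
    train_count: int | None = None
    test_count: int | None = None
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.train_fraction is None and self.train_count is None:
            raise ValueError("give either train_fraction or train_count")
        if self.train_fraction is not None and not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def load_csv(
    path,
    label_column: str,
    missing_markers=("?",),
    missing_policy: str = "drop",
) -> TabularDataset:
    """Load a UCI-style CSV with a header row.

    Cells equal to any ``missing_markers`` entry are treated as missing;
    rows containing missing features are dropped (default) or imputed with
    the column median.  Any other non-numeric cell raises with its
    row/column location.
    """
    if missing_policy not in ("drop", "impute"):
        raise ValueError("missing_policy must be 'drop' or 'impute'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
    feature_names = [c for c in df.columns if c != label_column]
    raw = df[feature_names].replace(list(missing_markers), np.nan)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"unparseable cell {raw.iloc[r, c]!r} at row {r}, column {feature_names[c]!r}"
        )
    labels = df[label_column].values
    x = numeric.values
    missing_row = np.isnan(x).any(axis=1)
    if missing_policy == "drop":
        x, labels = x[~missing_row], labels[~missing_row]
    else:
        medians = np.nanmedian(x, axis=0)
        idx = np.argwhere(np.isnan(x))
        x[idx[:, 0], idx[:, 1]] = medians[idx[:, 1]]
    return TabularDataset(
        features=x,
        labels=labels,
        feature_names=feature_names,
        class_names=sorted(pd.unique(labels)),
    )


def split(dataset: TabularDataset, spec: SplitSpec) -> tuple[TabularDataset, TabularDataset]:
    """Deterministic (seeded) train/test split, stratified by default."""
    n = dataset.n_instances
    if spec.train_count is not None:
        train_size = spec.train_count
        test_size = spec.test_count if spec.test_count is not None else n - train_size
        if train_size + test_size > n:
            raise ValueError(
                f"requested {train_size}+{test_size} instances but the dataset has {n}"
            )
    else:
        train_size = spec.train_fraction
        test_size = None
    stratify = dataset.labels if spec.stratified else None
    x_tr, x_te, y_tr, y_te = train_test_split(
        dataset.features,
        dataset.labels,
        train_size=train_size,
        test_size=test_size,
        stratify=stratify,
        random_state=spec.seed,
    )
    make = lambda x, y: TabularDataset(x, y, dataset.feature_names, dataset.class_names)
    return make(x_tr, y_tr), make(x_te, y_te)


def make_synthetic(
    n_per_class: int = 50,
    k_classes: int = 3,
    n_features: int = 4,
    class_separation: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TabularDataset:
    """Gaussian class clusters emulating a small UCI-style table.

    Class c's mean sits at c * class_separation on every feature axis, with
    isotropic noise of standard deviation ``noise_sd``; separation well
    above the noise gives linearly separable clusters, separation 0 makes
    the classes indistinguishable.  Labels are integers 1..k.
    """
    if k_classes < 2:
        raise ValueError("need at least two classes")
    if n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c in range(k_classes):
        mean = np.full(n_features, c * class_separation, dtype=float)
        blocks.append(rng.normal(mean, noise_sd, size=(n_per_class, n_features)))
        labels.extend([c + 1] * n_per_class)
    return TabularDataset(
        features=np.vstack(blocks),
        labels=np.array(labels),
        feature_names=[f"feature_{i + 1}" for i in range(n_features)],
        class_names=list(range(1, k_classes + 1)),
    )
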