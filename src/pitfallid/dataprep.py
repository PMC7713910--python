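"""Rare-species filtering, repeated train/test splits, and standardization.

The preparation protocol: species with too few observations to train on
(<= 30 by default) are set aside as "novel" species; the remaining table is
split 70:30 into train/test, repeated 10 times with simple (non-stratified)
random sampling; features are z-scored using means and standard deviations
fit on the training rows of each split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .manifest import feature_names


class DataPrepError(ValueError):
    pass


def filter_rare(
    table: pd.DataFrame, min_obs: int = 31
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a feature table into (common, rare) by species count.

    Species with fewer than ``min_obs`` observations (i.e. <= 30 under the
    default) go to the rare partition; the partition is exhaustive and
    disjoint.
    """
    counts = table["species"].value_counts()
    common_species = set(counts[counts >= min_obs].index)
    is_common = table["species"].isin(common_species)
    common = table[is_common].reset_index(drop=True)
    rare = table[~is_common].reset_index(drop=True)
    if common.empty:
        raise DataPrepError(
            f"no species reaches {min_obs} observations; nothing trainable"
        )
    return common, rare


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring with train-only statistics.

    Like sklearn's StandardScaler but with the sample (ddof=1) standard
    deviation and an explicit rule for constant features: they pass through
    centered, with the scale treated as 1 (and a warning), so downstream
    models never divide by zero.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureStandardizer":
        cols = self.columns or feature_names()
        self.columns_ = list(cols)
        vals = X[self.columns_].to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1) if len(vals) > 1 else np.zeros(vals.shape[1])
        zero = sd == 0
        if zero.any():
            bad = [c for c, z in zip(self.columns_, zero) if z]
            warnings.warn(
                f"constant feature(s) {bad[:5]}; centered only", stacklevel=2
            )
            sd = np.where(zero, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        out = X.copy()
        vals = out[self.columns_].to_numpy(dtype=float)
        out[self.columns_] = (vals - self.mean_) / self.scale_
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        out = X.copy()
        vals = out[self.columns_].to_numpy(dtype=float)
        out[self.columns_] = vals * self.scale_ + self.mean_
        return out


@dataclass
class SplitSet:
    """One train/test repeat, optionally standardized."""

    repeat_index: int
    train: pd.DataFrame
    test: pd.DataFrame
    standardizer: FeatureStandardizer | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def standardized(self) -> bool:
        return self.standardizer is not None


def make_splits(
    table: pd.DataFrame,
    ratio: float = 0.7,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[SplitSet]:
    """Repeated simple-random 70:30 splits (seeded, reproducible).

    Sampling is deliberately non-stratified, so the species composition of
    each training subset varies between repeats; a species missing entirely
    from some training subset is recorded as a warning, not an error.
    """
    if table.empty:
        raise DataPrepError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = int(round(ratio * n))
    splits = []
    for rep in range(1, n_repeats + 1):
        perm = rng.permutation(n)
        train = table.iloc[perm[:n_train]].reset_index(drop=True)
        test = table.iloc[perm[n_train:]].reset_index(drop=True)
        split = SplitSet(repeat_index=rep, train=train, test=test)
        missing = set(table["species"]) - set(train["species"])
        if missing:
            msg = f"repeat {rep}: species absent from training: {sorted(missing)}"
            split.notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        splits.append(split)
    return splits


def standardize(split: SplitSet, fit_on: str = "train") -> SplitSet:
    """Z-score a split's features; statistics from training rows only.

    ``fit_on="pooled"`` fits the statistics on train and test combined — a
    fidelity mode for protocols that standardized before evaluating — and is
    mild leakage, so the default is train-only.
    """
    if fit_on not in ("train", "pooled"):
        raise DataPrepError("fit_on must be 'train' or 'pooled'")
    scaler = FeatureStandardizer()
    ref = split.train if fit_on == "train" else pd.concat([split.train, split.test])
    scaler.fit(ref)
    return SplitSet(
        repeat_index=split.repeat_index,
        train=scaler.transform(split.train),
        test=scaler.transform(split.test),
        standardizer=scaler,
        notes=list(split.notes),
    )
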