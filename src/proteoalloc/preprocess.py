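"""Differential-expression preprocessing: valid-value filtering, log2
transform, and limit-of-detection (downshifted-normal) imputation.

The stages are scikit-learn transformers operating on a proteins x samples
:class:`pandas.DataFrame` with ``NaN`` for non-detections, so they compose
with sklearn pipelines; module-level functions wrap them for one-shot use.

Imputation models censoring at the mass spectrometer's detection limit:
missing values in each sample column are drawn from a normal distribution
narrowed to ``width_fraction * sigma`` and shifted ``downshift_sd * sigma``
below the column's observed mean — the convention of mainstream label-free
post-processing tools (defaults 0.3 and 1.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import SampleDesign

__all__ = [
    "MinValidFilter",
    "Log2Transformer",
    "DownshiftedNormalImputer",
    "filter_min_valid",
    "log2_transform",
    "impute_downshifted",
]


class MinValidFilter(BaseEstimator, TransformerMixin):
    """Remove proteins with too few valid (non-missing) values per group.

    Parameters
    ----------
    design : SampleDesign
        Sample-to-condition assignment.
    min_frac : float, default 0.70
        Minimum fraction of valid values required in a condition group.
    mode : {"all", "any"}, default "all"
        "all": the fraction must be met in **every** group ("at least 70%
        valid values in each group"); "any": in at least one group.

    Attributes
    ----------
    retained_ids_ : list of protein ids surviving the filter (input order).
    removed_ids_ : list of protein ids removed.
    """

    def __init__(self, design: SampleDesign, min_frac: float = 0.70, mode: str = "all"):
        self.design = design
        self.min_frac = min_frac
        self.mode = mode

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError(f"min_frac must be in [0, 1], got {self.min_frac}")
        if self.mode not in ("all", "any"):
            raise ValueError(f"mode must be 'all' or 'any', got {self.mode!r}")
        self.design.check_matches(X)
        per_group_ok = []
        for _, samples in self.design.groups().items():
            frac = X[samples].notna().mean(axis=1)
            per_group_ok.append(frac >= self.min_frac)
        ok_frame = pd.concat(per_group_ok, axis=1)
        keep = ok_frame.all(axis=1) if self.mode == "all" else ok_frame.any(axis=1)
        self.retained_ids_ = list(X.index[keep])
        self.removed_ids_ = list(X.index[~keep])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.retained_ids_]


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Elementwise log2; zeros become missing (log undefined at 0)."""

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        values = X.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("log2 transform requires non-negative abundances")
        with np.errstate(divide="ignore"):
            out = np.log2(values)
        out[values == 0] = np.nan
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class DownshiftedNormalImputer(BaseEstimator, TransformerMixin):
    """Impute missing log2 values from a downshifted, narrowed normal.

    Per sample column with observed mean ``mu`` and sample sd ``sigma``
    (ddof=1), each missing cell is replaced by a draw from
    ``Normal(mu - downshift_sd * sigma, (width_fraction * sigma)^2)``.
    Valid cells are never altered; the draws are fully determined by
    ``random_state``.

    Attributes
    ----------
    column_means_, column_sds_ : pandas.Series indexed by sample id.
    """

    def __init__(
        self,
        width_fraction: float = 0.3,
        downshift_sd: float = 1.8,
        random_state: int | None = 0,
    ):
        self.width_fraction = width_fraction
        self.downshift_sd = downshift_sd
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.width_fraction <= 0:
            raise ValueError("width_fraction must be > 0")
        if self.downshift_sd < 0:
            raise ValueError("downshift_sd must be >= 0")
        n_valid = X.notna().sum(axis=0)
        too_few = n_valid[n_valid < 2]
        if len(too_few):
            raise ValueError(
                "cannot estimate imputation distribution: fewer than 2 valid "
                f"values in sample(s) {list(too_few.index)}"
            )
        self.column_means_ = X.mean(axis=0, skipna=True)
        self.column_sds_ = X.std(axis=0, skipna=True, ddof=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.random_state)
        out = X.to_numpy(dtype=float).copy()
        for j, sample in enumerate(X.columns):
            mask = np.isnan(out[:, j])
            n_missing = int(mask.sum())
            if n_missing == 0:
                continue
            mu = self.column_means_[sample] - self.downshift_sd * self.column_sds_[sample]
            sd = self.width_fraction * self.column_sds_[sample]
            out[mask, j] = rng.normal(mu, sd, size=n_missing)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def filter_min_valid(
    matrix: pd.DataFrame,
    design: SampleDesign,
    min_frac: float = 0.70,
    mode: str = "all",
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the min-valid-fraction filter; returns (filtered, removed_ids)."""
    f = MinValidFilter(design, min_frac=min_frac, mode=mode).fit(matrix)
    return f.transform(matrix), f.removed_ids_


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    return Log2Transformer().fit_transform(matrix)


def impute_downshifted(
    logmatrix: pd.DataFrame,
    width_fraction: float = 0.3,
    downshift_sd: float = 1.8,
    seed: int | None = 0,
) -> pd.DataFrame:
    imp = DownshiftedNormalImputer(
        width_fraction=width_fraction, downshift_sd=downshift_sd, random_state=seed
    )
    return imp.fit_transform(logmatrix)
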