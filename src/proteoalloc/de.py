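"""Differential protein expression: pooled-variance t-tests, one-way ANOVA,
Benjamini-Hochberg FDR, regulation calls, presence calls and overlap counts.

Conventions for degenerate proteins (possible after imputation of nearly
constant columns, and routine in unit fixtures):

* zero pooled variance and zero mean difference -> p = 1 (no evidence);
* zero pooled variance but a nonzero difference -> p = 0 with a warning
  (infinitely strong evidence under the model; flagged because it usually
  means a constant fixture rather than real data).

Regulation calls use strict inequalities: UP means log2FC > fc_thresh and
p < p_thresh; DOWN is the mirror image; everything else is NS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .model import SampleDesign

__all__ = [
    "TwoGroupDifferential",
    "two_group_ttest",
    "anova_multi",
    "adjust_bh",
    "call_regulation",
    "differential_expression",
    "presence_call",
    "overlap_counts",
    "OverlapCounts",
]


def _group_values(
    logmatrix: pd.DataFrame, design: SampleDesign, group: str
) -> np.ndarray:
    samples = design.samples_for(group)  # raises KeyError on unknown label
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    values = logmatrix[samples].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "matrix contains missing values; impute before testing"
        )
    return values


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided pooled-variance Student t over matrix rows.

    Returns (t, p).  Degenerate rows follow the module conventions.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss1 = ((a - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((b - m2[:, None]) ** 2).sum(axis=1)
    # constant groups have exactly zero variance (the mean of n identical
    # floats need not be bitwise equal to them)
    ss1[np.ptp(a, axis=1) == 0] = 0.0
    ss2[np.ptp(b, axis=1) == 0] = 0.0
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df
    diff = m2 - m1
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.empty_like(diff)
    ok = se > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    zero_diff = ~ok & (diff == 0)
    p[zero_diff] = 1.0
    t[zero_diff] = 0.0
    zero_var = ~ok & (diff != 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} protein(s) have zero pooled variance with a "
            "nonzero mean difference; reporting p = 0",
            stacklevel=3,
        )
        p[zero_var] = 0.0
        t[zero_var] = np.sign(diff[zero_var]) * np.inf
    return t, p


def two_group_ttest(
    logmatrix: pd.DataFrame,
    design: SampleDesign,
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Per-protein two-sided pooled-variance t-test between two conditions.

    log2 fold change is mean(group2) - mean(group1) in log2 space, i.e.
    group2-over-group1.  Returns columns mean_g1, mean_g2, log2fc, t, p_value.
    """
    a = _group_values(logmatrix, design, group1)
    b = _group_values(logmatrix, design, group2)
    t, p = _pooled_t(a, b)
    return pd.DataFrame(
        {
            "mean_g1": a.mean(axis=1),
            "mean_g2": b.mean(axis=1),
            "log2fc": b.mean(axis=1) - a.mean(axis=1),
            "t": t,
            "p_value": p,
        },
        index=logmatrix.index,
    )


def anova_multi(
    logmatrix: pd.DataFrame,
    design: SampleDesign,
    groups: list[str],
) -> pd.Series:
    """One-way fixed-effects ANOVA p-value per protein over >= 3 groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use the t-test for 2")
    blocks = [_group_values(logmatrix, design, g) for g in groups]
    all_values = np.concatenate(blocks, axis=1)
    n_total = all_values.shape[1]
    k = len(blocks)
    grand = all_values.mean(axis=1)
    ssb = np.zeros(len(logmatrix))
    ssw = np.zeros(len(logmatrix))
    for block in blocks:
        m = block.mean(axis=1)
        ssb += block.shape[1] * (m - grand) ** 2
        block_ss = ((block - m[:, None]) ** 2).sum(axis=1)
        block_ss[np.ptp(block, axis=1) == 0] = 0.0
        ssw += block_ss
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = np.empty(len(logmatrix))
    ok = ssw > 0
    p[ok] = stats.f.sf(f[ok], df_b, df_w)
    p[~ok & (ssb == 0)] = 1.0
    zero_var = ~ok & (ssb > 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} protein(s) have zero within-group variance "
            "with differing means; reporting p = 0",
            stacklevel=2,
        )
        p[zero_var] = 0.0
    return pd.Series(p, index=logmatrix.index, name="p_value")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_regulation(
    result: pd.DataFrame, fc_thresh: float = 1.0, p_thresh: float = 0.05
) -> pd.Series:
    """UP/DOWN/NS calls from log2fc and p_value columns (strict thresholds)."""
    fc = result["log2fc"].to_numpy(dtype=float)
    p = result["p_value"].to_numpy(dtype=float)
    call = np.where(
        (fc > fc_thresh) & (p < p_thresh),
        "UP",
        np.where((fc < -fc_thresh) & (p < p_thresh), "DOWN", "NS"),
    )
    return pd.Series(call, index=result.index, name="call")


class TwoGroupDifferential(BaseEstimator):
    """Two-condition differential-expression analysis as an estimator.

    ``fit`` runs the pooled t-test on a complete log2 matrix, BH-adjusts the
    p-values within this comparison, and attaches regulation calls.

    Attributes
    ----------
    results_ : DataFrame with columns mean_g1, mean_g2, log2fc, t, p_value,
        q_value, call (one row per protein).
    """

    def __init__(
        self,
        design: SampleDesign,
        group1: str,
        group2: str,
        fc_thresh: float = 1.0,
        p_thresh: float = 0.05,
    ):
        self.design = design
        self.group1 = group1
        self.group2 = group2
        self.fc_thresh = fc_thresh
        self.p_thresh = p_thresh

    def fit(self, X: pd.DataFrame, y=None):
        res = two_group_ttest(X, self.design, self.group1, self.group2)
        res["q_value"] = adjust_bh(res["p_value"].to_numpy())
        res["call"] = call_regulation(res, self.fc_thresh, self.p_thresh)
        self.results_ = res
        return self


def differential_expression(
    logmatrix: pd.DataFrame,
    design: SampleDesign,
    group1: str,
    group2: str,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """One-shot wrapper around :class:`TwoGroupDifferential`."""
    est = TwoGroupDifferential(design, group1, group2, fc_thresh, p_thresh)
    return est.fit(logmatrix).results_


def presence_call(
    matrix: pd.DataFrame,
    design: SampleDesign,
    presence_min_frac: float = 0.70,
) -> pd.DataFrame:
    """Per-protein detection status per condition on the raw matrix.

    A protein is detected in a condition when its valid-value fraction
    there is >= ``presence_min_frac``.  The uniqueness column labels each
    protein ``unique:<condition>`` (detected in exactly one condition),
    ``shared`` (several), or ``absent`` (none).
    """
    design.check_matches(matrix)
    out = pd.DataFrame(index=matrix.index)
    detected_in: list[str] = []
    for condition, samples in design.groups().items():
        frac = matrix[samples].notna().mean(axis=1)
        out[f"valid_fraction_{condition}"] = frac
        out[f"detected_{condition}"] = frac >= presence_min_frac
        detected_in.append(condition)
    det_cols = out[[f"detected_{c}" for c in detected_in]].to_numpy()
    n_det = det_cols.sum(axis=1)
    labels = np.where(n_det == 0, "absent", np.where(n_det > 1, "shared", ""))
    only = np.argmax(det_cols, axis=1)
    uniq = n_det == 1
    labels = labels.astype(object)
    labels[uniq] = [f"unique:{detected_in[j]}" for j in only[uniq]]
    out["uniqueness"] = labels
    return out


@dataclass(frozen=True)
class OverlapCounts:
    n_common_up: int
    n_common_down: int
    n_up_a: int
    n_up_b: int
    n_down_a: int
    n_down_b: int


def overlap_counts(calls_a: pd.Series, calls_b: pd.Series) -> OverlapCounts:
    """Counts of commonly UP and commonly DOWN proteins across two comparisons."""
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("regulation calls cover different protein universes")
    calls_b = calls_b.reindex(calls_a.index)
    up_a, up_b = calls_a == "UP", calls_b == "UP"
    dn_a, dn_b = calls_a == "DOWN", calls_b == "DOWN"
    return OverlapCounts(
        n_common_up=int((up_a & up_b).sum()),
        n_common_down=int((dn_a & dn_b).sum()),
        n_up_a=int(up_a.sum()),
        n_up_b=int(up_b.sum()),
        n_down_a=int(dn_a.sum()),
        n_down_b=int(dn_b.sum()),
    )
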