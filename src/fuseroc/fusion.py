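"""Score-level (late) fusion of the two modality scores.

Each modality's continuous suspicion scores are min–max normalized to [0, 1]
over the analyzed cohort, then combined case-wise as

    fused = w * norm_dm + (1 - w) * norm_abus,

and the fusion weight ``w`` is selected by exhaustive grid search
(default 0.01 ... 0.99 in steps of 0.01) maximizing the empirical AUC of the
fused score against the malignant-vs-rest labels.  The selection is
in-sample: normalization bounds and the argmax weight are taken on the
cohort being analyzed, with no train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import roc
from .cohort import validate_case_table

__all__ = ["FusionResult", "minmax_normalize", "fuse", "weight_sweep"]


@dataclass(frozen=True)
class FusionResult:
    """AUC profile over the fusion-weight grid and the selected optimum."""

    weight_grid: np.ndarray
    auc_by_weight: np.ndarray
    optimal_weight_dm: float
    optimal_weight_abus: float
    fused_scores: np.ndarray
    auc_at_optimum: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"weight_dm": self.weight_grid, "auc": self.auc_by_weight})


def minmax_normalize(scores, name: str = "scores") -> np.ndarray:
    """Affine map of a score vector onto [0, 1] (min -> 0, max -> 1).

    Order-preserving, hence AUC-invariant.  A constant vector has no
    defined normalization and raises a ValueError naming the input.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError(f"cannot min-max normalize constant vector {name!r}")
    return (scores - lo) / (hi - lo)


def fuse(norm_dm, norm_abus, w_dm: float) -> np.ndarray:
    """Case-wise weighted average of the two normalized modality scores."""
    norm_dm = np.asarray(norm_dm, dtype=float)
    norm_abus = np.asarray(norm_abus, dtype=float)
    if norm_dm.shape != norm_abus.shape:
        raise ValueError(
            f"modality score vectors must be aligned (got {norm_dm.shape} vs {norm_abus.shape})"
        )
    if not 0.0 <= w_dm <= 1.0:
        raise ValueError(f"w_dm must lie in [0, 1], got {w_dm}")
    return w_dm * norm_dm + (1.0 - w_dm) * norm_abus


def weight_sweep(
    cases: pd.DataFrame,
    grid_start: float = 0.01,
    grid_stop: float = 0.99,
    grid_step: float = 0.01,
) -> FusionResult:
    """Evaluate fused AUC at every grid weight and select the argmax.

    Ties in AUC are broken toward the weight closest to 0.5, then the
    smaller weight.  Returns the full (weight, AUC) profile for plotting
    plus the fused scores at the optimum.
    """
    validate_case_table(cases)
    labels = roc.binary_labels(cases)
    norm_dm = minmax_normalize(cases["score_dm"].to_numpy(), name="score_dm")
    norm_abus = minmax_normalize(cases["score_abus"].to_numpy(), name="score_abus")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("weight sweep requires both malignant and non-malignant cases")

    grid = np.round(np.arange(grid_start, grid_stop + grid_step / 2, grid_step), 10)
    if len(grid) == 0:
        raise ValueError("empty weight grid")
    fused_all = grid[:, None] * norm_dm[None, :] + (1.0 - grid[:, None]) * norm_abus[None, :]
    ranks = rankdata(fused_all, axis=1)
    aucs = (ranks[:, labels == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    best = aucs.max()
    candidates = np.flatnonzero(aucs >= best - 1e-12)
    i = min(candidates, key=lambda k: (abs(grid[k] - 0.5), grid[k]))
    w = float(grid[i])
    return FusionResult(
        weight_grid=grid,
        auc_by_weight=aucs,
        optimal_weight_dm=w,
        optimal_weight_abus=1.0 - w,
        fused_scores=fuse(norm_dm, norm_abus, w),
        auc_at_optimum=float(aucs[i]),
    )
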