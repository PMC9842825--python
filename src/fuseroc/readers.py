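"""Simulated radiologist reading strategies on ordinal BI-RADS columns.

Three strategies are evaluated against the malignant-vs-rest truth:

* ``single`` — one reader; a case is recalled iff its BI-RADS category is at
  or above the recall threshold;
* ``pair_either_recall`` — double reading in which either reader's recall
  recalls the case (element-wise OR of the two recall vectors);
* ``panel_majority`` — a four-reader panel whose consensus BI-RADS category
  is the majority vote, then thresholded.

Majority voting on 4 readers is under-determined by "majority" alone; the
rules here are: a category held by a strict majority (>= 3 of 4) wins; the
modal category wins a 2-1-1 split; a 2-2 split between two categories goes
to the more suspicious of the two; with four distinct categories the more
suspicious member of the median pair is taken (screening-conservative
tie-breaking throughout).  The consensus is always one of the input
categories and is invariant to reader order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import roc
from .cohort import BIRADS_CATEGORIES, CATEGORY_RANK, validate_case_table

__all__ = [
    "RecallRule",
    "PanelResult",
    "STRATEGIES",
    "recall_vector",
    "pair_either_recall",
    "panel_majority",
    "evaluate_strategy",
    "strategy_table",
]

STRATEGIES = ("single", "pair_either_recall", "panel_majority")


@dataclass(frozen=True)
class RecallRule:
    """Recall iff BI-RADS category >= threshold in the order 1<2<3<4a<4b<4c<5.

    Default threshold is category 3: everything not clearly negative/benign
    triggers workup, consistent with high-sensitivity screening readers.
    """

    threshold_category: str = "3"

    def __post_init__(self) -> None:
        if self.threshold_category not in CATEGORY_RANK:
            raise ValueError(
                f"unknown BI-RADS category {self.threshold_category!r}; "
                f"expected one of {list(BIRADS_CATEGORIES)}"
            )

    @property
    def threshold_rank(self) -> int:
        return CATEGORY_RANK[self.threshold_category]


@dataclass(frozen=True)
class PanelResult:
    """Operating point of one reading strategy, with bootstrap CIs."""

    strategy: str
    readers_used: tuple[str, ...]
    rule: RecallRule
    sensitivity: float
    specificity: float
    ci_sensitivity: roc.IntervalEstimate | None = None
    ci_specificity: roc.IntervalEstimate | None = None


def _ranks(categories: Sequence[str]) -> np.ndarray:
    cats = np.asarray(categories, dtype=object)
    ranks = np.empty(len(cats), dtype=int)
    for i, c in enumerate(cats):
        c = str(c)
        if c not in CATEGORY_RANK:
            raise ValueError(f"unknown BI-RADS category {c!r}")
        ranks[i] = CATEGORY_RANK[c]
    return ranks


def recall_vector(categories: Sequence[str], rule: RecallRule = RecallRule()) -> np.ndarray:
    """Binary recall decisions: 1 iff category >= the rule's threshold."""
    return (_ranks(categories) >= rule.threshold_rank).astype(int)


def pair_either_recall(recalls_a, recalls_b) -> np.ndarray:
    """Double-reading combination: a case is recalled if either reader recalls it."""
    a = np.asarray(recalls_a).astype(bool)
    b = np.asarray(recalls_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"recall vectors must be aligned (got {a.shape} vs {b.shape})")
    return (a | b).astype(int)


def panel_majority(categories_by_reader: Sequence[Sequence[str]]) -> np.ndarray:
    """Consensus BI-RADS category of a four-reader panel by majority vote.

    See the module docstring for the tie-breaking rules.  Exactly four
    reader vectors are required.
    """
    if len(categories_by_reader) != 4:
        raise ValueError(
            f"panel_majority requires exactly 4 reader vectors, got {len(categories_by_reader)}"
        )
    ranks = np.stack([_ranks(col) for col in categories_by_reader], axis=1)
    s = np.sort(ranks, axis=1)  # s0 <= s1 <= s2 <= s3 per case
    out = np.where(
        s[:, 1] == s[:, 2],
        s[:, 1],  # strict majority, or the pair sits in the middle
        np.where(
            (s[:, 0] == s[:, 1]) & (s[:, 2] == s[:, 3]),
            s[:, 2],  # 2-2 split: more suspicious pair
            np.where(
                s[:, 0] == s[:, 1],
                s[:, 0],  # lone pair at the bottom (2-1-1)
                s[:, 2],  # lone pair at the top, or four distinct: median pair's upper member
            ),
        ),
    )
    cats = np.asarray(BIRADS_CATEGORIES, dtype=object)
    return cats[out]


def _strategy_recalls(
    cases: pd.DataFrame, strategy: str, readers: Sequence[str], rule: RecallRule
) -> np.ndarray:
    missing = [r for r in readers if r not in cases.columns]
    if missing:
        raise ValueError(f"case table lacks reader columns: {missing}")
    if strategy == "single":
        if len(readers) != 1:
            raise ValueError("strategy 'single' uses exactly one reader")
        return recall_vector(cases[readers[0]], rule)
    if strategy == "pair_either_recall":
        if len(readers) != 2:
            raise ValueError("strategy 'pair_either_recall' uses exactly two readers")
        return pair_either_recall(
            recall_vector(cases[readers[0]], rule), recall_vector(cases[readers[1]], rule)
        )
    if strategy == "panel_majority":
        if len(readers) != 4:
            raise ValueError("strategy 'panel_majority' uses exactly four readers")
        consensus = panel_majority([cases[r] for r in readers])
        return recall_vector(consensus, rule)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def evaluate_strategy(
    cases: pd.DataFrame,
    strategy: str,
    readers: Sequence[str],
    rule: RecallRule = RecallRule(),
    n_replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> PanelResult:
    """Sensitivity and specificity of a reading strategy, with bootstrap CIs.

    Sensitivity is the recalled fraction of malignant cases; specificity the
    non-recalled fraction of benign + normal cases.  CIs come from the
    class-stratified percentile bootstrap (``n_replicates`` = 0 skips them).
    """
    validate_case_table(cases)
    labels = roc.binary_labels(cases)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("strategy evaluation needs both malignant and non-malignant cases")

    def sens_metric(t: pd.DataFrame) -> float:
        rec = _strategy_recalls(t, strategy, readers, rule)
        lab = roc.binary_labels(t)
        return float(rec[lab == 1].mean())

    def spec_metric(t: pd.DataFrame) -> float:
        rec = _strategy_recalls(t, strategy, readers, rule)
        lab = roc.binary_labels(t)
        return float(1.0 - rec[lab == 0].mean())

    sens = sens_metric(cases)
    spec = spec_metric(cases)
    ci_sens = ci_spec = None
    if n_replicates > 0:
        ci_sens = roc.bootstrap_ci(sens_metric, cases, n_replicates, level, seed)
        ci_spec = roc.bootstrap_ci(spec_metric, cases, n_replicates, level, seed)
    return PanelResult(
        strategy=strategy,
        readers_used=tuple(readers),
        rule=rule,
        sensitivity=sens,
        specificity=spec,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
    )


def strategy_table(
    cases: pd.DataFrame,
    reader_cols: Sequence[str],
    rule: RecallRule = RecallRule(),
    n_replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> list[PanelResult]:
    """The standard benchmarking table over a reader set.

    Reader columns are interpreted positionally: the first two read one
    modality, the last two the other.  Rows: each single reader; the two
    same-modality either-recall pairs; the four cross-modality either-recall
    pairs; and the four-reader majority panel (when four readers exist).
    """
    kw = dict(rule=rule, n_replicates=n_replicates, level=level, seed=seed)
    out = [evaluate_strategy(cases, "single", [r], **kw) for r in reader_cols]
    if len(reader_cols) >= 2:
        out.append(evaluate_strategy(cases, "pair_either_recall", list(reader_cols[:2]), **kw))
    if len(reader_cols) >= 4:
        out.append(evaluate_strategy(cases, "pair_either_recall", list(reader_cols[2:4]), **kw))
        for a in reader_cols[:2]:
            for b in reader_cols[2:4]:
                out.append(evaluate_strategy(cases, "pair_either_recall", [a, b], **kw))
        out.append(evaluate_strategy(cases, "panel_majority", list(reader_cols[:4]), **kw))
    return out
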