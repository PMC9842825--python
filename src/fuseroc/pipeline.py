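"""End-to-end study orchestration.

``run_study`` ingests (or simulates) a case table, runs single-modality ROC
analysis, the fusion weight sweep, paired DeLong comparisons, maximum-Youden
operating points, and — when reader columns are present or simulated — the
reader-strategy table on the observer subcohort; ``render_report`` writes a
human-readable text report plus delimited tables.  Every source of
randomness derives from the single root seed in :class:`StudyConfig` by
fixed offsets, so a report regenerates bit-identically from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, fusion, roc
from .cohort import (
    BIRADS_CATEGORIES,
    CASE_TABLE_COLUMNS,
    CLASSES,
    BinormalModelSpec,
    CohortConfig,
    DEFAULT_MODEL,
    DEFAULT_READER_NAMES,
    DEFAULT_READER_PROFILES,
    ReaderProfile,
    generate_cohort,
    generate_reader_scores,
    observer_subcohort,
    validate_case_table,
)
from .readers import PanelResult, RecallRule, strategy_table

logger = logging.getLogger("fuseroc")

__all__ = [
    "StudyConfig",
    "ArmResult",
    "StudyReport",
    "read_case_table",
    "write_case_table",
    "run_study",
    "render_report",
]

# fixed sub-seed offsets off the root seed (kept < 2**31 by masking)
_SEED_SUBCOHORT = 1
_SEED_READERS = 2
_SEED_BOOTSTRAP = 3


def _subseed(root: int, offset: int) -> int:
    return int((root + offset) % (2**31 - 1))


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one study run.

    Exactly one input source: either ``input_path`` (a case-table file) or a
    simulation (``cohort`` + ``model`` [+ reader profiles]).
    """

    input_path: str | None = None
    cohort: CohortConfig | None = None
    model: BinormalModelSpec = DEFAULT_MODEL
    reader_profiles: Sequence[ReaderProfile] | None = DEFAULT_READER_PROFILES
    reader_names: Sequence[str] | None = DEFAULT_READER_NAMES
    subcohort_n_benign: int = 30
    subcohort_n_normal: int = 80
    grid_start: float = 0.01
    grid_stop: float = 0.99
    grid_step: float = 0.01
    bootstrap_replicates: int = 2000
    bootstrap_level: float = 0.95
    recall_threshold: str = "3"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ValueError(
                "exactly one input source required: input_path or a cohort simulation"
            )
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not 0.0 < self.bootstrap_level < 1.0:
            raise ValueError("bootstrap_level must lie in (0, 1)")


@dataclass(frozen=True)
class ArmResult:
    """Per-arm (dm / abus / multimodal) ROC summary."""

    arm: str
    auc: float
    ci_auc: roc.IntervalEstimate
    youden: roc.OperatingPoint
    curve: roc.ROCCurve


@dataclass(frozen=True)
class StudyReport:
    config: StudyConfig
    cases: pd.DataFrame
    arms: dict[str, ArmResult]
    fusion: fusion.FusionResult
    delong_fused_vs_dm: roc.DeLongResult
    delong_fused_vs_abus: roc.DeLongResult
    subcohort: pd.DataFrame | None
    subcohort_arms: dict[str, ArmResult] | None
    reader_strategies: list[PanelResult]
    provenance: dict


def read_case_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited (CSV) case table and validate the column contract.

    ``truth_class`` matching is case-insensitive ("Malignant" is accepted and
    normalized to lower case); reader categories are kept as strings.
    """
    table = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in CASE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    table["truth_class"] = table["truth_class"].astype(str).str.lower()
    bad_rows = [
        i + 2  # header is line 1
        for i, v in enumerate(table["truth_class"])
        if v not in CLASSES
    ]
    if bad_rows:
        raise ValueError(f"{path}: unknown truth_class at file lines {bad_rows}")
    for col in table.columns:
        if col not in CASE_TABLE_COLUMNS:
            table[col] = table[col].astype(str)
    validate_case_table(table)
    return table


def write_case_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a case table as UTF-8 CSV with a header row (round-trip exact)."""
    validate_case_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def _analyze_arm(
    name: str,
    scores: np.ndarray,
    cases: pd.DataFrame,
    score_lookup,
    n_replicates: int,
    level: float,
    seed: int,
) -> ArmResult:
    labels = roc.binary_labels(cases)
    curve = roc.empirical_roc(scores, labels)
    a = roc.auc(scores, labels)

    def auc_metric(t: pd.DataFrame) -> float:
        return roc.auc(score_lookup(t), roc.binary_labels(t))

    ci = roc.bootstrap_ci(auc_metric, cases, n_replicates, level, seed)
    return ArmResult(arm=name, auc=a, ci_auc=ci, youden=roc.max_youden(curve), curve=curve)


def _arm_results(
    cases: pd.DataFrame, fused: np.ndarray, config: StudyConfig, seed: int
) -> dict[str, ArmResult]:
    fused_by_id = dict(zip(cases["case_id"], fused))
    lookups = {
        "dm": lambda t: t["score_dm"].to_numpy(),
        "abus": lambda t: t["score_abus"].to_numpy(),
        "multimodal": lambda t: np.array([fused_by_id[i] for i in t["case_id"]]),
    }
    scores = {
        "dm": cases["score_dm"].to_numpy(),
        "abus": cases["score_abus"].to_numpy(),
        "multimodal": fused,
    }
    return {
        name: _analyze_arm(
            name,
            scores[name],
            cases,
            lookups[name],
            config.bootstrap_replicates,
            config.bootstrap_level,
            seed,
        )
        for name in ("dm", "abus", "multimodal")
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full evaluation pipeline; deterministic given the config."""
    if config.input_path is not None:
        cases = read_case_table(config.input_path)
        logger.info("loaded %d cases from %s", len(cases), config.input_path)
    else:
        cases = generate_cohort(config.cohort, config.model)
        logger.info("simulated %d cases (seed %d)", len(cases), config.cohort.seed)
    labels = roc.binary_labels(cases)
    if labels.sum() == 0:
        raise ValueError("cohort contains no malignant cases; nothing to evaluate")
    if labels.sum() == len(labels):
        raise ValueError("cohort contains only malignant cases; nothing to evaluate")

    boot_seed = _subseed(config.seed, _SEED_BOOTSTRAP)

    # fusion sweep on the full cohort
    sweep = fusion.weight_sweep(cases, config.grid_start, config.grid_stop, config.grid_step)
    arms = _arm_results(cases, sweep.fused_scores, config, boot_seed)

    delong_dm = roc.delong_paired_test(sweep.fused_scores, cases["score_dm"].to_numpy(), labels)
    delong_abus = roc.delong_paired_test(
        sweep.fused_scores, cases["score_abus"].to_numpy(), labels
    )

    # observer subcohort: reader columns, per-arm ROC, strategy table
    subcohort = None
    subcohort_arms = None
    strategies: list[PanelResult] = []
    reader_cols = [c for c in cases.columns if c not in CASE_TABLE_COLUMNS]
    have_readers = bool(reader_cols)
    if config.input_path is None and config.reader_profiles:
        counts = cases["truth_class"].value_counts()
        n_b = min(config.subcohort_n_benign, int(counts.get("benign", 0)))
        n_n = min(config.subcohort_n_normal, int(counts.get("normal", 0)))
        subcohort = observer_subcohort(
            cases, n_b, n_n, seed=_subseed(config.seed, _SEED_SUBCOHORT)
        )
        names = list(config.reader_names or [p.name for p in config.reader_profiles])
        subcohort = generate_reader_scores(
            subcohort,
            config.reader_profiles,
            seed=_subseed(config.seed, _SEED_READERS),
            names=names,
        )
        reader_cols = names
        have_readers = True
    elif have_readers:
        subcohort = cases

    if have_readers and subcohort is not None:
        sub_labels = roc.binary_labels(subcohort)
        if 0 < sub_labels.sum() < len(sub_labels):
            sub_sweep = fusion.weight_sweep(
                subcohort, config.grid_start, config.grid_stop, config.grid_step
            )
            subcohort_arms = _arm_results(subcohort, sub_sweep.fused_scores, config, boot_seed)
            strategies = strategy_table(
                subcohort,
                reader_cols,
                rule=RecallRule(config.recall_threshold),
                n_replicates=config.bootstrap_replicates,
                level=config.bootstrap_level,
                seed=boot_seed,
            )
    else:
        logger.info("no reader columns present; reader section omitted")

    provenance = {
        "software": f"fuseroc {__version__}",
        "seed": config.seed,
        # hash the scientific configuration only (output location excluded)
        "config_hash": hashlib.sha256(
            repr(dataclasses.replace(config, output_dir=None)).encode()
        ).hexdigest()[:16],
        "n_cases": int(len(cases)),
    }
    report = StudyReport(
        config=config,
        cases=cases,
        arms=arms,
        fusion=sweep,
        delong_fused_vs_dm=delong_dm,
        delong_fused_vs_abus=delong_abus,
        subcohort=subcohort,
        subcohort_arms=subcohort_arms,
        reader_strategies=strategies,
        provenance=provenance,
    )
    if config.output_dir is not None:
        render_report(report, config.output_dir)
    return report


def _fmt_ci(ci: roc.IntervalEstimate | None, pct: bool = False) -> str:
    if ci is None:
        return ""
    if pct:
        return f"[{100 * ci.lower:.1f}, {100 * ci.upper:.1f}]"
    return f"[{ci.lower:.3f}, {ci.upper:.3f}]"


def _composition(cases: pd.DataFrame) -> pd.DataFrame:
    counts = cases["truth_class"].value_counts()
    rows = [{"truth_class": c, "n": int(counts.get(c, 0))} for c in CLASSES]
    rows.append({"truth_class": "total", "n": int(len(cases))})
    return pd.DataFrame(rows)


def _report_text(report: StudyReport) -> str:
    buf = io.StringIO()
    w = buf.write
    w("fuseroc study report\n")
    w("====================\n\n")
    for k, v in report.provenance.items():
        w(f"{k}: {v}\n")
    w("\nCohort composition\n------------------\n")
    for _, row in _composition(report.cases).iterrows():
        w(f"  {row['truth_class']:>10}: {row['n']}\n")

    w("\nFull-cohort AI performance\n--------------------------\n")
    for name in ("dm", "abus", "multimodal"):
        arm = report.arms[name]
        yd = arm.youden
        w(
            f"  AI-{name.upper():<11} AUC = {arm.auc:.3f} {_fmt_ci(arm.ci_auc)}  "
            f"max Youden J = {yd.youden_j:.3f} "
            f"(sens {100 * yd.sensitivity:.1f}%, spec {100 * yd.specificity:.1f}%)\n"
        )
    w(
        f"\n  optimal fusion weights: dm = {report.fusion.optimal_weight_dm:.2f}, "
        f"abus = {report.fusion.optimal_weight_abus:.2f}\n"
    )
    w(
        f"  DeLong multimodal vs dm:   z = {report.delong_fused_vs_dm.z:.3f}, "
        f"p = {report.delong_fused_vs_dm.p_value:.3f}\n"
    )
    w(
        f"  DeLong multimodal vs abus: z = {report.delong_fused_vs_abus.z:.3f}, "
        f"p = {report.delong_fused_vs_abus.p_value:.3f}\n"
    )

    if report.subcohort is not None and report.reader_strategies:
        w("\nObserver subcohort\n------------------\n")
        for _, row in _composition(report.subcohort).iterrows():
            w(f"  {row['truth_class']:>10}: {row['n']}\n")
        if report.subcohort_arms is not None:
            w("\n  AI performance in the subcohort:\n")
            for name in ("dm", "abus", "multimodal"):
                arm = report.subcohort_arms[name]
                yd = arm.youden
                w(
                    f"    AI-{name.upper():<11} AUC = {arm.auc:.3f} {_fmt_ci(arm.ci_auc)}  "
                    f"max Youden: sens {100 * yd.sensitivity:.1f}%, "
                    f"spec {100 * yd.specificity:.1f}%\n"
                )
        rule = report.reader_strategies[0].rule
        w(
            f"\n  Reader strategies (recall at BI-RADS >= {rule.threshold_category}; "
            f"sens% / spec% with 95% CI):\n"
        )
        for s in report.reader_strategies:
            label = f"{s.strategy}({', '.join(s.readers_used)})"
            w(
                f"    {label:<70} {100 * s.sensitivity:5.1f} {_fmt_ci(s.ci_sensitivity, pct=True):<14} "
                f"{100 * s.specificity:5.1f} {_fmt_ci(s.ci_specificity, pct=True)}\n"
            )
    return buf.getvalue()


def render_report(report: StudyReport, output_dir: str | Path, formats=("text", "delimited")) -> list[Path]:
    """Write the report to ``output_dir``: a text summary and delimited tables.

    Numeric conventions: AUC and Youden J with 3 decimals; sensitivity and
    specificity as percentages with 1 decimal.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "text" in formats:
        p = out / "report.txt"
        p.write_text(_report_text(report), encoding="utf-8")
        written.append(p)

    if "delimited" in formats:
        write_case_table(report.cases, out / "cohort.csv")
        written.append(out / "cohort.csv")
        _composition(report.cases).to_csv(out / "composition.csv", index=False)
        written.append(out / "composition.csv")

        rows = []
        for scope, arms in (("full", report.arms), ("subcohort", report.subcohort_arms)):
            if arms is None:
                continue
            for name in ("dm", "abus", "multimodal"):
                arm = arms[name]
                rows.append(
                    {
                        "scope": scope,
                        "arm": name,
                        "auc": f"{arm.auc:.3f}",
                        "auc_ci_lower": f"{arm.ci_auc.lower:.3f}",
                        "auc_ci_upper": f"{arm.ci_auc.upper:.3f}",
                        "youden_j": f"{arm.youden.youden_j:.3f}",
                        "sensitivity_pct": f"{100 * arm.youden.sensitivity:.1f}",
                        "specificity_pct": f"{100 * arm.youden.specificity:.1f}",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "auc_summary.csv", index=False)
        written.append(out / "auc_summary.csv")

        report.fusion.to_frame().to_csv(out / "fusion_profile.csv", index=False)
        written.append(out / "fusion_profile.csv")

        for name in ("dm", "abus", "multimodal"):
            p = out / f"roc_{name}.csv"
            report.arms[name].curve.to_frame().to_csv(p, index=False)
            written.append(p)

        if report.reader_strategies:
            rows = []
            for s in report.reader_strategies:
                rows.append(
                    {
                        "strategy": s.strategy,
                        "readers": "+".join(s.readers_used),
                        "recall_threshold": s.rule.threshold_category,
                        "sensitivity_pct": f"{100 * s.sensitivity:.1f}",
                        "sens_ci_lower_pct": f"{100 * s.ci_sensitivity.lower:.1f}" if s.ci_sensitivity else "",
                        "sens_ci_upper_pct": f"{100 * s.ci_sensitivity.upper:.1f}" if s.ci_sensitivity else "",
                        "specificity_pct": f"{100 * s.specificity:.1f}",
                        "spec_ci_lower_pct": f"{100 * s.ci_specificity.lower:.1f}" if s.ci_specificity else "",
                        "spec_ci_upper_pct": f"{100 * s.ci_specificity.upper:.1f}" if s.ci_specificity else "",
                    }
                )
            pd.DataFrame(rows).to_csv(out / "reader_strategies.csv", index=False)
            written.append(out / "reader_strategies.csv")
    return written
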