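"""Full feature-combination sweep and optimal-subset selection.

The sweep ties the pipeline together: given a cohort of feature signal
sets (simulated or ingested), it computes the per-speed-class correlation
matrices, builds one combination dataset per enumerated feature subset,
cross-validates the biLSTM on each, and selects the *optimal* subsets —
the proper subsets whose mean accuracy is no more than ``tolerance_pct``
percentage points below the five-feature baseline AND whose features are
pairwise weakly correlated (R² < 0.40) in every speed class. Qualifiers
are ordered by (fewest features, then highest mean accuracy). Subsets that
clear the accuracy bar on highly correlated features are flagged
separately rather than selected.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .classify import BiLstmConfig, CVResult, cross_validate
from .core import FEATURE_NAMES, FeatureSignalSet, SPEED_CLASSES, SpeedClass
from .correlation import (
    LOW_CORRELATION_CUTOFF,
    CorrelationMatrix,
    correlation_matrix,
    low_correlation_subset,
)
from .patterns import PATTERN_LENGTH, build_combination_dataset, enumerate_combinations

__all__ = [
    "CombinationResult",
    "ExperimentReport",
    "run_sweep",
    "select_optimal",
    "write_report",
    "load_report",
    "subset_seed",
]


def subset_seed(master_seed: int, subset: Sequence[str]) -> int:
    """Deterministic per-subset child seed: CRC-32 of the subset name XOR master."""
    name = "+".join(subset)
    return int((zlib.crc32(name.encode()) ^ (master_seed & 0xFFFFFFFF)) % (2**31))


@dataclass
class CombinationResult:
    """Cross-validation outcome for one feature subset."""

    feature_subset: tuple[str, ...]
    cv: CVResult | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.cv is not None


@dataclass
class ExperimentReport:
    """Everything one sweep produced, with enough provenance to re-run it."""

    per_combination: list[CombinationResult]
    baseline: CVResult
    correlation_matrices: dict[SpeedClass, CorrelationMatrix]
    optimal_subsets: list[tuple[str, ...]]
    high_accuracy_high_correlation: list[tuple[str, ...]]
    config: dict
    seed: int

    def result_for(self, subset: Sequence[str]) -> CombinationResult:
        key = tuple(subset)
        for res in self.per_combination:
            if res.feature_subset == key:
                return res
        raise KeyError(f"subset {key} not in report")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def cv_dict(cv: CVResult | None) -> dict | None:
            if cv is None:
                return None
            return {
                "fold_accuracies": list(cv.fold_accuracies),
                "n_folds": cv.n_folds,
                "n_repeats": cv.n_repeats,
                "fold_train_seconds": list(cv.fold_train_seconds),
                "mean_accuracy": cv.mean_accuracy,
                "sd_accuracy": cv.sd_accuracy,
            }

        return {
            "seed": self.seed,
            "config": self.config,
            "baseline": cv_dict(self.baseline),
            "per_combination": [
                {
                    "feature_subset": list(r.feature_subset),
                    "cv": cv_dict(r.cv),
                    "error": r.error,
                }
                for r in self.per_combination
            ],
            "correlation_matrices": {
                cls.value: m.r2.tolist() for cls, m in self.correlation_matrices.items()
            },
            "optimal_subsets": [list(s) for s in self.optimal_subsets],
            "high_accuracy_high_correlation": [
                list(s) for s in self.high_accuracy_high_correlation
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentReport":
        def cv_obj(v: dict | None) -> CVResult | None:
            if v is None:
                return None
            return CVResult(
                fold_accuracies=list(v["fold_accuracies"]),
                n_folds=v["n_folds"],
                n_repeats=v["n_repeats"],
                fold_train_seconds=list(v["fold_train_seconds"]),
            )

        return cls(
            per_combination=[
                CombinationResult(
                    feature_subset=tuple(r["feature_subset"]),
                    cv=cv_obj(r["cv"]),
                    error=r["error"],
                )
                for r in d["per_combination"]
            ],
            baseline=cv_obj(d["baseline"]),
            correlation_matrices={
                SpeedClass(k): CorrelationMatrix(SpeedClass(k), np.array(v))
                for k, v in d["correlation_matrices"].items()
            },
            optimal_subsets=[tuple(s) for s in d["optimal_subsets"]],
            high_accuracy_high_correlation=[
                tuple(s) for s in d["high_accuracy_high_correlation"]
            ],
            config=d["config"],
            seed=d["seed"],
        )


def run_sweep(
    signal_sets: Iterable[FeatureSignalSet],
    sizes: Iterable[int] = (1, 2, 3, 4),
    config: BiLstmConfig | None = None,
    k: int = 17,
    n_repeats: int = 1,
    seed: int = 0,
    pattern_length: int = PATTERN_LENGTH,
    tolerance_pct: float = 2.0,
    r2_cutoff: float = LOW_CORRELATION_CUTOFF,
) -> ExperimentReport:
    """Cross-validate every enumerated subset plus the five-feature baseline.

    The baseline is always computed in-sweep on the same cohort (never
    imported from elsewhere), so subset accuracies and the baseline are
    directly comparable. Per-subset child seeds derive from the master seed
    and the canonical subset name, so any subset can be re-run in isolation.
    A failing subset yields a partial report with its error recorded.
    """
    config = config or BiLstmConfig()
    sets = list(signal_sets)
    subsets = enumerate_combinations(len(FEATURE_NAMES), sizes)
    if FEATURE_NAMES not in subsets:
        subsets = subsets + [FEATURE_NAMES]

    matrices: dict[SpeedClass, CorrelationMatrix] = {}
    for cls in SPEED_CLASSES:
        cls_sets = [s for s in sets if s.speed_class == cls]
        if cls_sets:
            matrices[cls] = correlation_matrix(cls_sets)

    results: list[CombinationResult] = []
    baseline: CVResult | None = None
    for subset in subsets:
        child = subset_seed(seed, subset)
        try:
            dataset = build_combination_dataset(sets, subset, length=pattern_length)
            cfg = dataclasses.replace(config, seed=child)
            # shared fold_seed: every subset is evaluated on the same
            # participant partitions, so accuracies compare pairwise
            cv = cross_validate(
                dataset, cfg, k=k, n_repeats=n_repeats, seed=child, fold_seed=seed
            )
            res = CombinationResult(feature_subset=subset, cv=cv)
        except Exception as exc:  # noqa: BLE001 - partial reports are the contract
            res = CombinationResult(feature_subset=subset, cv=None, error=str(exc))
        results.append(res)
        if subset == FEATURE_NAMES and res.ok:
            baseline = res.cv
    if baseline is None:
        raise RuntimeError("five-feature baseline failed; cannot build a report")

    report = ExperimentReport(
        per_combination=results,
        baseline=baseline,
        correlation_matrices=matrices,
        optimal_subsets=[],
        high_accuracy_high_correlation=[],
        config={
            "classifier": dataclasses.asdict(config),
            "k": k,
            "n_repeats": n_repeats,
            "sizes": sorted(set(sizes)),
            "pattern_length": pattern_length,
            "tolerance_pct": tolerance_pct,
            "r2_cutoff": r2_cutoff,
        },
        seed=seed,
    )
    report.optimal_subsets = select_optimal(report, tolerance_pct, r2_cutoff)
    report.high_accuracy_high_correlation = _accurate_but_correlated(
        report, tolerance_pct, r2_cutoff
    )
    return report


def _qualifies_accuracy(res: CombinationResult, baseline: CVResult, tolerance_pct: float) -> bool:
    return res.ok and res.cv.mean_accuracy >= baseline.mean_accuracy - tolerance_pct


def _low_corr_everywhere(
    report: ExperimentReport, subset: Sequence[str], cutoff: float
) -> bool:
    return all(
        low_correlation_subset(m, subset, cutoff)
        for m in report.correlation_matrices.values()
    )


def select_optimal(
    report: ExperimentReport,
    tolerance_pct: float = 2.0,
    r2_cutoff: float = LOW_CORRELATION_CUTOFF,
) -> list[tuple[str, ...]]:
    """Proper subsets within ``tolerance_pct`` of the baseline and weakly correlated.

    Returned ordered by (fewest features, then highest mean accuracy).
    """
    qualifiers = [
        res
        for res in report.per_combination
        if len(res.feature_subset) < len(FEATURE_NAMES)
        and _qualifies_accuracy(res, report.baseline, tolerance_pct)
        and _low_corr_everywhere(report, res.feature_subset, r2_cutoff)
    ]
    qualifiers.sort(key=lambda r: (len(r.feature_subset), -r.cv.mean_accuracy))
    return [r.feature_subset for r in qualifiers]


def _accurate_but_correlated(
    report: ExperimentReport, tolerance_pct: float, r2_cutoff: float
) -> list[tuple[str, ...]]:
    """Subsets that clear the accuracy bar but fail the correlation screen."""
    flagged = [
        res
        for res in report.per_combination
        if len(res.feature_subset) < len(FEATURE_NAMES)
        and _qualifies_accuracy(res, report.baseline, tolerance_pct)
        and not _low_corr_everywhere(report, res.feature_subset, r2_cutoff)
    ]
    flagged.sort(key=lambda r: (len(r.feature_subset), -r.cv.mean_accuracy))
    return [r.feature_subset for r in flagged]


def write_report(report: ExperimentReport, out_dir: str | Path) -> dict[str, Path]:
    """Write summary CSV, per-fold CSV and a full JSON bundle; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = set(report.optimal_subsets)

    summary = out_dir / "summary.csv"
    with summary.open("w") as fh:
        fh.write("subset,n_features,mean_acc,sd_acc,mean_time_min,sd_time_min,selected\n")
        for res in report.per_combination:
            name = "+".join(res.feature_subset)
            if res.ok:
                fh.write(
                    f"{name},{len(res.feature_subset)},{res.cv.mean_accuracy:.6f},"
                    f"{res.cv.sd_accuracy:.6f},{res.cv.mean_training_time:.6f},"
                    f"{res.cv.sd_training_time:.6f},{int(res.feature_subset in selected)}\n"
                )
            else:
                fh.write(f"{name},{len(res.feature_subset)},,,,,0\n")

    folds = out_dir / "folds.csv"
    with folds.open("w") as fh:
        fh.write("subset,repeat,fold,accuracy,train_seconds\n")
        for res in report.per_combination:
            if not res.ok:
                continue
            cv = res.cv
            name = "+".join(res.feature_subset)
            for idx, acc in enumerate(cv.fold_accuracies):
                rep, fold = divmod(idx, cv.n_folds)
                secs = cv.fold_train_seconds[idx] if cv.fold_train_seconds else ""
                fh.write(f"{name},{rep},{fold},{acc},{secs}\n")

    bundle = out_dir / "report.json"
    bundle.write_text(json.dumps(report.to_dict(), indent=2))
    return {"summary": summary, "folds": folds, "json": bundle}


def load_report(path: str | Path) -> ExperimentReport:
    """Reload a JSON report bundle written by :func:`write_report`."""
    return ExperimentReport.from_dict(json.loads(Path(path).read_text()))
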