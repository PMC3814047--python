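"""Repeated stratified cross-validation of the ERP and AR predictors.

Entries are randomly partitioned into ``n_folds`` near-equal folds; each fold
serves once as the test set while the remaining entries form the training
universe.  Test entries are stratified into single-EC and multiple-EC sets.
Per simulation (= one run x one fold) and per method/stratum a cell records:

* **testing** — entries evaluated,
* **match** — entries for which the method produced any prediction,
* **hit** — matched entries whose predicted EC set equals the annotation
  exactly (default; an overlap criterion is available),

with accuracy = hit / match.  Three method rows are reported: ``AR`` and
``ERP1`` on the full test stratum, and ``ERP2`` — the ERP predictor
re-scored on exactly the test entries the AR model matched, so that
``ERP2.testing == ERP2.match == AR.match`` by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ar import ARConfig, ar_predict, train_ar
from .predictor import FAILURE, predict
from .universe import Entry, Universe

__all__ = [
    "METHODS",
    "STRATA",
    "FoldPlan",
    "CVCell",
    "CVReport",
    "make_folds",
    "score_entry",
    "run_cv",
    "report_tables",
]

METHODS = ("AR", "ERP1", "ERP2")
STRATA = ("single", "multiple")


@dataclass
class FoldPlan:
    """A reproducible assignment of entries to folds."""

    assignments: dict[frozenset, int]  # architecture -> fold index
    n_folds: int
    run_seed: int

    def folds(self, entries: list[Entry]) -> list[list[Entry]]:
        out: list[list[Entry]] = [[] for _ in range(self.n_folds)]
        for entry in entries:
            out[self.assignments[entry.architecture]].append(entry)
        return out


def make_folds(entries: list[Entry], n_folds: int, seed: int) -> FoldPlan:
    """Uniformly random balanced partition; fold sizes differ by <= 1.

    With 5,203 entries and 5 folds the sizes are (1041, 1041, 1041, 1040,
    1040) in some order.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(entries) < n_folds:
        raise ValueError(f"need at least {n_folds} entries, got {len(entries)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    base, extra = divmod(len(entries), n_folds)
    assignments: dict[frozenset, int] = {}
    position = 0
    for fold in range(n_folds):
        size = base + (1 if fold < extra else 0)
        for idx in order[position : position + size]:
            assignments[entries[int(idx)].architecture] = fold
        position += size
    return FoldPlan(assignments=assignments, n_folds=n_folds, run_seed=seed)


def score_entry(
    predicted: tuple[bool, frozenset[str]],
    truth: frozenset[str],
    hit_mode: str = "exact",
) -> tuple[int, int]:
    """Score one test entry: (match, hit).

    ``match`` is 1 iff the method produced a non-failure prediction.
    ``hit`` is 1 iff match and the predicted EC set equals the annotated set
    exactly (``hit_mode='exact'``, default) or intersects it
    (``hit_mode='overlap'``).
    """
    if not truth:
        raise ValueError("truth EC set must be non-empty")
    matched, ecs = predicted
    if not matched:
        return 0, 0
    if hit_mode == "exact":
        hit = 1 if frozenset(ecs) == frozenset(truth) else 0
    elif hit_mode == "overlap":
        hit = 1 if frozenset(ecs) & frozenset(truth) else 0
    else:
        raise ValueError(f"unknown hit_mode {hit_mode!r}")
    return 1, hit


@dataclass
class CVCell:
    hit: int = 0
    match: int = 0
    testing: int = 0

    @property
    def accuracy(self) -> float | None:
        """hit / match; undefined (None) when nothing matched."""
        return self.hit / self.match if self.match else None

    def validate(self) -> None:
        if not 0 <= self.hit <= self.match <= self.testing:
            raise ValueError(f"inconsistent cell {self}")


@dataclass
class CVReport:
    """Per-simulation cells plus aggregation over runs x folds."""

    cells: dict[tuple[str, str], list[CVCell]]
    n_runs: int
    n_folds: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_simulations(self) -> int:
        return self.n_runs * self.n_folds

    def summary(self) -> dict:
        """Mean and sample sd (ddof=1; 0.0 below 2 samples) per cell."""
        out: dict = {}
        for key, cells in self.cells.items():
            method, stratum = key
            stats = {}
            for name in ("hit", "match", "testing"):
                values = np.array([getattr(c, name) for c in cells], dtype=float)
                stats[name] = {"mean": float(values.mean()), "sd": _sd(values)}
            accuracies = np.array(
                [c.accuracy for c in cells if c.match > 0], dtype=float
            )
            if accuracies.size:
                stats["accuracy"] = {
                    "mean": float(accuracies.mean()),
                    "sd": _sd(accuracies),
                    "n_defined": int(accuracies.size),
                }
            else:
                stats["accuracy"] = {"mean": None, "sd": None, "n_defined": 0}
            out.setdefault(stratum, {})[method] = stats
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_runs": self.n_runs,
                "n_folds": self.n_folds,
                "summary": self.summary(),
                "warnings": self.warnings,
            },
            indent=1,
        )


def _sd(values: np.ndarray) -> float:
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def run_cv(
    universe: Universe,
    runs: int = 20,
    n_folds: int = 5,
    base_seed: int = 0,
    ar_config: ARConfig = ARConfig(),
    hit_mode: str = "exact",
) -> CVReport:
    """Repeated k-fold cross-validation of AR, ERP1 and ERP2.

    Run ``r`` repartitions the entries with seed ``base_seed + r``; each of
    the ``runs * n_folds`` simulations trains both methods on the training
    entries only and scores every test entry, stratified by EC multiplicity.
    """
    entries = list(universe.entries)
    cells: dict[tuple[str, str], list[CVCell]] = {
        (m, s): [] for m in METHODS for s in STRATA
    }
    warnings: list[str] = []
    for run in range(runs):
        plan = make_folds(entries, n_folds, seed=base_seed + run)
        folds = plan.folds(entries)
        for fold_idx in range(n_folds):
            test_entries = folds[fold_idx]
            train_entries = [
                e for i, fold in enumerate(folds) if i != fold_idx for e in fold
            ]
            train_universe = Universe(train_entries)
            rules = train_ar(train_universe, ar_config)
            if not rules:
                warnings.append(
                    f"run {run} fold {fold_idx}: no association rules mined"
                )
            sim = {key: CVCell() for key in cells}
            for entry in test_entries:
                stratum = "single" if entry.is_single_ec else "multiple"
                truth = entry.ecs

                erp_result = predict(train_universe, entry.architecture)
                erp_pred = (erp_result.status != FAILURE, erp_result.ecs)
                erp_match, erp_hit = score_entry(erp_pred, truth, hit_mode)
                cell = sim[("ERP1", stratum)]
                cell.testing += 1
                cell.match += erp_match
                cell.hit += erp_hit

                ar_result = ar_predict(rules, entry.architecture)
                ar_match, ar_hit = score_entry(
                    (ar_result.matched, ar_result.ecs), truth, hit_mode
                )
                cell = sim[("AR", stratum)]
                cell.testing += 1
                cell.match += ar_match
                cell.hit += ar_hit

                if ar_match:  # ERP re-scored on the AR-matched subset
                    cell = sim[("ERP2", stratum)]
                    cell.testing += 1
                    cell.match += erp_match
                    cell.hit += erp_hit
            for key, cell in sim.items():
                cell.validate()
                cells[key].append(cell)
    return CVReport(cells=cells, n_runs=runs, n_folds=n_folds, warnings=warnings)


def report_tables(report: CVReport) -> str:
    """Render a counts table (mean +/- sd) and an accuracy table as TSV text."""
    summary = report.summary()
    count_rows = []
    acc_rows = []
    for stratum in STRATA:
        acc_row: dict = {"Data set": _stratum_label(stratum)}
        for method in METHODS:
            stats = summary[stratum][method]
            count_rows.append(
                {
                    "Data set": _stratum_label(stratum),
                    "Method": method,
                    "Hit": _fmt(stats["hit"]),
                    "Match": _fmt(stats["match"]),
                    "Testing set": _fmt(stats["testing"]),
                }
            )
            acc = stats["accuracy"]
            if acc["mean"] is None:
                acc_row[method] = "undefined"
            else:
                acc_row[method] = f"{100 * acc['mean']:.2f}% ± {100 * acc['sd']:.2f}%"
        acc_rows.append(acc_row)
    counts = pd.DataFrame(count_rows)
    accuracy = pd.DataFrame(acc_rows)
    parts = [
        f"# Mean entry counts over {report.n_simulations} simulations",
        counts.to_csv(sep="\t", index=False).rstrip("\n"),
        "",
        "# Accuracy (hit / match)",
        accuracy.to_csv(sep="\t", index=False).rstrip("\n"),
    ]
    if report.warnings:
        parts += ["", "# Warnings"] + [f"# {w}" for w in report.warnings]
    return "\n".join(parts) + "\n"


def _stratum_label(stratum: str) -> str:
    return "Single EC" if stratum == "single" else "Multiple ECs"


def _fmt(stats: dict) -> str:
    return f"{stats['mean']:.2f} ± {stats['sd']:.2f}"
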