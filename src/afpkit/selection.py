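"""Recursive feature elimination driven by extremely-randomized-tree weights.

ERT-RFE fits an extremely randomized trees (ERT) ensemble on the surviving
features, records the subset's cross-validated accuracy, ranks features by
impurity importance and drops the lowest-ranked ones, repeating until a
floor is reached. The subset with maximal CV accuracy wins; ties go to the
smaller subset. The full per-iteration record (surviving names, importances,
CV score) is returned as an auditable trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .encoders import FeatureMatrix


@dataclass
class SelectionIteration:
    """One elimination round: survivors, their importances, the CV score."""

    names: tuple[str, ...]
    importances: np.ndarray
    cv_accuracy: float


@dataclass
class SelectionTrace:
    """The audit trail of one ERT-RFE run."""

    iterations: list[SelectionIteration]
    best_iteration: int
    selected_names: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "best_iteration": self.best_iteration,
            "selected_names": self.selected_names,
            "iterations": [
                {
                    "names": list(it.names),
                    "importances": [float(v) for v in it.importances],
                    "cv_accuracy": it.cv_accuracy,
                }
                for it in self.iterations
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _resolve_step(step: float, n_surviving: int) -> int:
    if 0 < step < 1:
        return max(1, math.floor(step * n_surviving))
    if step >= 1:
        return int(step)
    raise ValueError(f"step must be a positive integer or a fraction in (0, 1), got {step}")


def ert_rfe(
    matrix: FeatureMatrix,
    step: float = 1,
    cv_folds: int = 5,
    min_features: int = 1,
    seed: int = 0,
    n_estimators: int = 250,
) -> SelectionTrace:
    """Run ERT-RFE on a labeled feature matrix.

    ``step`` is the number of lowest-importance features removed per round
    (a fraction in (0, 1) removes that share of the current survivors).
    Importance ties are broken by feature name, dropping the
    lexicographically later name first. Subset accuracy is stratified
    ``cv_folds``-fold accuracy of a seeded ERT ensemble; the folds are fixed
    once so every subset is scored on the same splits.
    """
    if matrix.labels is None:
        raise ValueError("ERT-RFE requires a labeled feature matrix")
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("ERT-RFE requires both classes to be present")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    X = matrix.values
    names = list(matrix.names)
    surviving = list(range(len(names)))
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    iterations: list[SelectionIteration] = []
    while True:
        Xs = X[:, surviving]
        model = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
        accuracy = float(cross_val_score(model, Xs, y, cv=folds, scoring="accuracy").mean())
        model.fit(Xs, y)
        importances = model.feature_importances_.copy()
        iterations.append(
            SelectionIteration(
                names=tuple(names[i] for i in surviving),
                importances=importances,
                cv_accuracy=accuracy,
            )
        )
        if len(surviving) <= min_features:
            break
        n_remove = min(_resolve_step(step, len(surviving)), len(surviving) - min_features)
        # ascending importance; ties drop the lexicographically later name first
        order = sorted(range(len(surviving)), key=lambda j: names[surviving[j]], reverse=True)
        order.sort(key=lambda j: importances[j])  # stable, keeps the name tie-break
        dropped = set(order[:n_remove])
        surviving = [idx for j, idx in enumerate(surviving) if j not in dropped]
    best = 0
    for i, it in enumerate(iterations):
        if it.cv_accuracy >= iterations[best].cv_accuracy:
            best = i  # later iterations have smaller subsets, so >= prefers them on ties
    return SelectionTrace(
        iterations=iterations,
        best_iteration=best,
        selected_names=list(iterations[best].names),
    )


def apply_selection(matrix: FeatureMatrix, trace: SelectionTrace) -> FeatureMatrix:
    """Subset a feature matrix to the trace's winning columns, in trace order."""
    return matrix.subset_columns(trace.selected_names)


def select_per_encoder(
    matrix: FeatureMatrix,
    prefixes: Sequence[str] = ("GAAC.", "DPC.", "PSETS.", "SGACT."),
    step: float = 1,
    cv_folds: int = 5,
    min_features: int = 1,
    seed: int = 0,
    n_estimators: int = 250,
) -> tuple[FeatureMatrix, dict[str, SelectionTrace]]:
    """Run ERT-RFE independently per encoder block, then fuse the winners.

    Feature blocks are identified by name prefix. Returns the fused selected
    matrix (blocks concatenated in ``prefixes`` order) and the per-block
    traces.
    """
    traces: dict[str, SelectionTrace] = {}
    selected: list[str] = []
    for prefix in prefixes:
        block_names = [n for n in matrix.names if n.startswith(prefix)]
        if not block_names:
            raise ValueError(f"no features with prefix {prefix!r} in matrix")
        block = matrix.subset_columns(block_names)
        trace = ert_rfe(
            block, step=step, cv_folds=cv_folds, min_features=min_features,
            seed=seed, n_estimators=n_estimators,
        )
        traces[prefix] = trace
        selected.extend(trace.selected_names)
    return matrix.subset_columns(selected), traces
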