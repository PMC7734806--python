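"""Feature-panel search with leave-one-out cross-validated evaluation.

Every candidate combination of features is scored by full LOOCV: one model
fit per held-out participant, with standardization constants, the Fisher
boundary and its balanced confidence level all re-derived inside each fold
so no information leaks from the held-out row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from metscreen.cohort import CohortMatrix, SubsetSpec
from metscreen.models import (
    FdaModel,
    balance_confidence,
    classify,
    fda_fit,
    logistic_fit,
)

CLASSIFIERS = ("fda", "logistic")
DEFAULT_BEAM_WIDTH = 50
DEFAULT_BUDGET = 100_000


class PanelError(ValueError):
    """Raised for invalid panel-search requests."""


@dataclass
class PanelEvaluation:
    """LOOCV result for one feature combination.

    ``type1`` is the fraction of controls misclassified as cases, ``type2``
    the fraction of cases misclassified as controls; positives are the case
    group throughout.
    """

    subset_id: str
    features: tuple[str, ...]
    classifier: str
    type1: float
    type2: float
    n_case: int
    n_control: int
    per_sample: list[tuple[str, str, str, float]]  # (participant, true, predicted, score/prob)

    @property
    def sensitivity(self) -> float:
        return 1.0 - self.type2

    @property
    def specificity(self) -> float:
        return 1.0 - self.type1

    @property
    def n_misclassified(self) -> int:
        return round(self.type1 * self.n_control) + round(self.type2 * self.n_case)

    @property
    def total_error(self) -> float:
        return self.n_misclassified / (self.n_case + self.n_control)

    def sort_key(self) -> tuple:
        return (self.n_misclassified, abs(self.type1 - self.type2), self.features)


def loocv_evaluate(
    m: CohortMatrix,
    features: Sequence[str],
    classifier: str = "logistic",
    subset_id: str = "iv",
    fold_models: list | None = None,
) -> PanelEvaluation:
    """Evaluate one feature combination under leave-one-out cross-validation.

    If a list is passed as ``fold_models``, the fitted per-fold models are
    appended to it (used by the no-leakage checks).
    """
    if classifier not in CLASSIFIERS:
        raise PanelError(f"unknown classifier {classifier!r}")
    features = tuple(features)
    kinds = {name: m.meta(name).kind for name in features}
    if classifier == "fda" and any(k != "continuous" for k in kinds.values()):
        binaries = sorted(n for n, k in kinds.items() if k != "continuous")
        raise PanelError(
            f"Fisher discriminant cannot take non-continuous features {binaries}; "
            "use the logistic classifier"
        )
    X = m.values[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PanelError("panel features must be complete (no missing cells)")
    case_mask = m.case_mask
    labels = np.where(case_mask, m.case_label, m.control_label)
    ids = list(m.participants)
    n = X.shape[0]
    per_sample: list[tuple[str, str, str, float]] = []
    fp = fn = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, ctr = X[keep], case_mask[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if classifier == "fda":
                model = fda_fit(Xtr[ctr], Xtr[~ctr], place_boundary=False)
                model = balance_confidence(model, Xtr[ctr], Xtr[~ctr])
            else:
                model = logistic_fit(Xtr, ctr.astype(int), positive_group=m.case_label)
        if fold_models is not None:
            fold_models.append(model)
        pred, value = classify(model, X[i])
        if isinstance(model, FdaModel) and pred != m.case_label:
            pred = m.control_label
        per_sample.append((str(ids[i]), str(labels[i]), pred, value))
        if labels[i] == m.control_label and pred == m.case_label:
            fp += 1
        elif labels[i] == m.case_label and pred != m.case_label:
            fn += 1
    n_case = int(case_mask.sum())
    n_control = n - n_case
    return PanelEvaluation(
        subset_id=subset_id,
        features=features,
        classifier=classifier,
        type1=fp / n_control,
        type2=fn / n_case,
        n_case=n_case,
        n_control=n_control,
        per_sample=per_sample,
    )


def search_panels(
    m: CohortMatrix,
    subset: SubsetSpec,
    sizes: Iterable[int] = range(2, 6),
    classifier: str = "logistic",
    strategy: str = "exhaustive",
    budget: int = DEFAULT_BUDGET,
    beam_width: int = DEFAULT_BEAM_WIDTH,
) -> list[PanelEvaluation]:
    """Rank feature combinations of the given sizes by LOOCV error.

    ``exhaustive`` enumerates every combination (refused above ``budget``);
    ``beam`` grows panels one feature per round, keeping the best
    ``beam_width`` at each size -- the documented scaled-down surrogate
    when the combinatorial count is out of reach.

    Ranking key: misclassification count ascending, then |typeI - typeII|,
    then feature names.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 2 or sizes[-1] > 10:
        raise PanelError("panel sizes must lie within [2, 10]")
    names = list(subset.feature_names)
    if sizes[-1] > len(names):
        raise PanelError("requested panel size exceeds the subset size")
    evaluations: list[PanelEvaluation] = []
    if strategy == "exhaustive":
        total = sum(comb(len(names), k) for k in sizes)
        if total > budget:
            raise PanelError(
                f"exhaustive search needs {total} evaluations, over the budget of "
                f"{budget}; use strategy='beam'"
            )
        for k in sizes:
            for combo in combinations(names, k):
                evaluations.append(loocv_evaluate(m, combo, classifier, subset.id))
    elif strategy == "beam":
        # size-1 panels seed the beam even though they are never reported
        seed_scores = {(nm,): loocv_evaluate(m, (nm,), classifier, subset.id) for nm in names}
        beam = sorted(seed_scores, key=lambda p: seed_scores[p].sort_key())[:beam_width]
        seen: set[frozenset] = set()
        for size in range(2, sizes[-1] + 1):
            level: dict[tuple, PanelEvaluation] = {}
            for panel in beam:
                for nm in names:
                    if nm in panel:
                        continue
                    candidate = tuple(sorted(panel + (nm,)))
                    key = frozenset(candidate)
                    if key in seen:
                        continue
                    seen.add(key)
                    level[candidate] = loocv_evaluate(m, candidate, classifier, subset.id)
            if not level:
                break
            if size in sizes:
                evaluations.extend(level.values())
            beam = sorted(level, key=lambda p: level[p].sort_key())[:beam_width]
    else:
        raise PanelError(f"unknown strategy {strategy!r}")
    evaluations.sort(key=lambda e: e.sort_key())
    return evaluations


@dataclass
class PanelReport:
    """Top-ranked panels plus near-ties within a total-error margin."""

    best: list[PanelEvaluation]
    near_ties: list[PanelEvaluation]
    margin: float


def report_best(
    table: Sequence[PanelEvaluation],
    k: int = 1,
    margin: float = 0.0,
) -> PanelReport:
    """Top-k panels and everything within ``margin`` of the best total error."""
    if not table:
        raise PanelError("empty evaluation table")
    ranked = sorted(table, key=lambda e: e.sort_key())
    best_err = ranked[0].total_error
    near = [e for e in ranked[k:] if e.total_error <= best_err + margin]
    return PanelReport(best=list(ranked[:k]), near_ties=near, margin=margin)


def evaluations_table(evaluations: Sequence[PanelEvaluation]) -> pd.DataFrame:
    """CSV-ready summary; error rates reported as whole percent."""
    return pd.DataFrame(
        {
            "subset": [e.subset_id for e in evaluations],
            "features": ["|".join(e.features) for e in evaluations],
            "classifier": [e.classifier for e in evaluations],
            "type1_pct": [round(100 * e.type1) for e in evaluations],
            "type2_pct": [round(100 * e.type2) for e in evaluations],
            "sensitivity_pct": [round(100 * e.sensitivity) for e in evaluations],
            "specificity_pct": [round(100 * e.specificity) for e in evaluations],
        }
    )
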