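"""Three-stage estimation of the driving-automation state.

Stage 1 compares the dwell percentage of each AOI between manual and
automated driving with paired t-tests, Holm-corrected across the 13
AOIs. Stage 2 fits a PLS regression of the state code (+1 manual, -1
automated) on one of four indicator sets (PRC / static / dynamic /
both), choosing capacity and indicators by leave-one-out MSEP. Stage 3
thresholds the continuous score at zero: negative scores are classified
as automated driving, non-negative as manual.

A final descriptive step classifies each AOI by the *net flow* of the
selected transition indicators: an AOI whose selected transitions
arrive more often than they depart is an entering AOI, the reverse an
exiting AOI, a zero balance an equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateDataError,
    GazeStateError,
    InsufficientDataError,
    PairingError,
    SchemaError,
)
from .indicators import (
    LabeledSequence,
    assemble_design,
    dwell_percentages,
    indicator_set,
)
from .pls import CvReport, PlsModel, predict_scores, select_indicators
from .reference import AOI_CODES

__all__ = [
    "MANUAL",
    "AUTOMATED",
    "classify_score",
    "EstimationReport",
    "run_pipeline",
    "fit_design",
    "compare_conditions",
    "paired_dwell_tests",
    "net_flow",
    "selected_transitions",
]

MANUAL = "manual"
AUTOMATED = "automated"

_STATE_NAME = {1: MANUAL, -1: AUTOMATED}


class InvalidScoreError(GazeStateError):
    """A prediction score is non-finite."""


def classify_score(score: float) -> str:
    """Binary state from a continuous score: negative -> automated,
    non-negative -> manual."""
    if not math.isfinite(score):
        raise InvalidScoreError(f"non-finite score: {score!r}")
    return AUTOMATED if score < 0 else MANUAL


@dataclass(frozen=True)
class EstimationReport:
    """Per-mode outcome of the prediction pipeline.

    ``scores`` are leave-one-out predictions (each unit scored by a model
    that never saw it); ``fitted_scores`` are the full-model in-sample
    values, reported separately. Classification and the error count use
    the leave-one-out scores.
    """

    mode: str
    unit_ids: tuple[tuple, ...]
    scores: np.ndarray
    fitted_scores: np.ndarray
    predicted: tuple[str, ...]
    true: tuple[str, ...]
    msep: float
    msep_insample: float
    n_selected: int
    n_components: int
    n_errors: int
    error_unit_ids: tuple[tuple, ...]
    model: PlsModel = field(repr=False)
    cv: CvReport = field(repr=False)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [u[0] for u in self.unit_ids],
                "condition": [u[1] for u in self.unit_ids],
                "score": self.scores,
                "fitted_score": self.fitted_scores,
                "predicted": list(self.predicted),
                "true": list(self.true),
            }
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "msep": float(self.msep),
            "msep_insample": float(self.msep_insample),
            "n_selected": int(self.n_selected),
            "n_components": int(self.n_components),
            "n_errors": int(self.n_errors),
            "error_unit_ids": [list(u) for u in self.error_unit_ids],
            "selected": list(self.model.selected),
            "cv": self.cv.to_dict(),
        }


def run_pipeline(
    trials: list[LabeledSequence],
    mode: str = "DS",
    *,
    max_ncomp: int | None = None,
    selection: str = "backward",
    transition_level: str = "samples",
) -> EstimationReport:
    """Full prediction pipeline for one indicator mode.

    Extracts indicators from the labelled trials, assembles and
    standardises the design matrix, selects indicators and component
    count by leave-one-out MSEP, classifies every unit from its left-out
    score, and reports MSEP and errors. Deterministic given inputs.
    """
    if len(trials) < 4:
        raise InsufficientDataError("need at least 4 trials")
    conds = {t.condition for t in trials}
    if not conds <= {1, -1} or len(conds) < 2:
        raise DegenerateDataError(
            "trials must carry both condition codes (+1 manual, -1 automated)"
        )
    sets = [indicator_set(t, transition_level=transition_level) for t in trials]
    dm = assemble_design(sets, mode)
    y = np.array([t.condition for t in trials], dtype=float)
    return fit_design(dm, y, max_ncomp=max_ncomp, selection=selection)


def fit_design(
    dm,
    y: np.ndarray,
    *,
    max_ncomp: int | None = None,
    selection: str = "backward",
) -> EstimationReport:
    """Selection, leave-one-out scoring and classification for an
    already-assembled design matrix with state codes ``y``."""
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) == {1.0, -1.0}:
        raise DegenerateDataError(
            "y must contain both condition codes (+1 manual, -1 automated)"
        )
    selected, model, cv = select_indicators(
        dm, y, max_ncomp=max_ncomp, strategy=selection
    )
    fitted = predict_scores(model, dm.values)
    loo_scores = cv.per_unit_predictions
    predicted = tuple(classify_score(s) for s in loo_scores)
    true = tuple(_STATE_NAME[int(c)] for c in y)
    errors = tuple(
        uid for uid, p, t in zip(dm.unit_ids, predicted, true) if p != t
    )
    return EstimationReport(
        mode=dm.mode,
        unit_ids=dm.unit_ids,
        scores=loo_scores,
        fitted_scores=fitted,
        predicted=predicted,
        true=true,
        msep=cv.msep,
        msep_insample=float(np.mean((y - fitted) ** 2)),
        n_selected=len(selected),
        n_components=model.n_components,
        n_errors=len(errors),
        error_unit_ids=errors,
        model=model,
        cv=cv,
    )


def compare_conditions(
    trials: list[LabeledSequence], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired manual-vs-automated comparison of dwell percentages.

    One paired t-test per AOI across participants, two-sided, with the
    Holm step-down adjustment over the 13 tests at family level
    ``alpha``. Differences are oriented automated minus manual. AOIs with
    identical paired values have zero difference and are reported as
    p = 1 (no evidence of any difference).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    by: dict[object, dict[int, pd.Series]] = {}
    for t in trials:
        if t.condition not in (1, -1):
            raise PairingError(f"trial {t.participant!r} has no condition code")
        by.setdefault(t.participant, {})[t.condition] = dwell_percentages(t)
    bad = [p for p, d in by.items() if set(d) != {1, -1}]
    if bad:
        raise PairingError(f"participants without both conditions: {bad}")
    if len(by) < 2:
        raise InsufficientDataError("need at least 2 paired participants")
    participants = list(by)
    manual = np.array([by[p][1].to_numpy() for p in participants])
    auto = np.array([by[p][-1].to_numpy() for p in participants])
    return paired_dwell_tests(manual, auto, alpha)


def paired_dwell_tests(
    manual: np.ndarray, auto: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Holm-corrected paired t-tests on aligned participants x AOIs dwell
    arrays (rows paired by participant)."""
    pvals = []
    for j in range(len(AOI_CODES)):
        d = auto[:, j] - manual[:, j]
        if np.allclose(d, 0.0):
            pvals.append(1.0)  # identical pairs: no evidence of a difference
            continue
        res = stats.ttest_rel(auto[:, j], manual[:, j])
        pvals.append(1.0 if np.isnan(res.pvalue) else float(res.pvalue))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return pd.DataFrame(
        {
            "manual_mean": manual.mean(axis=0),
            "automated_mean": auto.mean(axis=0),
            "difference": auto.mean(axis=0) - manual.mean(axis=0),
            "p_value": pvals,
            "p_holm": p_adj,
            "significant": reject,
        },
        index=list(AOI_CODES),
    )


def net_flow(transitions: list[tuple[str, str]]) -> pd.DataFrame:
    """Entering/exiting classification of AOIs from a set of selected
    transitions.

    For each AOI: ``in_count`` transitions arriving, ``out_count``
    transitions departing, ``net`` their difference. Self-transitions are
    excluded from both counts (they would add one to each and cancel).
    Positive net -> entering, negative -> exiting, zero -> equilibrium.
    """
    in_c = pd.Series(0, index=list(AOI_CODES), dtype=int)
    out_c = pd.Series(0, index=list(AOI_CODES), dtype=int)
    for a, b in transitions:
        if a not in AOI_CODES or b not in AOI_CODES:
            raise SchemaError(f"unknown AOI code in transition {(a, b)!r}")
        if a == b:
            continue
        out_c[a] += 1
        in_c[b] += 1
    net = in_c - out_c
    cls = np.where(net > 0, "entering", np.where(net < 0, "exiting", "equilibrium"))
    return pd.DataFrame(
        {"in_count": in_c, "out_count": out_c, "net": net, "class": cls}
    )


def selected_transitions(model: PlsModel, sign: int | None = None) -> list[tuple[str, str]]:
    """Transition indicators retained by a fitted model, optionally
    restricted to one coefficient sign (+1 manual-associated, -1
    automated-associated)."""
    out = []
    for name, coef in model.coefficients.items():
        if not name.startswith("trans_"):
            continue
        if sign is not None and np.sign(coef) != sign:
            continue
        a, b = name[len("trans_"):].split("__")
        out.append((a, b))
    return out
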