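"""Oculometric indicators: dwell percentages, transition matrices, and
the assembly of design matrices for state prediction.

One trial (a participant in one driving condition) yields 182 indicators:

* 13 *static* indicators — the percentage of retained samples spent in
  each AOI, summing to 100; the RC entry is the percent-road-centre (PRC)
  metric;
* 169 *dynamic* indicators — the 13x13 matrix of transition
  probabilities between consecutive samples, self-transitions included,
  each row normalised by its outgoing-transition count.

Four design-matrix modes stack these per-unit indicators into a
units x indicators table: PRC (1 column), S (13 static), D (169
dynamic), DS (182 both). Columns are standardised (mean 0, sd 1 with
the n-1 denominator) before regression; zero-variance columns are
dropped and recorded by name.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    EmptyTrialError,
    InsufficientDataError,
    SchemaError,
)
from .reference import AOI_CODES

__all__ = [
    "LabeledSequence",
    "IndicatorSet",
    "DesignMatrix",
    "MODES",
    "static_column",
    "transition_column",
    "mode_columns",
    "dwell_percentages",
    "percent_road_centre",
    "transition_matrix",
    "indicator_set",
    "assemble_design",
    "standardize",
]

MODES = ("PRC", "S", "D", "DS")

_AOI_INDEX = {code: i for i, code in enumerate(AOI_CODES)}


def static_column(aoi: str) -> str:
    return f"static_{aoi}"


def transition_column(origin: str, dest: str) -> str:
    return f"trans_{origin}__{dest}"


def mode_columns(mode: str) -> list[str]:
    """Canonical column order of a design-matrix mode: static columns in
    canonical AOI order, then transitions in row-major origin x destination
    order."""
    static = [static_column(a) for a in AOI_CODES]
    trans = [transition_column(a, b) for a in AOI_CODES for b in AOI_CODES]
    if mode == "PRC":
        return ["prc"]
    if mode == "S":
        return static
    if mode == "D":
        return trans
    if mode == "DS":
        return static + trans
    raise SchemaError(f"unknown design mode: {mode!r} (expected one of {MODES})")


@dataclass(frozen=True)
class LabeledSequence:
    """One trial's ordered AOI labels at a fixed sampling rate.

    ``gaps`` holds retained-sample positions ``i`` such that the pair
    ``(i-1, i)`` straddles dropped data and must not be counted as a
    transition. ``condition`` is +1 for manual, -1 for automated driving,
    None when unknown.
    """

    labels: Sequence[str]
    rate: float = 20.0
    participant: object = None
    condition: int | None = None
    gaps: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise SchemaError("sampling rate must be positive")
        if len(self.labels) == 0:
            raise EmptyTrialError("labelled sequence is empty")
        unknown = set(self.labels) - set(AOI_CODES)
        if unknown:
            raise SchemaError(f"unknown AOI codes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> np.ndarray:
        """Labels as integer indices into the canonical AOI order."""
        return np.fromiter(
            (_AOI_INDEX[c] for c in self.labels), dtype=np.intp, count=len(self.labels)
        )

    @property
    def unit_id(self) -> tuple:
        return (self.participant, self.condition)


@dataclass(frozen=True)
class IndicatorSet:
    """Per-trial indicators: 13 dwell percentages, 13x13 transition
    probabilities, the PRC scalar, and per-row outgoing-transition counts."""

    static: pd.Series
    dynamic: pd.DataFrame
    prc: float
    row_support: pd.Series
    participant: object = None
    condition: int | None = None

    @property
    def unit_id(self) -> tuple:
        return (self.participant, self.condition)

    def as_row(self) -> pd.Series:
        """Flatten into the canonical DS column layout (static then
        transitions, row-major)."""
        values = {static_column(a): self.static[a] for a in AOI_CODES}
        for a in AOI_CODES:
            for b in AOI_CODES:
                values[transition_column(a, b)] = self.dynamic.loc[a, b]
        row = pd.Series(values, dtype=float)
        row["prc"] = self.prc
        return row


def dwell_percentages(seq: LabeledSequence) -> pd.Series:
    """Percentage of retained samples spent in each AOI; sums to 100."""
    counts = np.bincount(seq.codes, minlength=len(AOI_CODES)).astype(float)
    return pd.Series(100.0 * counts / counts.sum(), index=list(AOI_CODES))


def percent_road_centre(seq: LabeledSequence) -> float:
    """Percent road centre (PRC): dwell percentage of the RC disc."""
    return float(dwell_percentages(seq)["RC"])


def transition_matrix(seq: LabeledSequence) -> tuple[pd.DataFrame, pd.Series]:
    """Row-stochastic transition-probability matrix estimated from
    consecutive sample pairs, plus per-row outgoing-transition counts.

    Pairs straddling a recorded gap are not counted. Rows with zero
    support are left all-zero rather than filled with fabricated
    probabilities.
    """
    if len(seq) < 2:
        raise InsufficientDataError("need at least 2 samples for transitions")
    codes = seq.codes
    keep = np.ones(len(codes) - 1, dtype=bool)
    for g in seq.gaps:
        if 1 <= g < len(codes):
            keep[g - 1] = False
    src = codes[:-1][keep]
    dst = codes[1:][keep]
    if src.size == 0:
        raise InsufficientDataError("no countable transitions (all pairs gapped)")
    n = len(AOI_CODES)
    counts = np.zeros((n, n))
    np.add.at(counts, (src, dst), 1.0)
    support = counts.sum(axis=1)
    probs = np.divide(
        counts, support[:, None], out=np.zeros_like(counts), where=support[:, None] > 0
    )
    idx = list(AOI_CODES)
    return (
        pd.DataFrame(probs, index=idx, columns=idx),
        pd.Series(support.astype(int), index=idx),
    )


def indicator_set(seq: LabeledSequence, transition_level: str = "samples") -> IndicatorSet:
    """Compute the full indicator set of one trial.

    ``transition_level='samples'`` counts transitions between consecutive
    samples at the acquisition rate (self-transitions included);
    ``'runs'`` collapses runs of identical labels first, so only shifts
    between distinct AOIs are counted.
    """
    if transition_level not in ("samples", "runs"):
        raise SchemaError(f"unknown transition_level: {transition_level!r}")
    tseq = seq if transition_level == "samples" else _collapse_runs(seq)
    dynamic, support = transition_matrix(tseq)
    static = dwell_percentages(seq)
    return IndicatorSet(
        static=static,
        dynamic=dynamic,
        prc=float(static["RC"]),
        row_support=support,
        participant=seq.participant,
        condition=seq.condition,
    )


def _collapse_runs(seq: LabeledSequence) -> LabeledSequence:
    labels: list[str] = []
    gaps: set[int] = set()
    prev = None
    for i, lab in enumerate(seq.labels):
        broken = i in seq.gaps
        if lab != prev or broken:
            if broken and labels:
                gaps.add(len(labels))
            labels.append(lab)
        prev = lab if not broken else lab
    return replace(seq, labels=labels, gaps=frozenset(gaps))


@dataclass(frozen=True)
class DesignMatrix:
    """Units x indicators table in one of the four modes.

    ``values`` rows are ordered like ``unit_ids``; ``center``/``scale``
    are set after :func:`standardize` and allow applying the training
    transform to new data; ``dropped`` names zero-variance columns
    removed at standardisation.
    """

    mode: str
    unit_ids: tuple[tuple, ...]
    values: pd.DataFrame
    center: pd.Series | None = None
    scale: pd.Series | None = None
    dropped: tuple[str, ...] = ()

    @property
    def standardized(self) -> bool:
        return self.center is not None

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def transform(self, new_values: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored centring/scaling to raw rows (training-schema
        columns required; extra columns ignored)."""
        if not self.standardized:
            raise SchemaError("design matrix has no stored standardisation")
        missing = [c for c in self.columns if c not in new_values.columns]
        if missing:
            raise SchemaError(f"missing indicator columns: {missing[:5]}...")
        x = new_values[self.columns].astype(float)
        return (x - self.center) / self.scale


def assemble_design(
    trials: Iterable[IndicatorSet], mode: str = "DS"
) -> DesignMatrix:
    """Stack per-trial indicators into the units x indicators matrix of a
    mode (PRC: 1, S: 13, D: 169, DS: 182 columns)."""
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError("need at least 2 trials to assemble a design")
    cols = mode_columns(mode)
    rows = []
    for t in trials:
        if list(t.static.index) != list(AOI_CODES) or list(t.dynamic.index) != list(
            AOI_CODES
        ):
            raise SchemaError("trial indicator set does not use the canonical AOI set")
        rows.append(t.as_row()[cols])
    values = pd.DataFrame(rows).reset_index(drop=True)
    values.columns = cols
    return DesignMatrix(
        mode=mode,
        unit_ids=tuple(t.unit_id for t in trials),
        values=values,
    )


def standardize(dm: DesignMatrix) -> DesignMatrix:
    """Centre and reduce every column to mean 0, sd 1 (sample sd, n-1);
    zero-variance columns are dropped and recorded."""
    if len(dm.values) < 2:
        raise InsufficientDataError("need at least 2 rows to standardise")
    center = dm.values.mean(axis=0)
    scale = dm.values.std(axis=0, ddof=1)
    tol = 1e-12 * np.maximum(1.0, center.abs())
    constant = scale <= tol
    if constant.all():
        raise DegenerateDataError("all design columns have zero variance")
    keep = [c for c in dm.columns if not constant[c]]
    dropped = tuple(c for c in dm.columns if constant[c])
    values = (dm.values[keep] - center[keep]) / scale[keep]
    return DesignMatrix(
        mode=dm.mode,
        unit_ids=dm.unit_ids,
        values=values,
        center=center[keep],
        scale=scale[keep],
        dropped=dropped,
    )
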