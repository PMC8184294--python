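"""File round-trips for the pipeline's interchange formats.

All formats are plain text with fixed headers:

* gaze CSV — ``t,azimuth_deg,elevation_deg,quality``, one row per sample;
* labelled CSV — ``t,aoi`` with the 13 canonical AOI codes;
* indicator CSV — one row per unit: ``participant,condition,prc``,
  then ``static_<AOI>`` and ``trans_<FROM>__<TO>`` columns;
* model JSON — selected indicators, standardised-scale coefficients,
  intercept, component count, centring/scaling, cross-validation summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aoi import GazeRecord
from .errors import SchemaError
from .indicators import IndicatorSet, LabeledSequence, mode_columns
from .pls import CvReport, PlsModel

__all__ = [
    "write_gaze_csv",
    "read_gaze_csv",
    "write_labelled_csv",
    "read_labelled_csv",
    "write_indicator_csv",
    "read_indicator_csv",
    "save_model",
    "load_model",
]

GAZE_HEADER = ["t", "azimuth_deg", "elevation_deg", "quality"]
LABELLED_HEADER = ["t", "aoi"]


def write_gaze_csv(records: list[GazeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": [g.t for g in records],
            "azimuth_deg": [g.azimuth for g in records],
            "elevation_deg": [g.elevation for g in records],
            "quality": [g.quality for g in records],
        }
    ).to_csv(path, index=False)


def read_gaze_csv(path: str | Path) -> list[GazeRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != GAZE_HEADER:
        raise SchemaError(
            f"{path}: expected header {','.join(GAZE_HEADER)}, got {','.join(df.columns)}"
        )
    return [
        GazeRecord(t=float(r.t), azimuth=float(r.azimuth_deg),
                   elevation=float(r.elevation_deg), quality=float(r.quality))
        for r in df.itertuples(index=False)
    ]


def write_labelled_csv(seq: LabeledSequence, path: str | Path) -> None:
    t = np.arange(len(seq)) / seq.rate
    # re-insert the time hole at recorded gaps so a reader recovers them
    for g in sorted(seq.gaps):
        t[g:] += 1.0 / seq.rate
    pd.DataFrame({"t": t, "aoi": list(seq.labels)}).to_csv(path, index=False)


def read_labelled_csv(
    path: str | Path, *, participant=None, condition: int | None = None
) -> LabeledSequence:
    df = pd.read_csv(path)
    if list(df.columns) != LABELLED_HEADER:
        raise SchemaError(
            f"{path}: expected header {','.join(LABELLED_HEADER)}, got {','.join(df.columns)}"
        )
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        step = float(np.median(dt))
        if step <= 0:
            raise SchemaError(f"{path}: non-increasing timestamps")
        gaps = frozenset(int(i) + 1 for i in np.nonzero(dt > 1.5 * step)[0])
        rate = 1.0 / step
    else:
        gaps, rate = frozenset(), 20.0
    return LabeledSequence(
        labels=df["aoi"].astype(str).tolist(),
        rate=rate,
        participant=participant,
        condition=condition,
        gaps=gaps,
    )


def write_indicator_csv(sets: list[IndicatorSet], path: str | Path) -> None:
    cols = ["prc"] + mode_columns("DS")
    rows = []
    for s in sets:
        row = s.as_row()[cols]
        row["participant"] = s.participant
        row["condition"] = s.condition
        rows.append(row)
    df = pd.DataFrame(rows)[["participant", "condition"] + cols]
    df.to_csv(path, index=False)


def read_indicator_csv(path: str | Path) -> pd.DataFrame:
    """Indicator table with ``participant``/``condition`` metadata columns
    and the full canonical indicator layout."""
    df = pd.read_csv(path)
    expected = ["participant", "condition", "prc"] + mode_columns("DS")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing indicator columns {missing[:5]}...")
    return df[expected]


def save_model(model: PlsModel, path: str | Path, cv: CvReport | None = None) -> None:
    d = model.to_dict()
    d["cv"] = cv.to_dict() if cv is not None else None
    Path(path).write_text(json.dumps(d, indent=2))


def load_model(path: str | Path) -> tuple[PlsModel, dict | None]:
    try:
        d = json.loads(Path(path).read_text())
        return PlsModel.from_dict(d), d.get("cv")
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: malformed model file: {exc}") from exc
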