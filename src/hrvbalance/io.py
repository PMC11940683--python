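"""File formats: RR text/CSV, phase annotations, cohort, judgments, labels.

All CSVs are comma-separated UTF-8 with a mandatory header row and "." as
the decimal separator.  RR plain text carries one interval in ms per line
(the chest-strap export level).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .judgments import JudgmentMatrix
from .series import ArtifactLabels, PhaseAnnotation, RRSeries

__all__ = [
    "read_rr",
    "write_rr",
    "read_phases",
    "write_phases",
    "read_cohort",
    "write_cohort",
    "read_judgments",
    "write_judgments",
    "write_artifact_labels",
    "read_artifact_labels",
]


def read_rr(path: str | Path, format: str = "plain") -> RRSeries:
    """Read an RR series.

    ``format="plain"``: one interval (ms) per line.  ``format="csv"``:
    columns ``time_s, rr_ms``; beat times are validated against the
    cumulative interval sum.
    """
    path = Path(path)
    if format == "plain":
        intervals = []
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    continue
                try:
                    v = float(s)
                except ValueError:
                    raise ParseError(f"non-numeric RR interval {s!r}", line=ln) from None
                if v <= 0 or not np.isfinite(v):
                    raise ParseError(f"non-positive RR interval {v}", line=ln)
                intervals.append(v)
        if len(intervals) < 2:
            raise ParseError(f"{path.name}: need >= 2 intervals, found {len(intervals)}")
        return RRSeries(intervals=np.asarray(intervals))
    if format == "csv":
        df = pd.read_csv(path)
        for col in ("time_s", "rr_ms"):
            if col not in df.columns:
                raise ParseError(f"{path.name}: missing column {col!r}")
        rr = df["rr_ms"].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(rr) | (rr <= 0))
        if bad.size:
            raise ParseError("non-positive RR interval", line=int(bad[0]) + 2)
        t = df["time_s"].to_numpy(dtype=float)
        start = float(t[0]) - rr[0] / 1000.0
        return RRSeries(intervals=rr, start_s=start)
    raise ParseError(f"unknown RR format {format!r}")


def write_rr(series: RRSeries, path: str | Path, format: str = "plain") -> None:
    path = Path(path)
    if format == "plain":
        path.write_text(
            "\n".join(repr(float(v)) for v in series.intervals) + "\n", encoding="utf-8"
        )
    elif format == "csv":
        pd.DataFrame({"time_s": series.beat_times, "rr_ms": series.intervals}).to_csv(
            path, index=False
        )
    else:
        raise ParseError(f"unknown RR format {format!r}")


def read_phases(path: str | Path) -> tuple[PhaseAnnotation, ...]:
    df = pd.read_csv(path)
    return tuple(
        PhaseAnnotation(phase=r.phase, start_s=float(r.start_s), end_s=float(r.end_s))
        for r in df.itertuples()
    )


def write_phases(phases, path: str | Path) -> None:
    pd.DataFrame(
        [{"phase": p.phase, "start_s": p.start_s, "end_s": p.end_s} for p in phases]
    ).to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "gender", "log_pub"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_judgments(path: str | Path) -> JudgmentMatrix:
    return JudgmentMatrix.from_frame(pd.read_csv(path))


def write_judgments(jm: JudgmentMatrix, path: str | Path) -> None:
    jm.to_frame().to_csv(path, index=False)


def write_artifact_labels(labels: ArtifactLabels, path: str | Path) -> None:
    idx = labels.indices()
    pd.DataFrame({"index": idx, "category": labels.categories[idx]}).to_csv(
        path, index=False
    )


def read_artifact_labels(path: str | Path, n_beats: int) -> ArtifactLabels:
    df = pd.read_csv(path)
    cats = np.array(["normal"] * n_beats, dtype=object)
    cats[df["index"].to_numpy(dtype=int)] = df["category"].to_numpy(dtype=object)
    return ArtifactLabels(categories=cats)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")
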