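"""Bidimensional autonomic-balance analysis on the HF-LF plane.

Instead of collapsing LF and HF into their ratio, the (LF, HF) pair is
re-expressed as a power coordinate ``LHFP = LF + HF`` and a bounded balance
coordinate ``LHFND = (LF - HF) / (LF + HF)`` in [-1, 1] -- a normalized 45
degree rotation of the HF-LF plane.  The transform is a bijection between
``{lf >= 0, hf >= 0, lf + hf > 0}`` and ``{lhfp > 0, |lhfnd| <= 1}``:

    lf = lhfp (1 + lhfnd) / 2,      hf = lhfp (1 - lhfnd) / 2.

Qualitative state labels relative to a personal baseline follow the
plane-quadrant reading of autonomic stress/recovery states; thresholds use
a configurable dead zone so the labelling is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedIndexError

__all__ = [
    "BidimPoint",
    "STATE_LABELS",
    "to_bidim",
    "from_bidim",
    "phase_trajectory",
    "classify_state",
]

STATE_LABELS = (
    "physical_stress",
    "emotional_stress",
    "mental_stress",
    "recovery_rebound",
    "rest",
    "flow",
)


@dataclass(frozen=True)
class BidimPoint:
    """A point carrying both plane representations."""

    lf: float
    hf: float
    phase: str | None = None
    group: str | None = None

    def __post_init__(self):
        if self.lf < 0 or self.hf < 0:
            raise InvalidParameterError("band powers must be >= 0")
        if self.lf + self.hf <= 0:
            raise UndefinedIndexError("LF + HF must be > 0")

    @property
    def lhfp(self) -> float:
        return self.lf + self.hf

    @property
    def lhfnd(self) -> float:
        return (self.lf - self.hf) / (self.lf + self.hf)


def to_bidim(lf: float, hf: float) -> tuple[float, float]:
    """(LF, HF) -> (LHFP, LHFND)."""
    if lf < 0 or hf < 0:
        raise InvalidParameterError("band powers must be >= 0")
    s = lf + hf
    if s <= 0:
        raise UndefinedIndexError("LF + HF = 0: LHFND undefined")
    return s, (lf - hf) / s


def from_bidim(lhfp: float, lhfnd: float) -> tuple[float, float]:
    """(LHFP, LHFND) -> (LF, HF); exact inverse of :func:`to_bidim`."""
    if lhfp <= 0:
        raise InvalidParameterError("lhfp must be > 0")
    if abs(lhfnd) > 1:
        raise InvalidParameterError("|lhfnd| must be <= 1")
    return lhfp * (1.0 + lhfnd) / 2.0, lhfp * (1.0 - lhfnd) / 2.0


def phase_trajectory(
    features: pd.DataFrame, grouping: str | pd.Series | None = None
) -> pd.DataFrame:
    """Per group x phase centroids in both planes.

    ``features`` is the feature table (needs subject, phase, lf, hf, lhfp,
    lhfnd columns); ``grouping`` is a column name in ``features`` or a
    subject -> group mapping; ``None`` pools everyone into one group.

    The LHFND centroid is the mean of per-subject LHFND values, *not* the
    LHFND of the mean powers -- group balance averages the individual
    balance indices.
    """
    df = features.copy()
    if grouping is None:
        df["group"] = "all"
    elif isinstance(grouping, str):
        df["group"] = df[grouping]
    else:
        df["group"] = df["subject"].map(grouping)
    if df["group"].isna().any():
        raise InvalidParameterError("grouping leaves some subjects unassigned")
    df = df.dropna(subset=["lf", "hf"])
    if df.empty:
        raise InvalidParameterError("no usable feature rows")
    cent = (
        df.groupby(["group", "phase"], sort=False)[["lf", "hf", "lhfp", "lhfnd"]]
        .mean()
        .reset_index()
    )
    return cent


def classify_state(
    point: BidimPoint, baseline: BidimPoint, dead_zone: float = 0.20
) -> str:
    """Label an (LF, HF) point relative to a baseline.

    Each band is rated high / neutral / low against the baseline with a
    +-``dead_zone`` fractional band.  Quadrant reading: (high LF, low HF) is
    physical stress; (low, low) emotional stress; (high, high) the
    recovery/rebound onset; balanced neutral is rest.  With LF neutral, a
    moderate HF decrease (ratio in [0.5, 1 - dead_zone)) is the engaged
    "flow" state, while a strong HF collapse with no clear LF evidence is
    labelled mental stress.  Labels are invariant to rescaling point and
    baseline together.
    """
    if baseline.lf <= 0 or baseline.hf <= 0:
        raise InvalidParameterError("baseline powers must be positive")
    rl = point.lf / baseline.lf
    rh = point.hf / baseline.hf
    lo, hi = 1.0 - dead_zone, 1.0 + dead_zone

    def rate(r: float) -> str:
        return "high" if r > hi else ("low" if r < lo else "neutral")

    lf_c, hf_c = rate(rl), rate(rh)
    if hf_c == "low":
        if lf_c == "high":
            return "physical_stress"
        if lf_c == "low":
            return "emotional_stress"
        return "flow" if rh >= 0.5 else "mental_stress"
    if hf_c == "neutral":
        if lf_c == "neutral":
            return "rest"
        return "physical_stress" if lf_c == "high" else "emotional_stress"
    # hf high
    return "rest" if lf_c == "low" else "recovery_rebound"
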