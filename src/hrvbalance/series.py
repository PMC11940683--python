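"""Core containers: RR-interval series, phase annotations, recordings, tachograms.

Conventions
-----------
An :class:`RRSeries` stores the RR intervals in milliseconds.  Beat times are
the cumulative interval sums in seconds, offset by ``start_s``: interval *i*
ends at ``beat_times[i]``.  A file with intervals ``800, 810, 790`` therefore
yields beat times ``0.8, 1.61, 2.4`` s (origin at the beat opening the first
interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, TooShortError

#: Artifact label vocabulary (mutually exclusive per beat).
ARTIFACT_CATEGORIES = ("normal", "ectopic", "long_short", "missed", "extra", "misaligned")

PHASES = ("pre", "interview", "post")


@dataclass(frozen=True)
class RRSeries:
    """A beat-to-beat interval series.

    Parameters
    ----------
    intervals : ndarray
        RR intervals in ms, strictly positive, length >= 2.
    start_s : float
        Time (s) of the beat opening the first interval.
    """

    intervals: np.ndarray
    start_s: float = 0.0

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.ndim != 1 or iv.size < 2:
            raise TooShortError(f"RRSeries needs >= 2 intervals, got {iv.size}")
        if not np.all(np.isfinite(iv)) or np.any(iv <= 0):
            raise InvalidInputError("RR intervals must be finite and > 0 ms")

    @property
    def n_beats(self) -> int:
        return self.intervals.size

    @property
    def beat_times(self) -> np.ndarray:
        """Time (s) at which each interval ends."""
        return self.start_s + np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals) / 1000.0)

    @classmethod
    def from_beat_times(cls, times_s: np.ndarray, start_s: float | None = None) -> "RRSeries":
        """Build from beat times (s); ``start_s`` defaults to the first time minus
        the first inter-beat gap, i.e. intervals are successive differences."""
        t = np.asarray(times_s, dtype=float)
        if t.size < 2:
            raise TooShortError("need >= 2 beat times")
        iv = np.diff(t) * 1000.0
        t0 = t[0] - iv[0] / 1000.0 if start_s is None else start_s
        # prepend the first interval implied by start_s
        if start_s is not None:
            first = (t[0] - start_s) * 1000.0
            iv = np.concatenate([[first], iv])
            return cls(intervals=iv, start_s=start_s)
        return cls(intervals=np.concatenate([[iv[0]], iv[1:]]), start_s=t0)

    def crop(self, t0: float, t1: float) -> "RRSeries":
        """Return the sub-series of intervals ending in ``(t0, t1]``."""
        bt = self.beat_times
        mask = (bt > t0) & (bt <= t1)
        if mask.sum() < 2:
            raise TooShortError("fewer than 2 intervals in requested window")
        idx = np.flatnonzero(mask)
        new_start = bt[idx[0]] - self.intervals[idx[0]] / 1000.0
        return RRSeries(intervals=self.intervals[idx], start_s=new_start)


@dataclass(frozen=True)
class ArtifactLabels:
    """Per-beat artifact categories for an :class:`RRSeries`."""

    categories: np.ndarray  # dtype object/str, one of ARTIFACT_CATEGORIES

    def __post_init__(self):
        cats = np.asarray(self.categories, dtype=object)
        bad = set(cats) - set(ARTIFACT_CATEGORIES)
        if bad:
            raise InvalidInputError(f"unknown artifact categories: {bad}")
        object.__setattr__(self, "categories", cats)

    @property
    def corrected_pct(self) -> float:
        """Percentage of beats labelled non-normal."""
        n = self.categories.size
        return 100.0 * float(np.sum(self.categories != "normal")) / n if n else 0.0

    def indices(self, category: str | None = None) -> np.ndarray:
        if category is None:
            return np.flatnonzero(self.categories != "normal")
        return np.flatnonzero(self.categories == category)


@dataclass(frozen=True)
class PhaseAnnotation:
    """One protocol phase: name and [start_s, end_s) window."""

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.phase not in PHASES:
            raise InvalidInputError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.end_s > self.start_s:
            raise InvalidInputError("phase end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level metadata used as covariates/factors downstream."""

    subject_id: str
    age: float = float("nan")
    gender: str = "F"
    log_pub: float = float("nan")
    training: bool = False
    cluster: str | None = None  # ground-truth performance cluster when simulated


@dataclass(frozen=True)
class RRRecording:
    """A subject's full three-phase RR recording."""

    series: RRSeries
    phases: tuple[PhaseAnnotation, ...]
    meta: SubjectMeta

    def __post_init__(self):
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        names = [p.phase for p in phases]
        if names != list(PHASES):
            raise InvalidInputError(f"phases must be exactly {PHASES} in order, got {names}")
        for a, b in zip(phases, phases[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise InvalidInputError("phase annotations overlap")

    def phase(self, name: str) -> PhaseAnnotation:
        for p in self.phases:
            if p.phase == name:
                return p
        raise KeyError(name)

    def with_series(self, series: RRSeries) -> "RRRecording":
        return replace(self, series=series)


@dataclass(frozen=True)
class Tachogram:
    """Evenly sampled RR series (ms) on a uniform time grid."""

    values: np.ndarray  # ms
    sample_rate: float = 4.0  # Hz
    start_s: float = 0.0
    detrended: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("tachogram values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return (self.values.size - 1) / self.sample_rate if self.values.size else 0.0
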