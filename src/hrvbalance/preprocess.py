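"""RR-series cleaning: artifact detection/correction, resampling, detrending.

The artifact detector follows the architecture of quartile-deviation-scaled
adaptive thresholding: a beat is suspect when its successive difference
(dRR) or its deviation from a sliding local median (mRR) exceeds a multiple
of the local quartile deviation (QD = IQR/2) computed in a sliding window.
Suspects are then classified as missed / extra / ectopic / misaligned /
long-short and corrected in a way that conserves total elapsed time exactly
(corrections only redistribute time inside adjacent interval pairs, split
one interval, or merge a pair).

Detrending uses the smoothness-priors operator: the trend is
``(I + lambda^2 D2' D2)^{-1} y`` with D2 the second-difference matrix — a
tunable high-pass filter whose cutoff at the default ``lam = 500`` and 4 Hz
sampling lies near 0.035 Hz, leaving the LF and HF bands essentially intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded

from .errors import InvalidInputError, SegmentUnavailableError, TooShortError
from .series import ArtifactLabels, PhaseAnnotation, RRRecording, RRSeries, Tachogram

__all__ = [
    "ArtifactRuleConfig",
    "CorrectionWarning",
    "detect_and_correct_artifacts",
    "resample_tachogram",
    "detrend_smoothness_priors",
    "extract_phase_segment",
]


class CorrectionWarning(UserWarning):
    """Raised (as a warning) when the corrected-beat percentage reaches 5 %."""


@dataclass(frozen=True)
class ArtifactRuleConfig:
    """Constants of the detection/classification rule (all configurable)."""

    qd_window: int = 91  # beats, sliding quartile-deviation window
    median_window: int = 11  # beats, local median window
    threshold: float = 5.2  # QD multiples flagging a suspect beat
    missed_ratio: tuple[float, float] = (1.7, 2.3)  # RR/median range for a merged pair
    extra_tol: float = 0.3  # |RR_i + RR_{i+1} - median| <= tol * median
    warn_pct: float = 5.0  # corrected-beat percentage triggering a warning


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def _rolling_qd(x: np.ndarray, window: int) -> np.ndarray:
    """Sliding quartile deviation (IQR/2), windows truncated at the edges."""
    s = pd.Series(x)
    q75 = s.rolling(window, center=True, min_periods=5).quantile(0.75)
    q25 = s.rolling(window, center=True, min_periods=5).quantile(0.25)
    qd = ((q75 - q25) / 2.0).to_numpy()
    return np.nan_to_num(qd, nan=np.nanmedian(qd) if np.isfinite(np.nanmedian(qd)) else 0.0)


def _spline_estimate(rr: np.ndarray, good: np.ndarray, i: int, med: float) -> float:
    """Cubic-spline estimate of interval i from surrounding good intervals."""
    idx = np.flatnonzero(good)
    left = idx[idx < i][-4:]
    right = idx[idx > i][:4]
    support = np.concatenate([left, right])
    if support.size >= 4:
        try:
            est = float(CubicSpline(support.astype(float), rr[support])(float(i)))
        except ValueError:
            est = med
    else:
        est = med
    # keep the estimate physiological relative to the local median
    return float(np.clip(est, 0.5 * med, 1.5 * med))


def detect_and_correct_artifacts(
    rr: RRSeries,
    config: ArtifactRuleConfig | None = None,
) -> tuple[RRSeries, ArtifactLabels]:
    """Detect and correct ectopic/missed/extra/misaligned beats.

    Returns the corrected series and per-beat labels *on the input series*.
    Total elapsed time is conserved exactly: every correction merges, splits,
    or redistributes time within adjacent intervals.  A
    :class:`CorrectionWarning` is emitted when >= 5 % of beats are corrected.
    """
    cfg = config or ArtifactRuleConfig()
    x = rr.intervals
    n = x.size
    if n < 20:
        raise TooShortError("artifact correction needs >= 20 beats")
    if np.any(x <= 0):
        raise InvalidInputError("non-positive RR interval")

    drr = np.diff(x, prepend=x[0])  # dRR_0 = 0
    med = _rolling_median(x, cfg.median_window)
    mrr = x - med
    thr_d = cfg.threshold * _rolling_qd(drr, cfg.qd_window)
    thr_m = cfg.threshold * _rolling_qd(mrr, cfg.qd_window)
    suspect = (np.abs(drr) > thr_d) | (np.abs(mrr) > thr_m)
    suspect_m_only = (np.abs(mrr) > thr_m) & ~(np.abs(drr) > thr_d)

    labels = np.array(["normal"] * n, dtype=object)
    good = ~suspect

    # classification pass (input indexing); corrections recorded as edit ops
    ops: list[tuple[str, int, float]] = []  # (kind, index, payload)
    i = 0
    while i < n:
        if not suspect[i] or labels[i] != "normal":
            i += 1
            continue
        # dRR "echo": the step after a corrected beat is suspect only through
        # dRR while its own interval is locally unremarkable -- skip it.
        if (
            i > 0
            and labels[i - 1] != "normal"
            and not (np.abs(mrr[i]) > thr_m[i])
        ):
            i += 1
            continue
        # smoothness veto: artifacts are impulsive, so a deviation shared in
        # sign and magnitude by BOTH neighbours is oscillatory physiology
        # (e.g. a strong LF trough outrunning the local median), not a beat
        # error.  Never vetoes ectopic/misaligned pairs (antisymmetric) or
        # missed/extra beats (isolated / one-sided).
        if (
            0 < i < n - 1
            and not (np.abs(drr[i]) > thr_d[i])
            and np.sign(mrr[i - 1]) == np.sign(mrr[i]) == np.sign(mrr[i + 1])
            and min(abs(mrr[i - 1]), abs(mrr[i + 1])) > 0.4 * abs(mrr[i])
        ):
            i += 1
            continue
        ratio = x[i] / med[i] if med[i] > 0 else np.inf
        pair_ok = i + 1 < n
        if cfg.missed_ratio[0] <= ratio <= cfg.missed_ratio[1]:
            labels[i] = "missed"
            ops.append(("split", i, 0.5))
            i += 1
        elif pair_ok and abs(x[i] + x[i + 1] - med[i]) <= cfg.extra_tol * med[i]:
            labels[i] = "extra"
            labels[i + 1] = "extra"
            ops.append(("merge", i, 0.0))
            i += 2
        elif (
            pair_ok
            and suspect[i + 1]
            and (x[i] - med[i]) * (x[i + 1] - med[i + 1]) < 0
        ):
            # short-long or long-short alternation with compensation
            labels[i] = "ectopic"
            labels[i + 1] = "ectopic"
            ops.append(("redistribute", i, 0.0))
            i += 2
        elif suspect_m_only[i] and (ratio > 1.3 or ratio < 0.7):
            labels[i] = "long_short"
            ops.append(("redistribute", i, 0.0))
            i += 1
        else:
            labels[i] = "misaligned"
            if pair_ok:
                labels[i + 1] = (
                    "misaligned" if suspect[i + 1] and labels[i + 1] == "normal" else labels[i + 1]
                )
                ops.append(("redistribute", i, 0.0))
            i += 1

    # apply edits right-to-left so earlier indices stay valid
    out = list(x)
    for kind, i, payload in reversed(ops):
        if kind == "split":
            total = out[i]
            out[i : i + 1] = [total * payload, total * (1.0 - payload)]
        elif kind == "merge":
            out[i : i + 2] = [out[i] + out[i + 1]]
        else:  # redistribute within (i, i+1), conserving their sum
            if i + 1 >= len(out):
                continue
            total = out[i] + out[i + 1]
            est = _spline_estimate(x, good, i, med[i])
            est = float(np.clip(est, 0.1 * total, 0.9 * total))
            out[i] = est
            out[i + 1] = total - est

    corrected = RRSeries(intervals=np.asarray(out, dtype=float), start_s=rr.start_s)
    art = ArtifactLabels(categories=labels)
    if art.corrected_pct >= cfg.warn_pct:
        warnings.warn(
            f"corrected {art.corrected_pct:.1f}% of beats (>= {cfg.warn_pct}%)",
            CorrectionWarning,
            stacklevel=2,
        )
    return corrected, art


def resample_tachogram(rr: RRSeries, sample_rate: float = 4.0) -> Tachogram:
    """Cubic-spline resample the RR series onto an even grid.

    Intervals are interpolated against their beat times and evaluated on
    ``t_first, t_first + 1/fs, ...`` up to the last beat (no extrapolation).
    """
    if rr.n_beats < 4:
        raise TooShortError("resampling needs >= 4 beats")
    t = rr.beat_times
    n_grid = int(np.floor((t[-1] - t[0]) * sample_rate)) + 1
    grid = t[0] + np.arange(n_grid) / sample_rate
    spline = CubicSpline(t, rr.intervals)
    return Tachogram(values=spline(grid), sample_rate=sample_rate, start_s=t[0])


def _smoothness_priors_trend(y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (I + lam^2 D2' D2) trend = y via a banded Cholesky solve."""
    n = y.size
    if lam == 0:
        return y.copy()
    # Pentadiagonal symmetric matrix I + lam^2 D2'D2 in upper-banded storage.
    l2 = lam * lam
    ab = np.zeros((3, n))
    # main diagonal of D2'D2: pattern 1, 5, 6, 6, ..., 6, 5, 1
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    if n > 1:
        d0[[1, -2]] = 5.0
    # first off-diagonal: -2, -4, -4, ..., -4, -2
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.full(n - 2, 1.0)
    ab[2, :] = 1.0 + l2 * d0
    ab[1, 1:] = l2 * d1
    ab[0, 2:] = l2 * d2
    return solveh_banded(ab, y, lower=False)


def detrend_smoothness_priors(
    tach: Tachogram, lam: float = 500.0
) -> tuple[Tachogram, Tachogram]:
    """Split a tachogram into (trend, residual) with the smoothness-priors filter.

    ``trend = (I + lam^2 D2' D2)^{-1} values``; residual = values - trend.
    ``lam = 0`` reproduces the input exactly (identity trend); straight lines
    lie in the null space of D2 and are returned as pure trend.
    """
    y = tach.values
    if y.size < 3:
        raise TooShortError("detrending needs >= 3 samples")
    trend = _smoothness_priors_trend(y, float(lam))
    residual = y - trend
    mk = dict(sample_rate=tach.sample_rate, start_s=tach.start_s)
    return (
        Tachogram(values=trend, detrended=False, **mk),
        Tachogram(values=residual, detrended=True, **mk),
    )


def extract_phase_segment(
    recording: RRRecording,
    phase: str,
    preferred_s: float = 300.0,
    fallback_s: float = 180.0,
) -> tuple[RRSeries, float, bool]:
    """Extract the centered analysis window of a phase.

    Returns ``(segment, window_s, used_fallback)``.  A window of
    ``preferred_s`` (or ``fallback_s`` when the phase is shorter) is centered
    on the phase; phases shorter than ``fallback_s`` raise
    :class:`SegmentUnavailableError`.
    """
    ann: PhaseAnnotation = recording.phase(phase)
    dur = ann.duration_s
    if dur >= preferred_s:
        window, fallback = preferred_s, False
    elif dur >= fallback_s:
        window, fallback = fallback_s, True
    else:
        raise SegmentUnavailableError(
            f"phase {phase!r} lasts {dur:.0f}s < fallback {fallback_s:.0f}s"
        )
    mid = 0.5 * (ann.start_s + ann.end_s)
    seg = recording.series.crop(mid - window / 2.0, mid + window / 2.0)
    return seg, window, fallback
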