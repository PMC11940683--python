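"""Time-domain and frequency-domain HRV features per phase segment.

Frequency-domain analysis uses Welch's averaged periodogram on the
detrended 4 Hz tachogram (Hann taper, 300 s windows, 50 % overlap; a single
full-length window when the segment is shorter).  Band powers are the
trapezoidal integrals of the one-sided density over the conventional
short-term bands: VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.

Derived balance indices:

* normalized units   ``LFnu = 100 * LF / (LF + HF)`` (and symmetrically HFnu);
* ``LHFP  = LF + HF``   -- combined oscillatory power (ms^2);
* ``LHFND = (LF - HF) / (LF + HF)`` -- bounded, symmetric balance index,
  identically ``(LFnu - HFnu) / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .errors import TooShortError, UndefinedIndexError
from .series import RRRecording, RRSeries, Tachogram
from . import preprocess

__all__ = [
    "SpectralEstimate",
    "BandPowers",
    "DEFAULT_BANDS",
    "time_domain_features",
    "welch_psd",
    "band_powers",
    "compute_feature_table",
    "FEATURE_COLUMNS",
]

#: Short-term band edges in Hz (VLF lower edge per short-term convention).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

FEATURE_COLUMNS = [
    "subject",
    "phase",
    "mean_rr",
    "mean_hr",
    "hr_range",
    "sdnn",
    "vlf",
    "lf",
    "hf",
    "total",
    "lf_nu",
    "hf_nu",
    "lf_hf",
    "lhfp",
    "lhfnd",
    "seg_s",
    "flags",
]


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided PSD of a tachogram segment (ms^2/Hz)."""

    freqs: np.ndarray
    density: np.ndarray
    window_s: float
    overlap: float
    taper: str = "hann"
    single_window: bool = False  # True when the segment was shorter than window_s

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "density", d)
        if f.shape != d.shape:
            raise ValueError("freqs and density must have identical shape")
        if np.any(d < -1e-12):
            raise ValueError("spectral density must be non-negative")


@dataclass(frozen=True)
class BandPowers:
    """VLF/LF/HF/total powers (ms^2) plus derived balance indices."""

    vlf: float
    lf: float
    hf: float

    @property
    def total(self) -> float:
        return self.vlf + self.lf + self.hf

    @property
    def lhfp(self) -> float:
        return self.lf + self.hf

    def _check(self):
        if self.lf + self.hf <= 0:
            raise UndefinedIndexError("LF + HF = 0: normalized indices undefined")

    @property
    def lf_nu(self) -> float:
        self._check()
        return 100.0 * self.lf / (self.lf + self.hf)

    @property
    def hf_nu(self) -> float:
        self._check()
        return 100.0 * self.hf / (self.lf + self.hf)

    @property
    def lf_hf_ratio(self) -> float:
        self._check()
        return self.lf / self.hf if self.hf > 0 else float("inf")

    @property
    def lhfnd(self) -> float:
        self._check()
        return (self.lf - self.hf) / (self.lf + self.hf)


def time_domain_features(segment: RRSeries) -> tuple[float, float, float, float]:
    """Return ``(mean_rr ms, mean_hr bpm, hr_range bpm, sdnn ms)``.

    ``mean_hr`` is the mean of instantaneous HR ``60000 / RR_i``;
    ``hr_range`` is max - min of instantaneous HR; ``sdnn`` uses the n-1
    denominator.
    """
    rr = segment.intervals
    if rr.size < 10:
        raise TooShortError("time-domain features need >= 10 beats")
    hr = 60000.0 / rr
    return (
        float(np.mean(rr)),
        float(np.mean(hr)),
        float(np.max(hr) - np.min(hr)),
        float(np.std(rr, ddof=1)),
    )


def welch_psd(
    tach: Tachogram, window_s: float = 300.0, overlap: float = 0.5
) -> SpectralEstimate:
    """Welch PSD of a tachogram (Hann taper, density normalization).

    The integral of the density over [0, fs/2] approximates the segment
    variance (Parseval, within taper bias).  Segments shorter than
    ``window_s`` fall back to a single full-length window, flagged via
    ``single_window``.
    """
    x = tach.values
    fs = tach.sample_rate
    if x.size / fs < 60.0:
        raise TooShortError("spectral estimation needs >= 60 s of signal")
    nperseg = int(round(window_s * fs))
    single = x.size < nperseg
    if single:
        nperseg = x.size
    freqs, density = welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(
        freqs=freqs,
        density=density,
        window_s=nperseg / fs,
        overlap=overlap,
        single_window=single,
    )


def band_powers(
    spec: SpectralEstimate, bands: dict[str, tuple[float, float]] | None = None
) -> BandPowers:
    """Integrate the PSD over VLF/LF/HF bands (trapezoidal rule)."""
    bands = bands or DEFAULT_BANDS
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (spec.freqs >= lo) & (spec.freqs <= hi)
        if mask.sum() < 2:
            out[name] = 0.0
        else:
            out[name] = float(np.trapezoid(spec.density[mask], spec.freqs[mask]))
    return BandPowers(vlf=out["vlf"], lf=out["lf"], hf=out["hf"])


def _segment_features(
    recording: RRRecording,
    phase: str,
    lam: float,
    sample_rate: float,
    window_s: float,
    overlap: float,
    preferred_s: float,
    fallback_s: float,
    quality_gate_pct: float,
) -> dict:
    seg, window, fallback = preprocess.extract_phase_segment(
        recording, phase, preferred_s=preferred_s, fallback_s=fallback_s
    )
    corrected, labels = preprocess.detect_and_correct_artifacts(seg)
    flags = []
    if fallback:
        flags.append("fallback_window")
    if labels.corrected_pct >= quality_gate_pct:
        flags.append("excluded_corrected_pct")
    mean_rr, mean_hr, hr_range, sdnn = time_domain_features(corrected)
    tach = preprocess.resample_tachogram(corrected, sample_rate=sample_rate)
    _, residual = preprocess.detrend_smoothness_priors(tach, lam=lam)
    spec = welch_psd(residual, window_s=window_s, overlap=overlap)
    if spec.single_window and window < window_s:
        # genuine fallback segment; nominal-length segments always lose a
        # fraction of a second to beat alignment and are not flagged
        flags.append("single_window")
    bp = band_powers(spec)
    return {
        "mean_rr": mean_rr,
        "mean_hr": mean_hr,
        "hr_range": hr_range,
        "sdnn": sdnn,
        "vlf": bp.vlf,
        "lf": bp.lf,
        "hf": bp.hf,
        "total": bp.total,
        "lf_nu": bp.lf_nu,
        "hf_nu": bp.hf_nu,
        "lf_hf": bp.lf_hf_ratio,
        "lhfp": bp.lhfp,
        "lhfnd": bp.lhfnd,
        "seg_s": window,
        "flags": ";".join(flags),
    }


def compute_feature_table(
    recordings: list[RRRecording],
    lam: float = 500.0,
    sample_rate: float = 4.0,
    window_s: float = 300.0,
    overlap: float = 0.5,
    preferred_s: float = 300.0,
    fallback_s: float = 180.0,
    quality_gate_pct: float = 5.0,
) -> pd.DataFrame:
    """One row per subject x phase; failures are flagged, never dropped.

    Rows whose segment cannot be analyzed carry NaN features and a reason in
    ``flags`` (machine-readable, semicolon-separated).
    """
    rows = []
    for rec in recordings:
        for ann in rec.phases:
            row = {"subject": rec.meta.subject_id, "phase": ann.phase}
            try:
                row.update(
                    _segment_features(
                        rec,
                        ann.phase,
                        lam,
                        sample_rate,
                        window_s,
                        overlap,
                        preferred_s,
                        fallback_s,
                        quality_gate_pct,
                    )
                )
            except Exception as exc:  # recorded per-row, pipeline continues
                row.update({c: np.nan for c in FEATURE_COLUMNS[2:-1]})
                row["flags"] = f"error:{type(exc).__name__}"
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
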