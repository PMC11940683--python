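"""Synthetic three-phase RR recordings, artifact injection, and jury ratings.

The generator emulates the study design the analysis layer assumes: a
pre-interview baseline (5 min), a live-interview stressor (10 min) and a
post-interview recovery (5 min).  RR series are produced by an integral
pulse frequency modulation (IPFM) model so that their spectral content is
known analytically: a low-frequency (LF, ~0.10 Hz) and a high-frequency
(HF, ~0.25 Hz, respiratory) sinusoidal modulator with chosen amplitudes, so
that band-integrated power targets a^2/2 per component.

Default phase targets are calibrated to published short-term HRV values for
a seated TV-interview protocol: mean RR 680/586/708 ms and LF power
643/449/1088 ms^2, HF 295/232/373 ms^2 across pre/interview/post, with the
post-interview rebound exceeding both earlier phases.

Jury ratings are generated from a two-latent-factor model (a "Content" and
a "Performance" factor) over six Likert dimensions, so that factor-recovery
of the analysis layer can be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, TooShortError
from .judgments import DIMENSIONS, LIKERT_MAX, LIKERT_MIN, JudgmentMatrix
from .series import (
    ArtifactLabels,
    PHASES,
    PhaseAnnotation,
    RRRecording,
    RRSeries,
    SubjectMeta,
)

__all__ = [
    "ModulatorSpec",
    "ProtocolConfig",
    "ArtifactSpec",
    "JuryConfig",
    "CohortConfig",
    "ipfm_beat_times",
    "simulate_recording",
    "inject_artifacts",
    "simulate_jury",
    "simulate_cohort",
    "TABLE_PHASE_TARGETS",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def _amp_for_power(power_ms2: float) -> float:
    """Sinusoid amplitude (ms) whose band power is ``power_ms2`` (a^2/2)."""
    return math.sqrt(2.0 * power_ms2)


@dataclass(frozen=True)
class ModulatorSpec:
    """Oscillatory structure of the instantaneous RR modulator.

    ``lf_phase``/``hf_phase`` default to ``None`` meaning "draw uniformly at
    random" in seeded generators; set them explicitly for fully pinned output.
    """

    mean_rr: float  # ms
    lf_amp: float = 0.0  # ms
    hf_amp: float = 0.0  # ms
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    noise_sd: float = 0.0  # ms, broadband
    lf_phase: float | None = None  # rad
    hf_phase: float | None = None  # rad

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be > 0 ms")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise InvalidParameterError("amplitudes and noise_sd must be >= 0")
        if not (LF_BAND[0] <= self.lf_freq < LF_BAND[1]):
            raise InvalidParameterError(f"lf_freq must lie in [{LF_BAND[0]}, {LF_BAND[1]})")
        if not (HF_BAND[0] <= self.hf_freq <= HF_BAND[1]):
            raise InvalidParameterError(f"hf_freq must lie in [{HF_BAND[0]}, {HF_BAND[1]}]")


#: Phase-wise (mean RR ms, LF power ms^2, HF power ms^2) calibration targets
#: for the whole cohort: interview shortening of RR with an oscillatory-power
#: drop, and a post-interview rebound above baseline.
TABLE_PHASE_TARGETS: dict[str, tuple[float, float, float]] = {
    "pre": (680.0, 643.0, 295.0),
    "interview": (586.0, 449.0, 232.0),
    "post": (708.0, 1088.0, 373.0),
}

#: Default phase durations (s): 5 min pre, 10 min interview, 5 min post.
DEFAULT_DURATIONS: dict[str, float] = {"pre": 300.0, "interview": 600.0, "post": 300.0}

DEFAULT_NOISE_SD = 5.0  # ms broadband modulator noise


def _default_phase_specs() -> dict[str, tuple[float, ModulatorSpec]]:
    specs = {}
    for phase in PHASES:
        rr, lf, hf = TABLE_PHASE_TARGETS[phase]
        specs[phase] = (
            DEFAULT_DURATIONS[phase],
            ModulatorSpec(
                mean_rr=rr,
                lf_amp=_amp_for_power(lf),
                hf_amp=_amp_for_power(hf),
                noise_sd=DEFAULT_NOISE_SD,
            ),
        )
    return specs


@dataclass(frozen=True)
class ProtocolConfig:
    """Ordered phase -> (duration_s, ModulatorSpec) map; exactly pre/interview/post."""

    phase_specs: dict[str, tuple[float, ModulatorSpec]] = field(
        default_factory=_default_phase_specs
    )

    def __post_init__(self):
        if tuple(self.phase_specs) != PHASES:
            raise InvalidParameterError(f"phases must be exactly {PHASES} in order")
        for phase, (dur, spec) in self.phase_specs.items():
            if dur <= 0:
                raise InvalidParameterError(f"duration of phase {phase!r} must be > 0")
            if not isinstance(spec, ModulatorSpec):
                raise InvalidParameterError("phase_specs values must be (duration, ModulatorSpec)")

    @property
    def total_duration_s(self) -> float:
        return sum(d for d, _ in self.phase_specs.values())


@dataclass(frozen=True)
class ArtifactSpec:
    """Per-category beat corruption rates; total must stay below 5 %.

    The default mix reflects a chest-strap error profile where detection
    dropouts (missed) and spurious triggers (extra) plus ectopy dominate,
    and small timing misalignments are rare.
    """

    ectopic: float = 0.012
    missed: float = 0.008
    extra: float = 0.008
    misaligned: float = 0.002

    def __post_init__(self):
        rates = (self.ectopic, self.missed, self.extra, self.misaligned)
        if any(r < 0 for r in rates):
            raise InvalidParameterError("artifact rates must be >= 0")
        if sum(rates) >= 0.05:
            raise InvalidParameterError("total artifact rate must be < 0.05")

    @property
    def total(self) -> float:
        return self.ectopic + self.missed + self.extra + self.misaligned

    def as_dict(self) -> dict[str, float]:
        return {
            "ectopic": self.ectopic,
            "missed": self.missed,
            "extra": self.extra,
            "misaligned": self.misaligned,
        }


# Rotated two-factor loading pattern for the six judgment dimensions
# (rows follow judgments.DIMENSIONS): factor 1 "Content" is carried by
# Interest/Agreement, factor 2 "Performance" by Authoritativeness, Learning
# and Clarity; Engagement splits over both.
DEFAULT_LOADINGS = np.array(
    [
        [0.943, 0.164],  # Interest
        [0.864, 0.158],  # Agreement
        [0.716, 0.525],  # Engagement
        [0.118, 0.823],  # Authoritativeness
        [0.172, 0.790],  # Learning
        [0.310, 0.779],  # Clarity
    ]
)

DEFAULT_DIM_MEANS = np.array([3.269, 3.380, 3.456, 3.499, 3.680, 3.921])


@dataclass(frozen=True)
class JuryConfig:
    """Two-latent-factor rating generator configuration."""

    n_raters: int = 26
    n_communicators: int = 30
    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    dim_means: np.ndarray = field(default_factory=lambda: DEFAULT_DIM_MEANS.copy())
    comm_sd: float = 0.25  # communicator-level latent scale (rating units)
    rater_bias_sd: float = 0.30
    residual_sd: float = 0.50
    round_ratings: bool = False  # Likert means are analyzed continuously

    def __post_init__(self):
        L = np.asarray(self.loadings, dtype=float)
        m = np.asarray(self.dim_means, dtype=float)
        object.__setattr__(self, "loadings", L)
        object.__setattr__(self, "dim_means", m)
        if L.shape != (len(DIMENSIONS), 2):
            raise InvalidParameterError(f"loadings must be {len(DIMENSIONS)} x 2")
        communality = np.sum(L**2, axis=1)
        if np.any(communality > 1.0 + 1e-9):
            raise InvalidParameterError(
                "loadings imply communality > 1 (implied correlation not positive definite)"
            )
        if m.shape != (len(DIMENSIONS),) or np.any(m < LIKERT_MIN) or np.any(m > LIKERT_MAX):
            raise InvalidParameterError("dimension means must lie within [1, 5]")
        if self.n_raters < 2 or self.n_communicators < 3:
            raise InvalidParameterError("need >= 2 raters and >= 3 communicators")


#: Per-cluster phase calibration.  The low-Authority (LA) group shows the
#: full stress/recovery excursion (LF drop of ~692 ms^2 into the interview,
#: rebound of ~1344 ms^2 after), the high-Authority (HA) group stays nearly
#: flat in LF power with a milder RR response.
CLUSTER_PHASE_TARGETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "LA": {
        "pre": (730.0, 900.0, 330.0),
        "interview": (600.0, 208.0, 200.0),
        "post": (740.0, 1552.0, 420.0),
    },
    "HA": {
        "pre": (650.0, 550.0, 300.0),
        "interview": (600.0, 550.0, 260.0),
        "post": (680.0, 560.0, 330.0),
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator: cluster mix, phase targets per cluster, covariates."""

    n_subjects: int = 24
    cluster_fractions: dict[str, float] = field(
        default_factory=lambda: {"LA": 0.5, "HA": 0.5}
    )
    phase_targets: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLUSTER_PHASE_TARGETS.items()}
    )
    age_mean: float = 52.64
    age_sd: float = 9.0
    log_pub_mean: float = 3.9231
    log_pub_sd: float = 0.8
    female_fraction: float = 0.56
    subject_amp_sd: float = 0.15  # lognormal sd of per-subject trait amplitude factor
    phase_amp_sd: float = 0.20  # lognormal sd of per-phase state amplitude factor
    rr_offset_sd: float = 25.0  # ms, per-subject mean-RR shift
    artifact_spec: ArtifactSpec | None = None  # None -> clean recordings

    def __post_init__(self):
        if self.n_subjects < 6:
            raise InvalidParameterError("n_subjects must be >= 6")
        fr = self.cluster_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-9 or any(f <= 0 for f in fr.values()):
            raise InvalidParameterError("cluster fractions must be positive and sum to 1")
        if set(fr) != set(self.phase_targets):
            raise InvalidParameterError("cluster_fractions and phase_targets keys must match")


# ---------------------------------------------------------------------------
# IPFM beat generator
# ---------------------------------------------------------------------------

def ipfm_beat_times(
    mod: ModulatorSpec,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    dt: float = 0.125,
) -> np.ndarray:
    """Generate beat times (s) from an IPFM model of the RR modulator.

    The instantaneous rate is ``r(t) = 1000 / (mean_rr + m(t))`` beats/s with
    ``m(t)`` the summed LF/HF sinusoids plus broadband noise (white on the
    modulator, sampled at 4 Hz and linearly interpolated).  A beat is emitted
    each time the running integral of ``r`` crosses an integer threshold
    (threshold 1.0, crossing times located by linear interpolation), so beat
    placement is grid-free.  To first order the resulting RR series equals
    ``mean_rr + m(t)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if duration_s <= 0 or mod.mean_rr <= 0:
        raise InvalidParameterError("duration_s and mean_rr must be positive")
    if duration_s < 10.0 * mod.mean_rr / 1000.0:
        raise InvalidParameterError("duration must cover at least 10 mean RR intervals")

    lf_phase = rng.uniform(0, 2 * np.pi) if mod.lf_phase is None else mod.lf_phase
    hf_phase = rng.uniform(0, 2 * np.pi) if mod.hf_phase is None else mod.hf_phase

    t = np.arange(0.0, duration_s + dt, dt)
    m = mod.lf_amp * np.sin(2 * np.pi * mod.lf_freq * t + lf_phase)
    m = m + mod.hf_amp * np.sin(2 * np.pi * mod.hf_freq * t + hf_phase)
    if mod.noise_sd > 0:
        # white noise on a 4 Hz grid, linearly interpolated onto the fine grid
        tn = np.arange(0.0, duration_s + 0.25, 0.25)
        noise = rng.normal(0.0, mod.noise_sd, size=tn.size)
        m = m + np.interp(t, tn, noise)

    rr_inst = np.maximum(mod.mean_rr + m, 0.2 * mod.mean_rr)  # guard against negative RR
    rate = 1000.0 / rr_inst  # beats per second

    # cumulative trapezoid integral of the rate
    integral = np.empty_like(t)
    integral[0] = 0.0
    np.cumsum((rate[1:] + rate[:-1]) * (0.5 * dt), out=integral[1:])

    n_beats = int(np.floor(integral[-1]))
    if n_beats < 2:
        raise InvalidParameterError("duration too short to emit two beats")
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    # locate integer crossings by inverse linear interpolation
    beat_times = np.interp(thresholds, integral, t)
    return beat_times


def simulate_recording(
    protocol: ProtocolConfig | None = None,
    subject: SubjectMeta | None = None,
    seed: int | np.random.Generator = 0,
) -> RRRecording:
    """Simulate one subject's contiguous three-phase recording."""
    protocol = protocol or ProtocolConfig()
    subject = subject or SubjectMeta(subject_id="sim")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    all_intervals = []
    annotations = []
    t0 = 0.0
    for phase, (dur, spec) in protocol.phase_specs.items():
        beats = ipfm_beat_times(spec, dur, seed=rng)
        rr = np.diff(np.concatenate([[0.0], beats])) * 1000.0
        all_intervals.append(rr)
        annotations.append(PhaseAnnotation(phase=phase, start_s=t0, end_s=t0 + dur))
        t0 += dur
    series = RRSeries(intervals=np.concatenate(all_intervals), start_s=0.0)
    return RRRecording(series=series, phases=tuple(annotations), meta=subject)


# ---------------------------------------------------------------------------
# Artifact injection with ground truth
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Draw k positions in [2, n-3], no two adjacent (gap >= 2)."""
    candidates = rng.permutation(np.arange(2, n - 2))
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in candidates:
        if len(chosen) == k:
            break
        if not taken[max(c - 2, 0) : min(c + 3, n)].any():
            chosen.append(int(c))
            taken[c] = True
    if len(chosen) < k:
        raise InvalidParameterError("series too short for requested artifact count")
    return np.array(sorted(chosen), dtype=int)


def inject_artifacts(
    rr: RRSeries,
    spec: ArtifactSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[RRSeries, ArtifactLabels]:
    """Corrupt an RR series with labelled artifacts, conserving total time.

    Artifact semantics (all exactly time-conserving):

    * ``missed``     -- two adjacent intervals merged into their sum;
    * ``extra``      -- one interval split into two random positive parts;
    * ``ectopic``    -- interval *i* shortened by d, interval *i+1* lengthened
      by d (premature beat with compensatory pause), d ~ 20-40 % of RR_i;
    * ``misaligned`` -- small antisymmetric jitter (|d| in 20-50 ms) on an
      adjacent interval pair.

    Returns the corrupted series and truth labels indexed on the *corrupted*
    series (one primary label per injected event).
    """
    spec = spec or ArtifactSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rr.n_beats
    if n < 50:
        raise TooShortError("need >= 50 beats for artifact injection")
    if spec.total >= 0.05:
        raise InvalidParameterError("total artifact rate must be < 0.05")

    counts = {cat: int(rng.binomial(n, rate)) for cat, rate in spec.as_dict().items()}
    k = sum(counts.values())
    out = list(rr.intervals.copy())
    labels = ["normal"] * n
    if k == 0:
        return RRSeries(intervals=np.array(out), start_s=rr.start_s), ArtifactLabels(
            categories=np.array(labels, dtype=object)
        )

    positions = _draw_positions(rng, n, k)
    cats = np.concatenate([[c] * m for c, m in counts.items() if m > 0])
    rng.shuffle(cats)

    offset = 0
    for pos, cat in zip(positions, cats):
        i = pos + offset
        if cat == "missed":
            out[i : i + 2] = [out[i] + out[i + 1]]
            labels[i : i + 2] = ["missed"]
            offset -= 1
        elif cat == "extra":
            u = rng.uniform(0.35, 0.65)
            a = out[i]
            out[i : i + 1] = [a * u, a * (1 - u)]
            labels[i : i + 1] = ["extra", "normal"]
            offset += 1
        elif cat == "ectopic":
            d = rng.uniform(0.20, 0.40) * out[i]
            out[i] -= d
            out[i + 1] += d
            labels[i] = "ectopic"
        else:  # misaligned
            d = rng.uniform(20.0, 50.0) * rng.choice([-1.0, 1.0])
            d = float(np.clip(d, -(out[i] - 50.0), out[i + 1] - 50.0))
            out[i] += d
            out[i + 1] -= d
            labels[i] = "misaligned"

    corrupted = RRSeries(intervals=np.array(out), start_s=rr.start_s)
    return corrupted, ArtifactLabels(categories=np.array(labels, dtype=object))


# ---------------------------------------------------------------------------
# Jury ratings with two-factor latent structure
# ---------------------------------------------------------------------------

def simulate_jury(
    cfg: JuryConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[JudgmentMatrix, np.ndarray]:
    """Generate jury ratings; returns (JudgmentMatrix, true factor scores 2 x C).

    Rating model:
    ``score[r, c, d] = clip(mean_d + comm_sd * (L_d . F_c + sqrt(1 - h2_d) u_cd)
    + bias_r + eps_rcd, 1, 5)``, with orthogonal standard-normal factor scores
    ``F_c`` so that communicator-level means carry the implied two-factor
    correlation structure.
    """
    cfg = cfg or JuryConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    R, C, D = cfg.n_raters, cfg.n_communicators, len(DIMENSIONS)
    L = cfg.loadings
    uniq = np.sqrt(np.clip(1.0 - np.sum(L**2, axis=1), 0.0, None))

    F = rng.standard_normal((2, C))
    unique_part = rng.standard_normal((C, D)) * uniq  # communicator-specific
    latent = cfg.comm_sd * ((L @ F).T + unique_part)  # (C, D)
    bias = rng.normal(0.0, cfg.rater_bias_sd, size=R)
    eps = rng.normal(0.0, cfg.residual_sd, size=(R, C, D))

    scores = cfg.dim_means[None, None, :] + latent[None, :, :] + bias[:, None, None] + eps
    if cfg.round_ratings:
        scores = np.round(scores)
    scores = np.clip(scores, LIKERT_MIN, LIKERT_MAX)
    return JudgmentMatrix(ratings=scores), F


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _protocol_for(
    targets: dict[str, tuple[float, float, float]],
    rr_offset: float,
    trait_factor: float,
    phase_factors: dict[str, float],
    noise_sd: float = DEFAULT_NOISE_SD,
) -> ProtocolConfig:
    specs = {}
    for phase in PHASES:
        rr, lf, hf = targets[phase]
        f = trait_factor * phase_factors[phase]
        specs[phase] = (
            DEFAULT_DURATIONS[phase],
            ModulatorSpec(
                mean_rr=rr + rr_offset,
                lf_amp=_amp_for_power(lf) * f,
                hf_amp=_amp_for_power(hf) * f,
                noise_sd=noise_sd,
            ),
        )
    return ProtocolConfig(phase_specs=specs)


def simulate_cohort(
    cfg: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[RRRecording], pd.DataFrame]:
    """Simulate a cohort of three-phase recordings with cluster ground truth.

    Returns the recordings and a cohort table with columns
    ``subject_id, age, gender, log_pub, cluster``.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    clusters: list[str] = []
    names = sorted(cfg.cluster_fractions)
    for name in names[:-1]:
        clusters += [name] * int(round(cfg.cluster_fractions[name] * cfg.n_subjects))
    clusters += [names[-1]] * (cfg.n_subjects - len(clusters))

    recordings: list[RRRecording] = []
    rows = []
    for si, cluster in enumerate(clusters):
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 30.0, 75.0))
        log_pub = float(rng.normal(cfg.log_pub_mean, cfg.log_pub_sd))
        gender = "F" if rng.uniform() < cfg.female_fraction else "M"
        trait = float(rng.lognormal(0.0, cfg.subject_amp_sd))
        phase_factors = {
            p: float(rng.lognormal(0.0, cfg.phase_amp_sd)) for p in PHASES
        }
        rr_offset = float(rng.normal(0.0, cfg.rr_offset_sd))
        meta = SubjectMeta(
            subject_id=f"S{si + 1:03d}",
            age=age,
            gender=gender,
            log_pub=log_pub,
            cluster=cluster,
        )
        protocol = _protocol_for(cfg.phase_targets[cluster], rr_offset, trait, phase_factors)
        rec = simulate_recording(protocol, meta, seed=rng)
        if cfg.artifact_spec is not None:
            corrupted, _ = inject_artifacts(rec.series, cfg.artifact_spec, seed=rng)
            rec = rec.with_series(corrupted)
        recordings.append(rec)
        rows.append(
            {
                "subject_id": meta.subject_id,
                "age": age,
                "gender": gender,
                "log_pub": log_pub,
                "cluster": cluster,
            }
        )
    return recordings, pd.DataFrame(rows)
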