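"""End-to-end pipeline: preprocess -> features -> bidimensional -> statistics.

The pipeline is deterministic given (config, seed, inputs); a run manifest
records the seed, a hash of the configuration, per-subject corrected-beat
percentages and every excluded segment with a machine-readable reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import bidim, features, io, simulate, stats
from .errors import HRVError
from .series import RRRecording, SubjectMeta

logger = logging.getLogger("hrvbalance")

__all__ = ["PipelineConfig", "run_pipeline", "write_simulated_inputs"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline settings with study defaults."""

    # spectral bands (Hz)
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    # preprocessing
    lam: float = 500.0
    sample_rate: float = 4.0
    window_s: float = 300.0
    overlap: float = 0.5
    preferred_s: float = 300.0
    fallback_s: float = 180.0
    quality_gate_pct: float = 5.0
    artifact_threshold: float = 5.2
    qd_window: int = 91
    median_window: int = 11
    # analysis
    dead_zone: float = 0.20
    retain_gt: float = 1.0
    adjust: str = "bonferroni"
    dvs: tuple[str, ...] = ("lf", "hf", "lhfp", "lhfnd", "mean_rr", "mean_hr", "sdnn")
    covariates: tuple[str, ...] = ("age", "log_pub")
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")
        for name in ("lam", "sample_rate", "window_s", "preferred_s", "fallback_s"):
            if getattr(self, name) < 0 or (name != "lam" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        for key in ("vlf_band", "lf_band", "hf_band", "dvs", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def write_simulated_inputs(
    out_dir: str | Path, cfg: simulate.CohortConfig | None = None, seed: int = 0
) -> None:
    """Materialize a simulated cohort as the pipeline's on-disk input layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings, cohort = simulate.simulate_cohort(cfg, seed=seed)
    io.write_cohort(cohort, out / "cohort.csv")
    for rec in recordings:
        sid = rec.meta.subject_id
        io.write_rr(rec.series, out / f"{sid}.rr.txt")
        io.write_phases(rec.phases, out / f"{sid}.phases.csv")
    jm, _ = simulate.simulate_jury(seed=seed)
    io.write_judgments(jm, out / "judgments.csv")


def _load_recordings(input_dir: Path) -> list[RRRecording]:
    cohort = io.read_cohort(input_dir / "cohort.csv")
    recs = []
    for row in cohort.itertuples():
        sid = row.subject_id
        series = io.read_rr(input_dir / f"{sid}.rr.txt")
        phases = io.read_phases(input_dir / f"{sid}.phases.csv")
        meta = SubjectMeta(
            subject_id=sid,
            age=float(row.age),
            gender=str(row.gender),
            log_pub=float(row.log_pub),
            cluster=getattr(row, "cluster", None),
        )
        recs.append(RRRecording(series=series, phases=phases, meta=meta))
    return recs


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, output_dir: str | Path
) -> dict:
    """Execute the full analysis over an input directory.

    Expects ``cohort.csv``, per-subject ``<id>.rr.txt`` + ``<id>.phases.csv``
    and optionally ``judgments.csv``.  Writes features.csv, trajectory.csv,
    stats.csv, emmeans.csv and manifest.json into ``output_dir``; per-subject
    failures are logged and recorded, never fatal.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "excluded": [],
        "corrected_pct": {},
    }

    recordings = _load_recordings(input_dir)
    cohort = io.read_cohort(input_dir / "cohort.csv")

    feat = features.compute_feature_table(
        recordings,
        lam=config.lam,
        sample_rate=config.sample_rate,
        window_s=config.window_s,
        overlap=config.overlap,
        preferred_s=config.preferred_s,
        fallback_s=config.fallback_s,
        quality_gate_pct=config.quality_gate_pct,
    )
    for row in feat.itertuples():
        if row.flags and ("error" in row.flags or "excluded" in row.flags):
            manifest["excluded"].append(
                {"subject": row.subject, "phase": row.phase, "reason": row.flags}
            )
            logger.warning("flagged %s/%s: %s", row.subject, row.phase, row.flags)
    feat.to_csv(output_dir / "features.csv", index=False)

    merged = feat.merge(cohort, left_on="subject", right_on="subject_id", how="left")
    usable = merged[~merged["flags"].str.contains("error|excluded", na=False)]

    grouping = "cluster" if "cluster" in cohort.columns else None
    try:
        traj = bidim.phase_trajectory(usable, grouping=grouping)
        traj.to_csv(output_dir / "trajectory.csv", index=False)
    except HRVError as exc:
        logger.warning("trajectory skipped: %s", exc)

    between = tuple(
        f for f in ("gender", "cluster") if f in usable.columns and usable[f].nunique() > 1
    )
    all_stats = []
    emm_rows = []
    for dv in config.dvs:
        model = None
        # degrade gracefully on singular designs (e.g. an empty factor cell)
        for kwargs in (
            {"between": between, "factor_interactions": True},
            {"between": between, "factor_interactions": False},
            {"between": ()},
        ):
            try:
                model = stats.rm_anova(
                    usable, dv=dv, covariates=config.covariates, **kwargs
                )
                break
            except HRVError as exc:
                logger.warning("rm_anova(%s, %s) failed: %s", dv, kwargs, exc)
        if model is None:
            continue
        tab = model.to_frame()
        tab.insert(0, "dv", dv)
        all_stats.append(tab)
        emm, contrasts = stats.adjusted_pairwise_contrasts(model, adjust=config.adjust)
        for phase, val in emm.items():
            emm_rows.append({"dv": dv, "phase": phase, "emmean": val})
        contrasts.insert(0, "dv", dv)
        all_stats.append(
            contrasts.rename(columns={"p_adj": "p"}).assign(
                effect="phase_pairwise", test="pairwise"
            )
        )
    if all_stats:
        pd.concat(all_stats, ignore_index=True).to_csv(
            output_dir / "stats.csv", index=False
        )
    if emm_rows:
        pd.DataFrame(emm_rows).to_csv(output_dir / "emmeans.csv", index=False)

    jpath = input_dir / "judgments.csv"
    if jpath.exists():
        jm = io.read_judgments(jpath)
        means = jm.communicator_means()
        pca = stats.pca_varimax(means, retain_gt=config.retain_gt)
        pd.DataFrame(
            pca.loadings_rotated,
            index=pca.variables,
            columns=[f"component_{i+1}" for i in range(pca.n_retained)],
        ).to_csv(output_dir / "pca_loadings.csv")
        manifest["pca_cumulative_pct"] = pca.cumulative_pct

    io.write_json(manifest, output_dir / "manifest.json")
    return manifest
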