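"""Pipeline orchestration: simulate -> reconstruct -> preprocess -> agree.

One :class:`RunConfig` (YAML-loadable, strictly validated) drives the whole
analysis: generate or load a study, reconstruct sock CoP with the printed
nominal geometry, resample both modalities to a common rate, align and
mean-center each pair, compute the agreement statistics, and tabulate one
record per (participant, exercise, repetition, foot, axis).  Every waveform
pair ends up either in the metrics table or in the exclusion list with a
reason; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import agreement as agr
from . import io as sio
from . import preprocess as pre
from .geometry import cop_series, default_geometry
from .simulate import SensorModel, Study, StudyDesign, generate_study

logger = logging.getLogger("sockcop")

__all__ = [
    "PreprocessConfig",
    "AgreementConfig",
    "SimulationConfig",
    "RunConfig",
    "PipelineResult",
    "analyze_trial",
    "analyze_study",
    "run_pipeline",
    "report",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessConfig(_StrictModel):
    resample_rate_hz: float = Field(125.0, gt=0)
    max_lag_s: float = Field(5.0, gt=0)
    marker_rel_threshold: float = Field(0.1, gt=0, lt=1)
    marker_min_duration_s: float = Field(2.0, gt=0)
    max_gap_s: float = Field(0.2, gt=0)


class AgreementConfig(_StrictModel):
    quantile_low: float = Field(2.5, ge=0, lt=50)
    quantile_high: float = Field(97.5, gt=50, le=100)
    alpha: float = Field(0.95, gt=0, lt=1)
    ccc_ci_alpha: float = Field(0.05, gt=0, lt=1)
    rmse_reference: Literal["platform", "sock"] = "platform"
    ccc_on: Literal["centered", "raw"] = "centered"


class SimulationConfig(_StrictModel):
    """Study-design knobs exposed to the config file.

    ``preset='ideal'`` switches to the noise-free design (exact sensors,
    no platform offset/noise/lag) used for the perfect-agreement limit.
    """

    preset: Literal["default", "ideal"] = "default"
    n_participants: int = Field(10, ge=1)
    n_applications: int = Field(2, ge=1)
    sensor_noise_sd_uS: float | None = Field(None, ge=0)
    platform_noise_sd_mm: float | None = Field(None, ge=0)
    lag_range_s: float | None = Field(None, ge=0)

    def to_design(self) -> StudyDesign:
        base = dict(
            n_participants=self.n_participants,
            n_applications=self.n_applications,
        )
        if self.preset == "ideal":
            return StudyDesign.ideal(**base)
        if self.sensor_noise_sd_uS is not None:
            base["sensor_model"] = SensorModel(noise_sd_uS=self.sensor_noise_sd_uS)
        if self.platform_noise_sd_mm is not None:
            base["platform_noise_sd_mm"] = self.platform_noise_sd_mm
        if self.lag_range_s is not None:
            base["lag_range_s"] = self.lag_range_s
        return StudyDesign(**base)


class RunConfig(_StrictModel):
    seed: int = 0
    input_dir: str | None = None       # read a written study instead of simulating
    out_dir: str | None = None
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    agreement: AgreementConfig = Field(default_factory=AgreementConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    summary: pd.DataFrame
    exclusions: list[dict]
    study: Study | None = None


def analyze_trial(
    sock_conductance,
    platform_cop,
    annotations: dict,
    preprocess: PreprocessConfig | None = None,
    agreement: AgreementConfig | None = None,
) -> list[dict]:
    """Agreement records (one per axis) for one sock/platform trial.

    The sock CoP is reconstructed with the printed nominal geometry — as
    an analyst without per-participant calibration would — then both
    waveforms are resampled to the common rate, aligned by one shared lag,
    mean-centered, and scored.
    """
    pp = preprocess or PreprocessConfig()
    ac = agreement or AgreementConfig()
    sock_cop = cop_series(sock_conductance, default_geometry())
    sock_rs = pre.resample(sock_cop, pp.resample_rate_hz, pp.max_gap_s)
    plat_rs = pre.resample(platform_cop, pp.resample_rate_hz, pp.max_gap_s)
    pair_x, pair_y = pre.align(sock_rs, plat_rs, pp.max_lag_s, annotations=annotations)

    rows = []
    for pair in (pair_x, pair_y):
        values = pair.raw() if ac.ccc_on == "raw" else (pair.sock, pair.platform)
        r = agr.rmse(values, (ac.quantile_low, ac.quantile_high), ac.rmse_reference)
        ba = agr.bland_altman(values, ac.alpha)
        ccc = agr.lin_ccc(values, ac.ccc_ci_alpha)
        rows.append(
            {
                **annotations,
                "axis": pair.axis,
                "n": pair.n,
                "lag_s": pair.lag_s,
                "rmse_abs_mm": r.rmse_abs_mm,
                "rmse_rel": r.rmse_rel,
                "delta_q_mm": r.delta_q_mm,
                "bias_mm": ba.bias_mm,
                "sd_diff_mm": ba.sd_diff_mm,
                "loa_low_mm": ba.loa_low_mm,
                "loa_high_mm": ba.loa_high_mm,
                "frac_outside": ba.frac_outside,
                "ccc": ccc.ccc,
                "rho": ccc.rho,
                "ccc_ci_low": ccc.ci_low,
                "ccc_ci_high": ccc.ci_high,
                "class_strict": agr.classify_concordance(ccc.ccc, "strict").label,
                "class_loose": agr.classify_concordance(ccc.ccc, "loose").label,
            }
        )
    return rows


def analyze_study(study: Study, config: RunConfig) -> PipelineResult:
    """Score every waveform pair of a study; collect failures as exclusions."""
    rows: list[dict] = []
    exclusions: list[dict] = []
    for trial in study.trials:
        try:
            rows.extend(
                analyze_trial(
                    trial.sock, trial.platform,
                    annotations={"trial_id": trial.trial_id, **trial.annotations},
                    preprocess=config.preprocess,
                    agreement=config.agreement,
                )
            )
        except ValueError as exc:
            logger.warning("trial %s excluded: %s", trial.trial_id, exc)
            for axis in ("x", "y"):
                exclusions.append(
                    {"trial_id": trial.trial_id, "axis": axis, "reason": str(exc)}
                )
    if not rows:
        raise RuntimeError("no waveform pair could be analyzed")
    metrics = pd.DataFrame(rows)
    summary = agr.summarize(metrics)
    return PipelineResult(metrics, summary, exclusions, study)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full simulate/load -> reconstruct -> agree -> report chain.

    With ``out_dir`` set, writes ``metrics.tsv``, ``summary.tsv``,
    ``exclusions.tsv`` (if any), ``report.txt`` and — when simulating —
    the study CSVs and manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.input_dir is not None:
        study = _load_study(config.input_dir)
    else:
        design = config.simulation.to_design()
        logger.info(
            "simulating study: %d trials (%d waveform pairs), seed=%d",
            design.n_trials, design.n_waveform_pairs, config.seed,
        )
        study = generate_study(design, seed=config.seed)
    result = analyze_study(study, config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.input_dir is None:
            sio.write_study(study, out / "study")
        sio.write_metrics_tsv(out / "metrics.tsv", result.metrics)
        result.summary.to_csv(out / "summary.tsv", sep="\t", float_format="%.6g")
        if result.exclusions:
            pd.DataFrame(result.exclusions).to_csv(
                out / "exclusions.tsv", sep="\t", index=False
            )
        (out / "report.txt").write_text(report(result.metrics), encoding="utf-8")
    return result


def _load_study(study_dir: str | Path) -> Study:
    """Rehydrate a written study directory into in-memory trials."""
    from .simulate import Trial

    study_dir = Path(study_dir)
    manifest = sio.read_manifest(study_dir)
    trials = []
    for entry in manifest["trials"]:
        tid = entry["trial_id"]
        ann = {k: entry[k] for k in ("participant", "exercise", "foot", "repetition")}
        sock = sio.read_conductance_csv(
            study_dir / f"{tid}_sock.csv",
            foot=ann["foot"], participant=ann["participant"],
            exercise=ann["exercise"], repetition=ann["repetition"],
        )
        platform = sio.read_cop_csv(
            study_dir / f"{tid}_platform.csv", source="platform", annotations=ann
        )
        truth_path = study_dir / f"{tid}_truth.csv"
        truth = (
            sio.read_cop_csv(truth_path, source="truth", annotations=ann)
            if truth_path.exists()
            else platform
        )
        trials.append(
            Trial(
                trial_id=tid, annotations=ann, sock=sock,
                platform=platform, truth=truth,
                params=entry.get("params", {}),
            )
        )
    design = StudyDesign()  # nominal; the data on disk is authoritative
    return Study(design=design, seed=manifest.get("seed", 0), trials=tuple(trials))


def report(metrics: pd.DataFrame) -> str:
    """Human-readable agreement summary of a metrics table."""
    if metrics.empty:
        raise ValueError("empty metrics table")
    summary = agr.summarize(metrics)
    lines = [
        f"Waveform pairs analyzed: {len(metrics)}",
        "",
    ]
    for axis, row in summary.iterrows():
        name = {"x": "CoP X (mediolateral)", "y": "CoP Y (anteroposterior)"}.get(
            axis, "All axes"
        )
        lines += [
            f"{name}: n = {int(row['n'])}",
            (
                f"  CCC range [{row['ccc_min']:.2f}, {row['ccc_max']:.2f}]; "
                f"RMSE range [{row['rmse_min_mm']:.1f}, {row['rmse_max_mm']:.1f}] mm"
            ),
            (
                f"  CCC >= 0.90: {int(row['n_ccc_ge_090'])} ({row['frac_ccc_ge_090']:.0%}); "
                f"CCC >= 0.60: {int(row['n_ccc_ge_060'])} ({row['frac_ccc_ge_060']:.0%}); "
                f"CCC < 0.40: {int(row['n_ccc_lt_040'])} ({row['frac_ccc_lt_040']:.0%})"
            ),
        ]
    return "\n".join(lines) + "\n"
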