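"""End-to-end orchestration: spikes -> bursts -> metrics -> dose-response.

``analyze_recordings`` turns well recordings into the per-well metrics
table; ``run_dose_response`` turns the metrics table into the ratio table,
BMR band and effect report; ``run_pipeline`` composes the two from files
on disk and writes every output table plus a run manifest.  Every stage
logs its in/out counts (electrodes included, wells retained, outliers
excluded) so the filters are auditable.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bursts import BurstConfig, detect_bursts
from .core import WellRecording
from .detection import active_electrodes
from .metrics import ANALYSIS_WINDOW_S, PARAMETERS, analysis_window, compute_metrics
from .netbursts import NetworkBurstConfig, detect_network_bursts
from .stats import EffectReport, bmr_band, cumulative_ratios, flag_and_summarize, include_wells
from .io import read_experiment

__all__ = ["RunConfig", "analyze_recordings", "run_dose_response", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    burst: BurstConfig = field(default_factory=BurstConfig)
    network_burst: NetworkBurstConfig = field(default_factory=NetworkBurstConfig)
    analysis_window_s: float = ANALYSIS_WINDOW_S
    recording_duration_s: float = 1800.0
    n_electrodes: int = 16
    recording_days: tuple[int, ...] = (7, 10, 14, 17, 21, 24, 28)
    baseline_div: int = 7
    final_div: int = 28
    alpha: float = 0.05
    bmr_mode: str = "per_div"
    min_rate_per_min: float = 6.0
    min_bursting_electrodes: int = 4
    parameters: tuple[str, ...] = PARAMETERS
    seed: int = 0

    def __post_init__(self):
        if self.final_div not in self.recording_days:
            raise ValueError("final_div must be one of recording_days")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    ratios: pd.DataFrame
    band: pd.DataFrame
    report: EffectReport
    outlier_fraction: float


def analyze_well(rec: WellRecording, cfg: RunConfig) -> dict:
    """One well at one DIV: window, electrode filter, detection, metrics."""
    win = analysis_window(rec, cfg.analysis_window_s)
    win_len = min(rec.duration_s, cfg.analysis_window_s)
    included = active_electrodes(win.trains, win_len, cfg.min_rate_per_min)
    filtered = win.subset(included)
    bursts = []
    for e in sorted(filtered.trains):
        bursts.extend(detect_bursts(filtered.trains[e], cfg.burst))
    nbs = detect_network_bursts(filtered, cfg.network_burst)
    m = compute_metrics(filtered, bursts, nbs)
    return (
        dict(
            experiment=rec.condition.experiment,
            plate=rec.plate,
            well=rec.well,
            div=rec.div,
            compound=rec.condition.compound,
            concentration_um=rec.condition.concentration_um,
            sex=rec.condition.sex,
        )
        | m.as_dict()
    )


def analyze_recordings(recordings: list[WellRecording], cfg: RunConfig = RunConfig()) -> pd.DataFrame:
    """Metrics table: one row per (experiment, well, DIV)."""
    rows = [analyze_well(rec, cfg) for rec in recordings]
    df = pd.DataFrame(rows)
    log.info("metrics computed for %d well-recordings", len(df))
    return df


def run_dose_response(metrics_df: pd.DataFrame, cfg: RunConfig = RunConfig()) -> PipelineResult:
    """Inclusion, cumulative ratios, BMR band, flags and LOEC summary."""
    kept = include_wells(metrics_df, cfg.baseline_div, cfg.min_bursting_electrodes)
    ratios, frac = cumulative_ratios(kept, final_div=cfg.final_div, parameters=cfg.parameters)
    band = bmr_band(ratios, mode=cfg.bmr_mode)
    report = flag_and_summarize(ratios, band, alpha=cfg.alpha)
    return PipelineResult(metrics=kept, ratios=ratios, band=band, report=report, outlier_fraction=frac)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Read spike lists + plate map from disk, run everything, write outputs."""
    recs, _ = read_experiment(cfg.input_dir, duration_s=cfg.recording_duration_s,
                              n_electrodes=cfg.n_electrodes)
    if not recs:
        raise ValueError(f"no spike lists found in {cfg.input_dir}")
    metrics_df = analyze_recordings(recs, cfg)
    result = run_dose_response(metrics_df, cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics_df.to_csv(out / "well_metrics.csv", index=False)
    result.ratios.to_csv(out / "ratio_table.csv", index=False)
    result.band.to_csv(out / "bmr_band.csv", index=False)
    result.report.flags.to_csv(out / "effect_flags.csv", index=False)
    result.report.loec.to_csv(out / "loec_summary.csv", index=False)
    (out / "effect_report.json").write_text(result.report.to_json())
    manifest = {
        "meanet_version": __version__,
        "python": platform.python_version(),
        "config": {k: str(v) for k, v in vars(cfg).items()},
        "n_well_recordings": len(recs),
        "n_wells_retained": int(result.metrics[["experiment", "well"]].drop_duplicates().shape[0]),
        "outlier_fraction": result.outlier_fraction,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline outputs written to %s", out)
    return result
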