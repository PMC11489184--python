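"""Reading and writing the pipeline's plain-text tables.

Spike lists are tidy CSVs with columns (experiment, plate, well,
electrode, time_s), one file per recording day named ``spikes_divNN.csv``;
plate maps are CSVs with columns (well, compound, concentration_um, sex,
experiment).  Raw-trace fixtures for the optional detection stage are one
CSV of voltage samples per electrode plus a JSON sidecar carrying the
sampling rate.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Condition, SpikeTrain, WellRecording
from .detection import RawTrace

__all__ = [
    "write_spike_list",
    "read_spike_list",
    "write_plate_map",
    "read_plate_map",
    "write_experiment",
    "read_experiment",
    "read_raw_trace",
]

log = logging.getLogger(__name__)

SPIKE_COLUMNS = ["experiment", "plate", "well", "electrode", "time_s"]
PLATE_MAP_COLUMNS = ["well", "compound", "concentration_um", "sex", "experiment"]


def write_spike_list(recordings: list[WellRecording], path) -> None:
    """Write one recording day's wells as a spike-list CSV."""
    rows = []
    for rec in recordings:
        for e in rec.electrodes:
            t = rec.trains[e].spike_times
            rows.append(
                pd.DataFrame(
                    {
                        "experiment": rec.condition.experiment,
                        "plate": rec.plate,
                        "well": rec.well,
                        "electrode": e,
                        "time_s": t,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_spike_list(
    path,
    plate_map: pd.DataFrame,
    div: int,
    duration_s: float,
    n_electrodes: int = 16,
) -> list[WellRecording]:
    """Read one recording day's spike-list CSV into well recordings.

    Wells absent from the plate map are an error; unsorted or duplicated
    spike times are collapsed with a warning.  Wells listed in the plate
    map but silent in the file yield empty recordings.
    """
    df = pd.read_csv(path)
    if missing := set(SPIKE_COLUMNS) - set(df.columns):
        raise ValueError(f"spike list {path} is missing columns {sorted(missing)}")
    pm = plate_map.set_index("well")
    unknown = set(df["well"].unique()) - set(pm.index)
    if unknown:
        raise ValueError(f"spike list references wells not in the plate map: {sorted(unknown)}")
    recs = []
    for well, pinfo in pm.iterrows():
        sub = df[df["well"] == well]
        trains = {}
        for e in range(n_electrodes):
            t = np.asarray(sub.loc[sub["electrode"] == e, "time_s"], dtype=float)
            tu = np.unique(t)
            if tu.size != t.size or (t.size and np.any(np.diff(t) < 0)):
                log.warning("well %s electrode %d: unsorted/duplicate spike times collapsed", well, e)
            trains[e] = SpikeTrain(electrode=e, spike_times=tu, window=(0.0, duration_s))
        cond = Condition(
            compound=str(pinfo["compound"]),
            concentration_um=float(pinfo["concentration_um"]),
            sex=str(pinfo["sex"]),
            experiment=str(pinfo["experiment"]),
        )
        plate = int(sub["plate"].iloc[0]) if len(sub) else int(pinfo.get("plate", 0))
        recs.append(
            WellRecording(
                well=well,
                div=div,
                condition=cond,
                trains=trains,
                duration_s=duration_s,
                n_electrodes=n_electrodes,
                plate=plate,
            )
        )
    return recs


def write_plate_map(plate_map: pd.DataFrame, path) -> None:
    plate_map.to_csv(path, index=False)


def read_plate_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path)
    if missing := set(PLATE_MAP_COLUMNS) - set(pm.columns):
        raise ValueError(f"plate map {path} is missing columns {sorted(missing)}")
    return pm


def write_experiment(recordings: list[WellRecording], plate_map: pd.DataFrame, out_dir) -> list[Path]:
    """Write per-DIV spike lists plus the plate map into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    divs = sorted({rec.div for rec in recordings})
    for div in divs:
        p = out / f"spikes_div{div:02d}.csv"
        write_spike_list([r for r in recordings if r.div == div], p)
        paths.append(p)
    pmp = out / "plate_map.csv"
    write_plate_map(plate_map, pmp)
    paths.append(pmp)
    return paths


def read_experiment(
    in_dir, duration_s: float = 1800.0, n_electrodes: int = 16
) -> tuple[list[WellRecording], pd.DataFrame]:
    """Read a directory of ``spikes_divNN.csv`` files plus ``plate_map.csv``."""
    d = Path(in_dir)
    plate_map = read_plate_map(d / "plate_map.csv")
    recs: list[WellRecording] = []
    for p in sorted(d.glob("spikes_div*.csv")):
        m = re.search(r"spikes_div(\d+)\.csv$", p.name)
        if not m:
            continue
        recs.extend(read_spike_list(p, plate_map, div=int(m.group(1)),
                                    duration_s=duration_s, n_electrodes=n_electrodes))
    return recs, plate_map


def read_raw_trace(csv_path, sidecar_path=None) -> RawTrace:
    """Read a single-electrode raw voltage fixture (CSV + JSON sidecar)."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    samples = np.loadtxt(csv_path, dtype=float)
    return RawTrace(
        electrode=int(meta.get("electrode", 0)),
        samples=samples,
        sampling_rate=float(meta.get("sampling_rate", 12500.0)),
    )
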