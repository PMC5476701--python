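"""Cohort and table file I/O.

The interchange format is long-format CSV: one row per frame for raw
traces (fly_id, genotype, group, hemisphere, compartment, trial, frame,
fluorescence), one row per observation for derived tables. Floats are
written with 17 significant digits so a write/read round trip is
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import RECORDING_DURATION, SAMPLING_RATE
from .synthdata import FlyRecording

N_FRAMES = int(round(RECORDING_DURATION * SAMPLING_RATE))
FLOAT_FORMAT = "%.17g"

COHORT_COLUMNS = ["fly_id", "genotype", "group", "hemisphere", "compartment",
                  "trial", "frame", "fluorescence"]


class IOError_(ValueError):
    """Schema violation in an input file."""


def write_cohort(recordings: list[FlyRecording], directory) -> dict[str, Path]:
    """Write a cohort as traces CSV + currents CSV + truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    cur_rows = []
    truth = {}
    for fly in recordings:
        for (side, comp, trial), trace in sorted(fly.traces.items()):
            rows.append(pd.DataFrame({
                "fly_id": fly.fly_id, "genotype": fly.genotype,
                "group": fly.group, "hemisphere": side, "compartment": comp,
                "trial": trial, "frame": np.arange(trace.size),
                "fluorescence": trace,
            }))
        for trial, current in sorted(fly.shock_currents.items()):
            cur_rows.append({"fly_id": fly.fly_id, "trial": trial,
                             "current_nA": current})
        truth[fly.fly_id] = {"genotype": fly.genotype, "group": fly.group,
                             **{k: v for k, v in fly.truth.items()}}
    traces_path = directory / "traces.csv"
    pd.concat(rows, ignore_index=True).to_csv(
        traces_path, index=False, float_format=FLOAT_FORMAT)
    currents_path = directory / "currents.csv"
    pd.DataFrame(cur_rows).to_csv(currents_path, index=False,
                                  float_format=FLOAT_FORMAT)
    truth_path = directory / "truth.yaml"
    with open(truth_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, allow_unicode=True, sort_keys=True)
    return {"traces": traces_path, "currents": currents_path,
            "truth": truth_path}


def read_cohort(directory) -> list[FlyRecording]:
    """Read a cohort written by :func:`write_cohort`.

    Validates the schema: required columns, and exactly 225 frames
    (0..224) per trace.
    """
    directory = Path(directory)
    df = pd.read_csv(directory / "traces.csv", float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"traces.csv: missing column(s) {missing}")
    currents = pd.read_csv(directory / "currents.csv", float_precision="round_trip")
    truth_path = directory / "truth.yaml"
    truth = {}
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            truth = yaml.safe_load(fh) or {}

    flies: list[FlyRecording] = []
    for fly_id, fly_df in df.groupby("fly_id", sort=True):
        genotype = fly_df.genotype.iloc[0]
        group = fly_df.group.iloc[0]
        traces: dict[tuple[str, str, int], np.ndarray] = {}
        hemis: dict[str, set] = {}
        for (side, comp, trial), g in fly_df.groupby(
                ["hemisphere", "compartment", "trial"], sort=True):
            g = g.sort_values("frame")
            if len(g) != N_FRAMES or not np.array_equal(
                    g.frame.to_numpy(), np.arange(N_FRAMES)):
                raise IOError_(
                    f"fly {fly_id}, compartment {comp}, trial {trial}: "
                    f"expected frames 0..{N_FRAMES - 1}, got {len(g)} rows")
            traces[(side, comp, int(trial))] = g.fluorescence.to_numpy()
            hemis.setdefault(side, set()).add(comp)
        cur = currents[currents.fly_id == fly_id]
        flies.append(FlyRecording(
            fly_id=fly_id, genotype=genotype, group=group,
            hemispheres={s: tuple(sorted(c)) for s, c in hemis.items()},
            traces=traces,
            shock_currents={int(r.trial): float(r.current_nA)
                            for r in cur.itertuples()},
            truth=truth.get(fly_id, {}),
        ))
    return flies


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
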