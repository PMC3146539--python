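"""Plain-text I/O: CSV event tables, time-course tables and YAML configs."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd
import yaml

from .fitting import TimeCourseDataset
from .model import PARAM_NAMES, RateParameters, StimulationSchedule
from .quant import BeadEventTable

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_timecourse",
    "write_timecourse",
    "read_params",
    "write_params",
    "read_layout",
]

PathLike = Union[str, Path]


def write_event_table(table: BeadEventTable, path: PathLike) -> None:
    """One row per event; header = scatter and channel names."""
    table.events.to_csv(path, index=False)


def read_event_table(
    path: PathLike,
    condition: str = "",
    time_min: Optional[float] = None,
    replicate: Optional[int] = None,
) -> BeadEventTable:
    df = pd.read_csv(path)
    return BeadEventTable(
        events=df, condition=condition, time_min=time_min, replicate=replicate
    )


def write_timecourse(dataset: TimeCourseDataset, path: PathLike) -> None:
    """CSV of (time_min, observable, replicate, value); when the dataset has
    ground-truth parameters they go to a ``<stem>.truth.yaml`` sidecar."""
    path = Path(path)
    dataset.data.to_csv(path, index=False)
    if dataset.true_params is not None:
        sidecar = path.with_suffix(".truth.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {
                    "true_params": dataset.true_params.to_dict(),
                    "dose_times": list(dataset.schedule.dose_times),
                    "horizon": dataset.schedule.horizon,
                },
                fh,
            )


def read_timecourse(
    path: PathLike,
    schedule: Optional[StimulationSchedule] = None,
) -> TimeCourseDataset:
    path = Path(path)
    data = pd.read_csv(path)
    truth = None
    sidecar = path.with_suffix(".truth.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            raw = yaml.safe_load(fh)
        truth = RateParameters.from_dict(raw["true_params"])
        if schedule is None:
            schedule = StimulationSchedule(
                dose_times=tuple(raw["dose_times"]), horizon=raw["horizon"]
            )
    return TimeCourseDataset(
        data=data,
        true_params=truth,
        schedule=schedule or StimulationSchedule(),
    )


def write_params(params: RateParameters, path: PathLike) -> None:
    """YAML with explicit units (rates per minute, tau_rec in minutes)."""
    doc = {
        "units": {"rates": "1/min", "tau_rec": "min", "scales": "arbitrary"},
        "params": params.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_params(path: PathLike) -> RateParameters:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    d = raw.get("params", raw)
    return RateParameters.from_dict({k: float(v) for k, v in d.items() if k in PARAM_NAMES})


def read_layout(path: PathLike) -> Dict[str, Dict[str, object]]:
    """Layout config mapping event-table file name → condition, time_min,
    replicate and the matched background-control file."""
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise ValueError("layout must be a mapping of file name to sample metadata")
    return layout
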