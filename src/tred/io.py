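"""File formats: trajectory CSV, estimates CSV, TIFF stacks, config files.

Trajectory CSV dialect: header ``track_id,frame,t_s,x_um,y_um`` plus the
optional columns ``cell_id,condition,true_state``; frames 0-based, UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .msd import DiffusionEstimate
from .simulate import SimulationConfig, StateSpec, Trajectory

__all__ = [
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_estimates_csv",
    "read_estimates_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "load_simulation_config",
]


def tracks_to_dataframe(tracks: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        df = pd.DataFrame(
            {"track_id": tr.track_id, "frame": tr.frames, "t_s": tr.times, "x_um": tr.x, "y_um": tr.y}
        )
        if tr.cell_id is not None:
            df["cell_id"] = tr.cell_id
        if tr.condition is not None:
            df["condition"] = tr.condition
        if tr.true_states is not None:
            df["true_state"] = tr.true_states
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "t_s", "x_um", "y_um"])
    return pd.concat(rows, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        out.append(
            Trajectory(
                track_id=tid,
                frames=g["frame"].to_numpy(),
                times=g["t_s"].to_numpy(),
                x=g["x_um"].to_numpy(),
                y=g["y_um"].to_numpy(),
                cell_id=g["cell_id"].iloc[0] if "cell_id" in g else None,
                condition=g["condition"].iloc[0] if "condition" in g else None,
                true_states=g["true_state"].to_numpy() if "true_state" in g else None,
            )
        )
    return out


def write_tracks_csv(tracks: Sequence[Trajectory], path: str | Path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Trajectory]:
    return dataframe_to_tracks(pd.read_csv(path))


def estimates_to_dataframe(estimates: Sequence[DiffusionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [e.track_id for e in estimates],
            "cell_id": [e.cell_id for e in estimates],
            "condition": [e.condition for e in estimates],
            "D_um2_s": [e.D for e in estimates],
            "L_nm": [e.L_nm for e in estimates],
            "offset_um2": [e.offset for e in estimates],
            "r2": [e.r_squared for e in estimates],
            "converged": [e.converged for e in estimates],
        }
    )


def write_estimates_csv(estimates: Sequence[DiffusionEstimate], path: str | Path) -> None:
    estimates_to_dataframe(estimates).to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON mirroring its field names."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "states" in data:
        data["states"] = [
            StateSpec(
                label=s["label"],
                D_micro=float(s["D_micro"]),
                corral_L=float(s.get("corral_L", np.inf)),
                hop_prob=float(s.get("hop_prob", 0.0)),
            )
            for s in data["states"]
        ]
    for key in ("transition_matrix", "initial_occupancy"):
        if key in data:
            data[key] = np.asarray(data[key], dtype=float)
    return SimulationConfig(**data)
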