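"""File formats: trajectory CSV, axon-axis sidecars, TIFF stacks, YAML configs.

The trajectory dialect is one tidy CSV with columns
``traj_id, frame, x_nm, y_nm, snr, condition`` (0-based consecutive frames,
constant frame interval), plus an optional sidecar
``traj_id, axis_x, axis_y`` carrying each trajectory's unit axon axis with
the anterograde-positive sign convention.  Image stacks travel as multi-page
16-bit TIFF.  Scenario presets and camera models round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import CameraModel, ImageStack
from .synthdata import ScenarioPreset
from .transport import Trajectory

__all__ = [
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_axis_csv",
    "read_axis_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "preset_to_yaml",
    "preset_from_yaml",
    "camera_to_yaml",
    "camera_from_yaml",
]


def write_trajectories_csv(
    trajectories: list[Trajectory], path: str | Path, axis_path: str | Path | None = None
) -> None:
    rows = []
    for traj in trajectories:
        for frame, (x, y) in zip(traj.frame_index, traj.positions):
            rows.append(
                {
                    "traj_id": traj.traj_id,
                    "frame": int(frame),
                    "x_nm": float(x),
                    "y_nm": float(y),
                    "snr": float(traj.snr),
                    "condition": traj.condition_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if axis_path is not None:
        write_axis_csv(trajectories, axis_path)


def read_trajectories_csv(
    path: str | Path, dt: float = 0.05, axis_path: str | Path | None = None
) -> list[Trajectory]:
    """Load trajectories; rows must have consecutive frames per traj_id.

    Trajectories with frame gaps are rejected with an error (gaps make a
    track ineligible rather than being bridged).
    """
    df = pd.read_csv(path)
    axes = read_axis_csv(axis_path) if axis_path is not None else {}
    out = []
    for tid, sub in df.groupby("traj_id", sort=False):
        sub = sub.sort_values("frame")
        if np.any(np.diff(sub["frame"].to_numpy()) != 1):
            raise ValueError(f"trajectory {tid!r} has non-consecutive frames")
        out.append(
            Trajectory(
                positions=sub[["x_nm", "y_nm"]].to_numpy(float),
                dt=dt,
                frame_index=sub["frame"].to_numpy() - sub["frame"].iloc[0],
                snr=float(sub["snr"].iloc[0]) if "snr" in sub else np.inf,
                axon_axis=axes.get(tid),
                condition_label=(
                    str(sub["condition"].iloc[0]) if "condition" in sub else "control"
                ),
                traj_id=tid,
            )
        )
    return out


def write_axis_csv(trajectories: list[Trajectory], path: str | Path) -> None:
    rows = [
        {
            "traj_id": t.traj_id,
            "axis_x": float(t.axon_axis[0]),
            "axis_y": float(t.axon_axis[1]),
        }
        for t in trajectories
        if t.axon_axis is not None
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_axis_csv(path: str | Path) -> dict:
    df = pd.read_csv(path)
    return {
        row.traj_id: np.array([row.axis_x, row.axis_y], dtype=float)
        for row in df.itertuples()
    }


def write_stack_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write frames as multi-page 16-bit TIFF (values clipped to uint16)."""
    import tifffile

    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"frame_interval_s": stack.frame_interval,
                               "channel": stack.channel})


def read_stack_tiff(
    path: str | Path, frame_interval: float = 0.05, channel: str = "broadband"
) -> ImageStack:
    import tifffile

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(
        frames=data.astype(float), frame_interval=frame_interval, channel=channel
    )


def preset_to_yaml(preset: ScenarioPreset, path: str | Path) -> None:
    d = asdict(preset)
    d["transition_matrix"] = np.asarray(preset.transition_matrix).tolist()
    for key in ("state_labels", "state_kinds", "speed_means", "speed_sds",
                "direction_signs", "snr_distribution"):
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def preset_from_yaml(path: str | Path) -> ScenarioPreset:
    d = yaml.safe_load(Path(path).read_text())
    d["transition_matrix"] = np.asarray(d["transition_matrix"], dtype=float)
    for key in ("state_labels", "state_kinds", "speed_means", "speed_sds",
                "direction_signs", "snr_distribution"):
        d[key] = tuple(d[key])
    return ScenarioPreset(**d)


def camera_to_yaml(camera: CameraModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(camera), sort_keys=False))


def camera_from_yaml(path: str | Path) -> CameraModel:
    return CameraModel(**yaml.safe_load(Path(path).read_text()))
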