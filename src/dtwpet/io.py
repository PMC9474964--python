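"""File formats: TAC/input-function CSV, frame-timing sidecars, NIfTI volumes.

TAC CSV columns: ``frame_start_s, frame_end_s, activity_kBq_per_mL``.
Input-function CSV columns: ``time_min, value``.
Frame timing uses the BIDS-PET dialect: a JSON sidecar with
``FrameTimesStart`` and ``FrameDuration`` arrays in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import FrameSchedule, InputFunction, TimeActivityCurve
from .parametric import DynamicImage, ParametricMaps

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_input_function_csv",
    "write_input_function_csv",
    "read_frame_sidecar",
    "write_frame_sidecar",
    "load_dynamic_image",
    "save_parametric_maps",
]


def read_tac_csv(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    required = {"frame_start_s", "frame_end_s", "activity_kBq_per_mL"}
    if not required.issubset(df.columns):
        raise ValueError(f"TAC CSV must have columns {sorted(required)}")
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy() / 60.0,
        df["frame_end_s"].to_numpy() / 60.0,
    )
    return TimeActivityCurve(schedule, df["activity_kBq_per_mL"].to_numpy())


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame({
        "frame_start_s": tac.schedule.start * 60.0,
        "frame_end_s": tac.schedule.end * 60.0,
        "activity_kBq_per_mL": tac.values,
    }).to_csv(path, index=False)


def read_input_function_csv(path: str | Path) -> InputFunction:
    df = pd.read_csv(path)
    if not {"time_min", "value"}.issubset(df.columns):
        raise ValueError("input-function CSV must have columns time_min, value")
    return InputFunction(df["time_min"].to_numpy(), df["value"].to_numpy())


def write_input_function_csv(input_fn: InputFunction, path: str | Path) -> None:
    pd.DataFrame({"time_min": input_fn.times, "value": input_fn.values}).to_csv(
        path, index=False
    )


def read_frame_sidecar(path: str | Path) -> FrameSchedule:
    meta = json.loads(Path(path).read_text())
    start = np.asarray(meta["FrameTimesStart"], dtype=float)
    dur = np.asarray(meta["FrameDuration"], dtype=float)
    return FrameSchedule(start / 60.0, (start + dur) / 60.0)


def write_frame_sidecar(schedule: FrameSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "FrameTimesStart": (schedule.start * 60.0).tolist(),
        "FrameDuration": (schedule.durations * 60.0).tolist(),
    }, indent=2))


def load_dynamic_image(
    image_path: str | Path, sidecar_path: str | Path
) -> DynamicImage:
    img = nib.load(str(image_path))
    schedule = read_frame_sidecar(sidecar_path)
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(
        np.asarray(img.dataobj, dtype=float),
        tuple(float(z) for z in zooms),
        schedule,
        affine=np.asarray(img.affine),
    )


def save_parametric_maps(
    maps: ParametricMaps, out_dir: str | Path, affine: np.ndarray | None = None
) -> dict[str, Path]:
    """Write one 3-D NIfTI per parameter; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written: dict[str, Path] = {}
    for name, vol in maps.as_dict().items():
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(p))
        written[name] = p
    return written
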