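"""File formats: behavior CSV/HDF5, neural HDF5, images, GMM JSON.

Behavior tables carry columns t_s, speed_mm_s, left_eye_rad, right_eye_rad,
heading_rad, roll_rad, pitch_rad.  Neural matrices live in HDF5 groups
/F (neurons x time), /mask, /centroids_um and /regions with fs_hz as a root
attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from sleepscope.neuro_prep import NeuronMatrix
from sleepscope.saccades import EyeAngleTrace
from sleepscope.states import SpeedTrace, SubstateGMM

BEHAVIOR_COLUMNS = (
    "t_s", "speed_mm_s", "left_eye_rad", "right_eye_rad",
    "heading_rad", "roll_rad", "pitch_rad",
)


def behavior_frame(synth) -> pd.DataFrame:
    """Tabulate a BehaviorSynthesis into the standard column layout."""
    t = synth.trace.t_s
    return pd.DataFrame({
        "t_s": t,
        "speed_mm_s": synth.speed.speed_mm_s,
        "left_eye_rad": synth.trace.left_rad,
        "right_eye_rad": synth.trace.right_rad,
        "heading_rad": synth.heading_rad,
        "roll_rad": synth.roll_rad,
        "pitch_rad": synth.pitch_rad,
    })


def write_behavior_csv(path, synth) -> None:
    behavior_frame(synth).to_csv(path, index=False)


def read_behavior_csv(path) -> tuple[EyeAngleTrace, SpeedTrace, pd.DataFrame]:
    df = pd.read_csv(path)
    missing = {"t_s", "speed_mm_s", "left_eye_rad", "right_eye_rad"} - set(df)
    if missing:
        raise ValueError(f"behavior CSV missing columns: {sorted(missing)}")
    dt = np.diff(df["t_s"].values)
    fs = 1.0 / np.median(dt)
    trace = EyeAngleTrace(df["left_eye_rad"].values.copy(),
                          df["right_eye_rad"].values.copy(), fs)
    speed = SpeedTrace(df["speed_mm_s"].values.copy(), fs)
    return trace, speed, df


def write_behavior_h5(path, synth) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs_hz"] = synth.trace.fs_hz
        for col, arr in behavior_frame(synth).items():
            f.create_dataset(col, data=np.asarray(arr))


def write_neural_h5(path, matrix: NeuronMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs_hz"] = matrix.fs_hz
        f.create_dataset("F", data=np.where(matrix.mask, matrix.F, np.nan))
        f.create_dataset("mask", data=matrix.mask)
        f.create_dataset("centroids_um", data=matrix.centroids_um)
        f.create_dataset(
            "regions",
            data=np.array([str(r) for r in matrix.regions], dtype="S64"),
        )


def read_neural_h5(path) -> NeuronMatrix:
    with h5py.File(path, "r") as f:
        return NeuronMatrix(
            F=f["F"][()],
            mask=f["mask"][()].astype(bool),
            fs_hz=float(f.attrs["fs_hz"]),
            centroids_um=f["centroids_um"][()],
            regions=np.array([s.decode() for s in f["regions"][()]],
                             dtype=object),
        )


def write_gmm_json(path, gmm: SubstateGMM) -> None:
    Path(path).write_text(gmm.to_json())


def read_gmm_json(path) -> SubstateGMM:
    return SubstateGMM.from_json(Path(path).read_text())


def write_image_stack(path, frames: np.ndarray, sidecar: dict) -> None:
    """Multi-page TIFF plus a JSON sidecar with the ground truth."""
    import tifffile

    tifffile.imwrite(path, (np.clip(frames, 0, 1) * 65535).astype(np.uint16))
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    import tifffile

    frames = tifffile.imread(path).astype(np.float64) / 65535.0
    side_path = Path(str(path) + ".json")
    sidecar = json.loads(side_path.read_text()) if side_path.exists() else {}
    return frames, sidecar
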