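"""File formats: EEG container (HDF5), plain matrix fallback, pose JSON,
frame stacks, and stamped delimited tables.

Dialects
--------
* ``h5``      — repo-standard EEG container: one HDF5 file, one dataset per
  subject under ``/data/<subject>``, plus fs/labels/layout attributes.
* ``matrix``  — plain numeric fallback: a directory of per-subject TSV
  matrices (channels x samples) plus a ``meta.json`` sidecar.
* pose JSON   — per-frame files with a ``people`` array, each person a flat
  ``[x1, y1, c1, x2, y2, c2, ...]`` keypoint list; or one consolidated file.
* frames      — ``.npz`` array container, or a directory of ``.png`` images.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ClipLayout
from .recording import MultiSubjectRecording

# ---------------------------------------------------------------------------
# EEG container (HDF5) and matrix fallback


def write_recording_h5(rec: MultiSubjectRecording, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = rec.fs
        f.attrs["channel_labels"] = json.dumps(rec.channel_labels)
        f.attrs["layout"] = rec.layout.to_frame().to_json(orient="split")
        grp = f.create_group("data")
        for s in rec.subjects:
            grp.create_dataset(s, data=rec.data[s], track_times=False)
        f.attrs["subjects"] = json.dumps(rec.subjects)
    return path


def read_recording_h5(path: str | Path) -> MultiSubjectRecording:
    import h5py

    with h5py.File(path, "r") as f:
        subjects = json.loads(f.attrs["subjects"])
        labels = json.loads(f.attrs["channel_labels"])
        layout = ClipLayout.from_frame(pd.read_json(
            io_wrap(f.attrs["layout"]), orient="split"))
        fs = float(f.attrs["fs"])
        data = {s: f["data"][s][...] for s in subjects}
    return MultiSubjectRecording(subjects, data, fs, labels, layout)


def io_wrap(s: str):
    from io import StringIO

    return StringIO(s)


def write_recording_matrix(rec: MultiSubjectRecording, dirpath: str | Path) -> Path:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for s in rec.subjects:
        np.savetxt(dirpath / f"{s}.tsv", rec.data[s], delimiter="\t", fmt="%.10g")
    meta = {
        "subjects": rec.subjects,
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "layout": rec.layout.to_frame().to_dict(orient="list"),
    }
    (dirpath / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return dirpath


def read_recording_matrix(dirpath: str | Path) -> MultiSubjectRecording:
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "meta.json").read_text())
    data = {
        s: np.atleast_2d(np.loadtxt(dirpath / f"{s}.tsv", delimiter="\t"))
        for s in meta["subjects"]
    }
    layout = ClipLayout.from_frame(pd.DataFrame(meta["layout"]))
    return MultiSubjectRecording(
        meta["subjects"], data, float(meta["fs"]), meta["channel_labels"], layout
    )


# ---------------------------------------------------------------------------
# Pose-keypoint JSON dialect


def write_keypoints_json(track, path: str | Path, per_frame: bool = False) -> Path:
    """Write a KeypointTrack as pose JSON (consolidated file or directory)."""
    path = Path(path)
    frames = [
        {"people": [{"pose_keypoints_2d": person_to_flat(p, track.joint_names)}
                    for p in frame]}
        for frame in track.frames
    ]
    if per_frame:
        path.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames):
            (path / f"frame_{i:06d}_keypoints.json").write_text(json.dumps(fr))
        meta = {"fps": track.fps, "joint_names": track.joint_names}
        (path / "meta.json").write_text(json.dumps(meta))
    else:
        doc = {"fps": track.fps, "joint_names": track.joint_names, "frames": frames}
        path.write_text(json.dumps(doc))
    return path


def read_keypoints_json(path: str | Path):
    from .movement import KeypointTrack

    path = Path(path)
    if path.is_dir():
        meta = json.loads((path / "meta.json").read_text())
        files = sorted(path.glob("frame_*_keypoints.json"))
        raw_frames = [json.loads(f.read_text()) for f in files]
        fps, joint_names = meta["fps"], meta["joint_names"]
    else:
        doc = json.loads(path.read_text())
        raw_frames = doc["frames"]
        fps, joint_names = doc["fps"], doc["joint_names"]
    frames = [
        [flat_to_person(p["pose_keypoints_2d"], joint_names)
         for p in fr.get("people", [])]
        for fr in raw_frames
    ]
    return KeypointTrack(fps=float(fps), frames=frames, joint_names=list(joint_names))


def person_to_flat(person: dict, joint_names: list[str]) -> list[float]:
    out: list[float] = []
    for j in joint_names:
        x, y, c = person.get(j, (0.0, 0.0, 0.0))
        out.extend([float(x), float(y), float(c)])
    return out


def flat_to_person(flat: list[float], joint_names: list[str]) -> dict:
    return {
        j: (flat[3 * i], flat[3 * i + 1], flat[3 * i + 2])
        for i, j in enumerate(joint_names)
    }


# ---------------------------------------------------------------------------
# Frame stacks


def write_frames(stack: np.ndarray, path: str | Path, fps: float = 25.0) -> Path:
    """Write a grayscale (n, h, w) or RGB (n, h, w, 3) stack.

    A ``.npz`` path gets the array container; a directory gets PNG images.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, frames=stack, fps=np.array(fps))
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.asarray(stack), 0, 255).astype(np.uint8)
        for i, frame in enumerate(arr):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
        (path / "meta.json").write_text(json.dumps({"fps": fps}))
    return path


def read_frames(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        stack = np.stack([iio.imread(f) for f in files]).astype(float)
        fps = 25.0
        meta = path / "meta.json"
        if meta.exists():
            fps = float(json.loads(meta.read_text())["fps"])
        return stack, fps
    with np.load(path) as z:
        return z["frames"].astype(float), float(z["fps"])


# ---------------------------------------------------------------------------
# Stamped delimited tables


def write_table(df: pd.DataFrame, path: str | Path, stamp: dict | None = None) -> Path:
    """Write a TSV with ``# key=value`` header comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (stamp or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]
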