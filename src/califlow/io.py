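"""Readers, writers, configuration echo, and the experiment log.

Frame streams are multi-page TIFF stacks or directories of numbered
PNG/TIFF frames; tabular outputs (detection matrices, signal tables,
motion tracks, spike matrices) are comma-separated text with a header row.
Every output directory receives the echoed run configuration and a
checksum manifest so a run is reproducible and verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import os
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml


class StreamError(Exception):
    pass


def read_stream(path: str | os.PathLike, fmt: str | None = None
                ) -> Iterator[np.ndarray]:
    """Yield grayscale frames in index order (the ImgSrc actor body).

    ``fmt`` is ``tiff_stack`` or ``frame_dir``; inferred from the path when
    omitted.  Each yielded array is one frame, native dtype.
    """
    path = Path(path)
    if fmt is None:
        fmt = "frame_dir" if path.is_dir() else "tiff_stack"
    if fmt == "tiff_stack":
        if not path.exists():
            raise StreamError(f"missing stack {path}")
        with tifffile.TiffFile(path) as tf:
            for i, page in enumerate(tf.pages):
                try:
                    yield page.asarray()
                except Exception as exc:  # pragma: no cover - corrupt file
                    raise StreamError(f"unreadable frame {i} in {path}") from exc
    elif fmt == "frame_dir":
        if not path.is_dir():
            raise StreamError(f"missing frame directory {path}")
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise StreamError(f"no frames in {path}")
        for i, f in enumerate(files):
            try:
                frame = iio.imread(f)
            except Exception as exc:
                raise StreamError(f"unreadable frame {i}: {f}") from exc
            if frame.ndim == 3:
                frame = frame[..., 0]
            yield frame
    else:
        raise StreamError(f"unknown stream format {fmt!r}")


def write_tiff_stack(path: str | os.PathLike, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames))


def write_frame_dir(path: str | os.PathLike, frames: np.ndarray,
                    prefix: str = "frame") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(path / f"{prefix}_{i:05d}.png", frame)


# -- tabular formats -----------------------------------------------------

def write_detection_matrix(path, delta: np.ndarray) -> None:
    delta = np.asarray(delta).reshape(-1, 3)
    df = pd.DataFrame({"neuron_id": np.arange(delta.shape[0]),
                       "x": delta[:, 0], "y": delta[:, 1],
                       "radius": delta[:, 2]})
    df.to_csv(path, index=False)


def read_detection_matrix(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x", "y", "radius"]].to_numpy(dtype=np.float64)


def write_signal_table(path, table: np.ndarray) -> None:
    table = np.asarray(table)
    cols = {"frame_index": np.arange(table.shape[0])}
    for i in range(table.shape[1]):
        cols[f"n{i}"] = table[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_signal_table(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["frame_index"]).to_numpy(dtype=np.float64)


def write_track(path, track: np.ndarray,
                statuses: list[str] | None = None) -> None:
    track = np.asarray(track).reshape(-1, 3)
    data = {"frame": np.arange(track.shape[0]), "tx": track[:, 0],
            "ty": track[:, 1], "theta": track[:, 2]}
    if statuses is not None:
        data["status"] = statuses
    pd.DataFrame(data).to_csv(path, index=False)


def read_track(path) -> tuple[np.ndarray, list[str] | None]:
    df = pd.read_csv(path)
    track = df[["tx", "ty", "theta"]].to_numpy(dtype=np.float64)
    statuses = df["status"].tolist() if "status" in df else None
    return track, statuses


def write_spikes(path, spikes: np.ndarray) -> None:
    # frame-major: one row per frame, one column per neuron
    spikes = np.asarray(spikes)
    df = pd.DataFrame(spikes.T,
                      columns=[f"n{i}" for i in range(spikes.shape[0])])
    df.insert(0, "frame", np.arange(spikes.shape[1]))
    df.to_csv(path, index=False)


def read_spikes(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["frame"]).to_numpy(dtype=np.uint8).T


def write_masks(path, masks: np.ndarray, index_path=None) -> None:
    tifffile.imwrite(path, (np.asarray(masks) > 0).astype(np.uint8) * 255)
    if index_path is not None:
        rows = []
        for i in range(masks.shape[0]):
            ys, xs = np.nonzero(masks[i])
            rows.append({"neuron_id": i, "centroid_x": xs.mean(),
                         "centroid_y": ys.mean(),
                         "width": xs.max() - xs.min() + 1,
                         "height": ys.max() - ys.min() + 1})
        pd.DataFrame(rows).to_csv(index_path, index=False)


def read_masks(path) -> np.ndarray:
    return tifffile.imread(path) > 0


# -- config echo, log, manifest ------------------------------------------

def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_log(path, log) -> None:
    with open(path, "w") as fh:
        fh.write(log.dump() + "\n")


def write_manifest(outdir: str | os.PathLike,
                   manifest_name: str = "MANIFEST.sha256") -> None:
    """Checksum every regular file in the output directory."""
    outdir = Path(outdir)
    lines = []
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != manifest_name:
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            lines.append(f"{digest}  {p.relative_to(outdir)}")
    (outdir / manifest_name).write_text("\n".join(lines) + "\n")
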