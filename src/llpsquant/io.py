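"""File I/O for the pipeline's standard formats.

Image stacks travel as multi-page TIFF with CZYX axes and pixel-size
metadata (written via tifffile); FRAP traces as CSV with a
``# n_pre_frames=N`` header line followed by time_s/bleached/reference
columns; ground truth as JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .foci import ImageStack
from .frap import RecoveryTrace
from .synthetic import GroundTruth


def write_stack_tiff(path: str | Path, stack: ImageStack) -> None:
    meta = {
        "axes": "CZYX",
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": stack.channel_names,
    }
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        metadata=meta,
    )


def read_stack_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a CZYX TIFF; explicit geometry arguments override metadata."""
    with tifffile.TiffFile(str(path)) as tf:
        voxels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if voxels.ndim == 3:  # single channel written without C axis
        voxels = voxels[None]
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    zs = z_step_um if z_step_um is not None else meta.get("z_step_um")
    if px is None or zs is None:
        raise ValueError(f"{path}: pixel geometry missing from metadata; pass overrides")
    names = meta.get("channel_names") or [f"ch{i}" for i in range(voxels.shape[0])]
    return ImageStack(
        voxels=np.asarray(voxels, dtype=np.float64),
        pixel_size_um=float(px),
        z_step_um=float(zs),
        channel_names=list(names),
    )


def write_trace_csv(path: str | Path, trace: RecoveryTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_pre_frames={trace.n_pre_frames}\n")
        pd.DataFrame(
            {
                "time_s": trace.times_s,
                "bleached": trace.bleached_intensity,
                "reference": trace.reference_intensity,
            }
        ).to_csv(fh, index=False)


def read_trace_csv(path: str | Path, n_pre_frames: int | None = None) -> RecoveryTrace:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "n_pre_frames=" in first:
            header_npre = int(first.split("n_pre_frames=")[1].strip())
            df = pd.read_csv(fh)
        else:
            header_npre = None
            fh.seek(0)
            df = pd.read_csv(fh)
    npre = n_pre_frames if n_pre_frames is not None else header_npre
    if npre is None:
        raise ValueError(f"{path}: n_pre_frames not in header; pass it explicitly")
    return RecoveryTrace(
        times_s=df["time_s"].to_numpy(),
        bleached_intensity=df["bleached"].to_numpy(),
        reference_intensity=df["reference"].to_numpy(),
        n_pre_frames=npre,
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    d = asdict(truth)
    for key, val in list(d.items()):
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, default=float)
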