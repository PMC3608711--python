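"""File formats: multi-frame TIFF stacks with JSON sidecars.

A phase-stepping scan is stored as a multi-frame TIFF (frame k = step
k) next to a JSON sidecar carrying the acquisition metadata (ids,
group, seed, step fractions).  Retrieved maps and truth maps are 32-bit
float TIFFs; masks are 8-bit TIFFs; overlays are PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from PIL import Image

from .phantom import StepScan

__all__ = [
    "write_stepscan",
    "read_stepscan",
    "write_map",
    "read_map",
    "write_mask",
    "read_mask",
    "write_png",
]


class SidecarError(ValueError):
    """Missing or inconsistent sidecar metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stepscan(path: str | Path, scan: StepScan) -> Path:
    """Write frames as a multi-frame TIFF plus a JSON sidecar.

    Poisson counts are integers well below 2**24, so the float32
    on-disk representation round-trips them exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, scan.frames.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "n_steps": scan.n_steps,
        "step_fractions": [float(f) for f in scan.step_fractions],
        "is_reference": bool(scan.is_reference),
        "specimen_id": scan.specimen_id,
        "projection_index": int(scan.projection_index),
        "seed": scan.seed,
    }
    _sidecar_path(path).write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return path


def read_stepscan(
    path: str | Path, n_steps: Optional[int] = None
) -> StepScan:
    """Read a stepping scan written by :func:`write_stepscan`.

    A foreign multi-frame TIFF without a sidecar is accepted when
    ``n_steps`` is given: uniform step fractions over one period are
    synthesized.  A frame count disagreeing with the sidecar (or with
    ``n_steps``) is a structural error.
    """
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        meta = json.loads(sidecar_file.read_text())
        if meta["n_steps"] != frames.shape[0]:
            raise SidecarError(
                f"sidecar declares {meta['n_steps']} steps but "
                f"{path.name} holds {frames.shape[0]} frames"
            )
        return StepScan(
            frames=frames,
            step_fractions=np.asarray(meta["step_fractions"]),
            is_reference=meta["is_reference"],
            specimen_id=meta.get("specimen_id", ""),
            projection_index=meta.get("projection_index", -1),
            seed=meta.get("seed"),
        )
    if n_steps is None:
        raise SidecarError(
            f"no sidecar next to {path.name}; pass n_steps to accept a "
            f"foreign stack with synthesized uniform step fractions"
        )
    if frames.shape[0] != n_steps:
        raise SidecarError(
            f"expected {n_steps} frames, found {frames.shape[0]}"
        )
    return StepScan(
        frames=frames,
        step_fractions=np.arange(n_steps) / n_steps,
        is_reference=False,
    )


def write_map(path: str | Path, array: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)


def write_png(path: str | Path, rgb: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb).save(path, format="PNG")
    return path
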