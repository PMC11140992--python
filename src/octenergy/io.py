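"""Readers and writers: multi-page TIFF stacks with JSON sidecars, trace
and biomarker CSVs.  CSVs round-trip at full float precision (values are
written with Python's shortest-roundtrip repr)."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import BScanStack, GroundTruth, PhantomConfig

__all__ = [
    "FormatError",
    "write_stack",
    "read_stack",
    "write_traces",
    "read_traces",
    "write_records",
    "read_records",
    "write_ground_truth",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: BScanStack, path: str | Path) -> Path:
    """Write frames as a multi-page 16-bit grayscale TIFF plus a JSON
    metadata sidecar (pixel sizes, nerve-head column, free-form
    metadata)."""

    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames.astype(float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "axial_px_um": stack.axial_px_um,
        "lateral_px_um": stack.lateral_px_um,
        "onh_col": int(stack.onh_col),
        "metadata": _jsonable(stack.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_stack(path: str | Path, **overrides) -> BScanStack:
    """Read a TIFF stack and its sidecar back into a :class:`BScanStack`.

    8-bit input is promoted to 16-bit (scaled by 257) with a warning;
    missing sidecar fields may be supplied as keyword overrides."""

    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D/3-D grayscale stack, got shape {frames.shape}")
    if frames.dtype == np.uint8:
        log.warning("%s: 8-bit input promoted to 16-bit (x257)", path)
        frames = frames.astype(np.uint16) * 257
    elif frames.dtype != np.uint16:
        raise FormatError(f"{path}: unsupported dtype {frames.dtype}")

    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        try:
            meta = json.loads(side.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed sidecar {side}: {exc}") from exc
    def pick(key, default=None):
        if key in overrides:
            return overrides[key]
        if key in meta:
            return meta[key]
        if default is None:
            raise FormatError(f"{path}: missing required metadata {key!r}")
        return default

    return BScanStack(
        frames=frames,
        axial_px_um=float(pick("axial_px_um")),
        lateral_px_um=float(pick("lateral_px_um")),
        onh_col=int(pick("onh_col", frames.shape[2] // 2)),
        metadata=meta.get("metadata", {}),
    )


def write_traces(traces: dict, path: str | Path) -> Path:
    """Traces CSV: column, layer, depth_px, confidence."""

    rows = []
    for layer, tr in traces.items():
        conf = tr.confidence if tr.confidence is not None else np.full(tr.depth.size, np.nan)
        for c in range(tr.depth.size):
            rows.append((c, layer, tr.depth[c], conf[c]))
    df = pd.DataFrame(rows, columns=["column", "layer", "depth_px", "confidence"])
    df.to_csv(path, index=False)
    return Path(path)


def read_traces(path: str | Path) -> dict:
    from .segmentation import BoundaryTrace

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read traces CSV {path}: {exc}") from exc
    needed = {"column", "layer", "depth_px"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: traces CSV must have columns {sorted(needed)}")
    out = {}
    for layer, sub in df.groupby("layer", sort=False):
        sub = sub.sort_values("column")
        conf = sub["confidence"].to_numpy() if "confidence" in sub else None
        out[str(layer)] = BoundaryTrace(str(layer), sub["depth_px"].to_numpy(), conf)
    return out


def write_records(df: pd.DataFrame, path: str | Path, append: bool = False) -> Path:
    path = Path(path)
    if append and path.exists():
        df.to_csv(path, index=False, mode="a", header=False)
    else:
        df.to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read records CSV {path}: {exc}") from exc


def write_ground_truth(
    truth: GroundTruth, path_csv: str | Path, mouse: str = "", frame: int = 0
) -> Path:
    """Ground truth as tidy CSV (mouse, frame, column, layer, depth_px)
    with a JSON sidecar of per-frame transforms and the generator
    config."""

    rows = []
    for layer, depth in truth.boundaries.items():
        for c, d in enumerate(depth):
            rows.append((mouse, frame, c, layer, d))
    df = pd.DataFrame(rows, columns=["mouse", "frame", "column", "layer", "depth_px"])
    path_csv = Path(path_csv)
    df.to_csv(path_csv, index=False)
    side = {
        "elm_rpe_um": truth.elm_rpe_um,
        "ez_elongation": truth.ez_elongation,
        "frame_transforms": [list(t) for t in truth.frame_transforms],
        "config": _jsonable(asdict(truth.config)) if truth.config is not None else None,
    }
    _sidecar(path_csv).write_text(json.dumps(side, indent=1, sort_keys=True))
    return path_csv
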