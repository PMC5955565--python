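"""File formats: multi-page TIFF stacks with JSON sidecars, map/mask TIFFs.

A polarization stack is stored as a multi-page 32-bit float TIFF (page k =
angle alpha_k) next to a ``<stem>.json`` sidecar holding the angle list,
pixel size and acquisition parameters — angle metadata in TIFF tags varies
too much between writers to be portable.  Order maps are written as a float
TIFF pair (rho, psi) plus an 8-bit validity mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .masking import ActinMask
from .polarimetry import OrderMaps, PolarizationStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_order_maps",
    "read_order_maps",
    "write_mask",
    "read_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: PolarizationStack, extra: dict | None = None) -> Path:
    """Write a stack as multi-page float32 TIFF + JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {
        "angles_deg": [float(a) for a in stack.angles],
        "pixel_size_nm": float(stack.pixel_size),
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_stack(path, angle_spec=None, pixel_size: float | None = None) -> PolarizationStack:
    """Read a multi-page TIFF stack; angles from ``angle_spec`` or the sidecar.

    Page bit depths of 8/16/32 are accepted and promoted to float.  A page
    count differing from the angle count is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    angles = np.asarray(angle_spec if angle_spec is not None else meta.get("angles_deg"), dtype=float) \
        if (angle_spec is not None or "angles_deg" in meta) else None
    if angles is None:
        raise ValueError(f"no angle list given and no sidecar found for {path}")
    if data.shape[0] != len(angles):
        raise ValueError(
            f"{path}: {data.shape[0]} pages but {len(angles)} angles"
        )
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_nm", 154.0))
    return PolarizationStack(data=data, angles=angles, pixel_size=px)


def write_order_maps(outdir, order: OrderMaps, prefix: str = "order") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rho": outdir / f"{prefix}_rho.tif",
        "psi": outdir / f"{prefix}_psi.tif",
        "valid": outdir / f"{prefix}_valid.tif",
    }
    tifffile.imwrite(paths["rho"], order.rho.astype(np.float32))
    tifffile.imwrite(paths["psi"], order.psi.astype(np.float32))
    tifffile.imwrite(paths["valid"], order.valid.astype(np.uint8))
    (outdir / f"{prefix}_maps.json").write_text(
        json.dumps({"pixel_size_nm": float(order.pixel_size)}, indent=2)
    )
    return paths


def read_order_maps(outdir, prefix: str = "order") -> OrderMaps:
    outdir = Path(outdir)
    rho = tifffile.imread(outdir / f"{prefix}_rho.tif").astype(float)
    psi = tifffile.imread(outdir / f"{prefix}_psi.tif").astype(float)
    valid = tifffile.imread(outdir / f"{prefix}_valid.tif").astype(bool)
    meta_path = outdir / f"{prefix}_maps.json"
    px = 154.0
    if meta_path.exists():
        px = float(json.loads(meta_path.read_text()).get("pixel_size_nm", px))
    return OrderMaps(rho=rho, psi=psi, valid=valid, clipped=np.zeros_like(valid), pixel_size=px)


def write_mask(path, mask: ActinMask) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
    meta = {
        "smoothing_scale_um": mask.smoothing_scale,
        "threshold": mask.threshold,
        "roi": None if mask.roi is None else np.asarray(mask.roi).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_mask(path) -> ActinMask:
    path = Path(path)
    arr = tifffile.imread(path) > 0
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    roi = meta.get("roi")
    return ActinMask(
        mask=arr,
        smoothing_scale=float(meta.get("smoothing_scale_um", np.nan)),
        threshold=float(meta.get("threshold", np.nan)),
        roi=None if roi is None else np.asarray(roi, dtype=float),
    )
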