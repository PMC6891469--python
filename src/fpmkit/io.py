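"""Readers and writers: multi-page TIFF stacks, field TIFF pairs, sidecars.

The canonical on-disk stack is a multi-page TIFF (16-bit unsigned for raw
camera codes, 32-bit float otherwise) with a JSON sidecar listing, per
page in order: LED index (m, n), exposure_ms, duty_cycle, plus the
normalized flag and any saturated-pixel coordinates.  Complex fields are
stored as paired 32-bit float amplitude/phase TIFFs with a JSON sidecar
carrying the pixel pitch and generator metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .samples import ComplexField
from .simulate import LRStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_field",
    "read_field",
    "write_trace_csv",
    "write_factors_csv",
    "write_json",
]


def write_stack(stack: LRStack, tiff_path: str | Path) -> Path:
    """Write images to multi-page TIFF and metadata to a ``.json`` sidecar."""
    tiff_path = Path(tiff_path)
    imgs = stack.images
    if imgs.dtype != np.uint16:
        imgs = imgs.astype(np.float32)
    tifffile.imwrite(tiff_path, imgs)
    sidecar = {
        "normalized": stack.normalized,
        "pages": [
            {
                "m": int(md["led_index"][0]),
                "n": int(md["led_index"][1]),
                "exposure_ms": float(md["exposure_ms"]),
                "duty_cycle": float(md["duty_cycle"]),
                "saturated_rc": np.argwhere(stack.sat_masks[i]).tolist(),
            }
            for i, md in enumerate(stack.metadata)
        ],
    }
    sidecar_path = tiff_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar))
    return sidecar_path


def read_stack(tiff_path: str | Path) -> LRStack:
    """Read a stack written by :func:`write_stack`; validates counts/shapes."""
    tiff_path = Path(tiff_path)
    images = tifffile.imread(tiff_path)
    if images.ndim == 2:
        images = images[None]
    sidecar_path = tiff_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"stack sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    pages = sidecar["pages"]
    if len(pages) != images.shape[0]:
        raise ValueError(
            f"sidecar lists {len(pages)} pages but TIFF has {images.shape[0]}"
        )
    metadata = []
    sat = np.zeros(images.shape, dtype=bool)
    for i, page in enumerate(pages):
        metadata.append(
            {
                "led_index": (page["m"], page["n"]),
                "exposure_ms": page["exposure_ms"],
                "duty_cycle": page["duty_cycle"],
            }
        )
        for r, c in page.get("saturated_rc", []):
            sat[i, r, c] = True
    return LRStack(
        images=images,
        metadata=metadata,
        sat_masks=sat,
        normalized=sidecar.get("normalized", False),
    )


def write_field(field: ComplexField, out_dir: str | Path, prefix: str = "field") -> dict[str, str]:
    """Write amplitude/phase float32 TIFF pair plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amp_path = out_dir / f"{prefix}_amplitude.tiff"
    phase_path = out_dir / f"{prefix}_phase.tiff"
    tifffile.imwrite(amp_path, field.amplitude.astype(np.float32))
    tifffile.imwrite(phase_path, field.phase.astype(np.float32))
    sidecar = {
        "pixel_pitch_um": field.pixel_pitch_um,
        "meta": _jsonable(field.meta),
    }
    sidecar_path = out_dir / f"{prefix}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {
        "amplitude": str(amp_path),
        "phase": str(phase_path),
        "sidecar": str(sidecar_path),
    }


def read_field(out_dir: str | Path, prefix: str = "field") -> ComplexField:
    out_dir = Path(out_dir)
    amp = tifffile.imread(out_dir / f"{prefix}_amplitude.tiff").astype(float)
    phase = tifffile.imread(out_dir / f"{prefix}_phase.tiff").astype(float)
    sidecar = json.loads((out_dir / f"{prefix}.json").read_text())
    return ComplexField(
        data=amp * np.exp(1j * phase),
        pixel_pitch_um=sidecar["pixel_pitch_um"],
        meta=sidecar.get("meta", {}),
    )


def write_trace_csv(trace: list[float], path: str | Path) -> None:
    lines = ["sweep,cost"] + [f"{i},{v:.10g}" for i, v in enumerate(trace)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_factors_csv(
    metadata: list[dict[str, Any]], factors: np.ndarray, path: str | Path
) -> None:
    lines = ["m,n,factor"]
    for md, c in zip(metadata, factors):
        m, n = md["led_index"]
        lines.append(f"{m},{n},{c:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonable(obj: Any) -> Any:
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


def write_json(data: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2))
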