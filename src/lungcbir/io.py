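"""Case readers and writers: MetaImage (.mhd/.raw) volumes, PNG slice
directories with a JSON manifest, and lossless NPZ stacks.

MetaImage is read through SimpleITK, which applies any rescale
slope/intercept in the header, so slices come back in Hounsfield units.
PNG is an 8-bit quantized export: intensities are windowed to
``PNG_WINDOW`` (HU) and scaled to 0..255; the window is recorded in the
manifest so the quantization is invertible up to the 8-bit step.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Tuple

import numpy as np
import SimpleITK as sitk
from PIL import Image

from .phantom import CaseSeries

logger = logging.getLogger(__name__)

PNG_WINDOW: Tuple[float, float] = (-1000.0, 400.0)


class FormatError(ValueError):
    pass


def write_case(case: CaseSeries, path, format: str = "mhd") -> Path:
    """Write a case as MetaImage ('mhd'), PNG directory ('png'), or NPZ.

    MetaImage and NPZ are lossless for float HU data; PNG quantizes to
    8 bits over the window recorded in the manifest.
    """
    path = Path(path)
    if format == "mhd":
        path.parent.mkdir(parents=True, exist_ok=True)
        vol = sitk.GetImageFromArray(case.stack().astype(np.float32))
        vol.SetSpacing((float(case.spacing[1]), float(case.spacing[0]), 1.0))
        target = path if path.suffix == ".mhd" else path.with_suffix(".mhd")
        sitk.WriteImage(vol, str(target))
        return target
    if format == "npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        target = path if path.suffix == ".npz" else path.with_suffix(".npz")
        np.savez_compressed(target, stack=case.stack(),
                            spacing=np.asarray(case.spacing, float),
                            case_id=np.array(case.case_id))
        return target
    if format == "png":
        path.mkdir(parents=True, exist_ok=True)
        lo, hi = PNG_WINDOW
        logger.info("PNG export of %s quantized over window [%g, %g] HU",
                    case.case_id, lo, hi)
        names = []
        for i, sl in enumerate(case.slices):
            q = np.clip((sl - lo) / (hi - lo), 0, 1)
            img = Image.fromarray((q * 255).round().astype(np.uint8))
            name = f"slice{i:04d}.png"
            img.save(path / name)
            names.append(name)
        manifest = {"case_id": case.case_id, "n_slices": len(case.slices),
                    "spacing": list(map(float, case.spacing)),
                    "window_hu": [lo, hi], "slices": names}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return path
    raise FormatError(f"unknown format {format!r}")


def read_case(path) -> CaseSeries:
    """Read a case written by :func:`write_case` (format auto-detected)."""
    path = Path(path)
    if path.is_dir():
        return _read_png_dir(path)
    if path.suffix == ".mhd":
        return _read_mhd(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            stack = z["stack"]
            return CaseSeries(str(z["case_id"]), [s for s in stack],
                              tuple(z["spacing"]))
    raise FormatError(f"cannot infer case format from {path}")


def _read_mhd(path: Path) -> CaseSeries:
    try:
        vol = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"malformed MetaImage {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(vol).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    sx, sy = vol.GetSpacing()[0], vol.GetSpacing()[1]
    return CaseSeries(path.stem, [s for s in arr], (float(sy), float(sx)))


def _read_png_dir(path: Path) -> CaseSeries:
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"PNG case directory {path} lacks manifest.json")
    manifest = json.loads(manifest_path.read_text())
    lo, hi = manifest.get("window_hu", PNG_WINDOW)
    slices = []
    for name in manifest["slices"]:         # manifest order wins over filenames
        f = path / name
        if not f.exists():
            raise FormatError(f"slice listed in manifest missing on disk: {f}")
        arr = np.asarray(Image.open(f), dtype=float) / 255.0
        slices.append(arr * (hi - lo) + lo)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes in {path}: {shapes}")
    return CaseSeries(manifest["case_id"], slices,
                      tuple(manifest.get("spacing", (1.0, 1.0))))


def write_dataset_manifest(path, cases, seed: int) -> None:
    entries = [{"case_id": c.case_id, "n_slices": c.n_slices,
                "spacing": list(map(float, c.spacing)), "seed": seed}
               for c in cases]
    Path(path).write_text(json.dumps(entries, indent=1))
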