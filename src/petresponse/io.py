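"""Raster image I/O (NIfTI and 16-bit PNG) and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError

log = logging.getLogger("petresponse")

PNG_SCALE = 65535


def write_image(array: np.ndarray, path) -> None:
    """Write a 2-D float image in [0, 1] (or a boolean mask) to disk.

    ``.nii``/``.nii.gz`` use NIfTI; ``.png`` uses 16-bit grayscale with
    intensities scaled by 65535.
    """
    path = Path(path)
    arr = np.asarray(array)
    if path.suffix == ".png":
        from PIL import Image

        data = (np.clip(arr.astype(float), 0.0, 1.0) * PNG_SCALE).round().astype(np.uint16)
        Image.fromarray(data).save(path)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine=np.eye(4)), str(path))
    else:
        raise ConfigurationError(f"unsupported image format {path.suffix!r} for {path}")


def read_image(path) -> np.ndarray:
    """Read a 2-D image written by :func:`write_image`; returns floats in [0, 1]
    for PNG and raw floats for NIfTI."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    if path.suffix == ".png":
        from PIL import Image

        return np.asarray(Image.open(path), dtype=float) / PNG_SCALE
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return np.squeeze(data)
    raise ConfigurationError(f"unsupported image format {path.suffix!r} for {path}")


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int | None, artifacts) -> Path:
    """Record one artifact-producing command: config snapshot, seed, digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "artifacts": {str(Path(p).name): sha256_of(p) for p in artifacts},
    }
    path = out_dir / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def manifest_matches(out_dir, command: str, artifacts) -> bool:
    """True when a previous manifest exists and all artifact digests match."""
    path = Path(out_dir) / f"{command}.manifest.json"
    if not path.exists():
        return False
    try:
        recorded = json.loads(path.read_text())["artifacts"]
    except (json.JSONDecodeError, KeyError):
        return False
    for p in artifacts:
        p = Path(p)
        if not p.exists() or recorded.get(p.name) != sha256_of(p):
            return False
    return True
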