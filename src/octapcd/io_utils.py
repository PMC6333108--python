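"""Reading and writing angiograms, masks and sidecar metadata.

Angiograms travel as 8-bit grayscale PNG (or TIFF) with a JSON sidecar that
carries the physical scale, laterality, slab, signal strength index and —
for synthetic images — the ground-truth density values.  Masks are written
as 8-bit PNG (0/255).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError
from .segmentation import Angiogram


def sidecar_path(image_path) -> Path:
    p = Path(image_path)
    return p.with_suffix(p.suffix + ".json")


def write_angiogram(
    image: Angiogram,
    path,
    extra_metadata: Optional[Dict] = None,
) -> Path:
    """Write an angiogram as 8-bit grayscale plus a JSON sidecar.

    Pixel intensities are assumed in [0, 1] and quantised to 0-255.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(path, (np.round(px * 255)).astype(np.uint8))
    meta = {
        "scale_um_per_px": image.scale_um_per_px,
        "laterality": image.laterality,
        "slab": image.slab,
        "ssi": image.ssi,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_angiogram(path) -> Tuple[Angiogram, Dict]:
    """Read an angiogram written by :func:`write_angiogram`.

    Returns the image (intensities rescaled to [0, 1]) and the full sidecar
    metadata dictionary.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise ValidationError(f"missing sidecar metadata file: {side}")
    meta = json.loads(side.read_text())
    raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D grayscale image")
    maxval = 65535.0 if raw.dtype == np.uint16 else 255.0
    image = Angiogram(
        pixels=raw.astype(float) / maxval,
        scale_um_per_px=float(meta["scale_um_per_px"]),
        laterality=meta.get("laterality", "OD"),
        slab=meta.get("slab", "irVD"),
        ssi=float(meta.get("ssi", 65.0)),
    )
    return image, meta


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path) -> np.ndarray:
    return iio.imread(Path(path)) > 127
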