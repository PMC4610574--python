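"""Image and annotation readers/writers and the output naming convention.

Overlay images are stored as ``[name]_[date]_[count].jpg`` with the date
formatted ``day-month-year_hour.minutes.seconds.milliseconds``
(``dd-MM-yyyy_HH.mm.ss.SSS``), the convention of the original field
tool, so a folder of results is self-describing.  Flower centers travel
as one CSV per image with a ``row,col`` header, 0-based coordinates.
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "format_output_date",
    "output_filename",
    "write_centers_csv",
    "read_centers_csv",
    "write_manifest",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG as 8-bit RGB; alpha is dropped with a warning."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        rgb = im.convert("RGB")
        return np.asarray(rgb, dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray, quality: int = 95) -> None:
    Image.fromarray(image).save(path, quality=quality)


def format_output_date(when: datetime) -> str:
    """``dd-MM-yyyy_HH.mm.ss.SSS`` with milliseconds zero-padded to 3."""
    ms = when.microsecond // 1000
    return when.strftime("%d-%m-%Y_%H.%M.%S") + f".{ms:03d}"


def output_filename(name: str, count: int, when: datetime | None = None) -> str:
    """Overlay filename ``[name]_[date]_[count].jpg``."""
    when = when or datetime.now()
    return f"{name}_{format_output_date(when)}_{count}.jpg"


def write_centers_csv(path: str | Path, centers) -> None:
    pd.DataFrame(list(centers), columns=["row", "col"]).to_csv(path, index=False)


def read_centers_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["row", "col"]:
        raise ValueError(f"{path}: expected header 'row,col', got {list(df.columns)}")
    return [(float(r), float(c)) for r, c in zip(df["row"], df["col"])]


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
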