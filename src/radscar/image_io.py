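"""Reading and writing images, masks, feature tables and metric files.

In-memory conventions
---------------------
* An *HU image* is a 2-D ``float64`` ndarray whose values are Hounsfield
  units; rows are indexed top-down, columns left-right, 0-based.
* A *binary mask* is a 2-D ``bool`` ndarray of the same shape as the image
  it annotates.
* All rectangular regions are half-open ``[r0, r1) x [c0, c1)``.

File dialects
-------------
``png16``
    16-bit grayscale PNG. Stored integer ``v`` maps to ``v - 1024`` HU
    (the CT convention: air at -1024 HU is stored as 0), so negative HU
    survive the unsigned container. Writing rounds to the nearest integer.
``tiff``
    Single-page TIFF. Integer pixel types use the same -1024 offset;
    floating-point TIFFs carry HU verbatim.
``csv-matrix``
    Comma-separated rows, no header, one row per image row; values are HU
    verbatim at full float precision. Lossless for any finite image.

Masks are stored as 8-bit PNG with values {0, 255} or csv-matrix with
values {0, 1}. Any other stored value is rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    MaskValueError,
    NonFiniteValueError,
    RaggedMatrixError,
    UnsupportedBitDepthError,
    UnsupportedDialectError,
)

HU_OFFSET = 1024  # stored integer = HU + 1024 for png16/tiff

_EXT_TO_DIALECT = {
    ".png": "png16",
    ".tif": "tiff",
    ".tiff": "tiff",
    ".csv": "csv-matrix",
    ".txt": "csv-matrix",
}


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("png16", "tiff", "csv-matrix"):
            raise UnsupportedDialectError(f"unknown dialect {dialect!r}")
        return dialect
    try:
        return _EXT_TO_DIALECT[path.suffix.lower()]
    except KeyError:
        raise UnsupportedDialectError(
            f"cannot infer dialect from suffix {path.suffix!r}; pass dialect="
        ) from None


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise RaggedMatrixError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {width}"
                )
            rows.append([float(c) for c in cells])
    if not rows:
        raise RaggedMatrixError(f"{path}: empty matrix")
    return np.asarray(rows, dtype=np.float64)


def read_image(path, dialect: str | None = None) -> np.ndarray:
    """Read an HU image.

    Parameters
    ----------
    path : path-like
    dialect : {"png16", "tiff", "csv-matrix"}, optional
        Inferred from the file suffix when omitted.

    Returns
    -------
    ndarray of float64, shape (height, width), values in HU.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv-matrix":
        img = _read_csv_matrix(path)
    else:
        raw = np.asarray(iio.imread(path))
        if raw.ndim != 2:
            raise UnsupportedBitDepthError(
                f"{path}: expected a single-channel 2-D image, got shape {raw.shape}"
            )
        if dialect == "png16":
            if raw.dtype != np.uint16:
                raise UnsupportedBitDepthError(
                    f"{path}: png16 dialect requires 16-bit pixels, got {raw.dtype}"
                )
            img = raw.astype(np.float64) - HU_OFFSET
        else:  # tiff
            if np.issubdtype(raw.dtype, np.integer):
                img = raw.astype(np.float64) - HU_OFFSET
            elif np.issubdtype(raw.dtype, np.floating):
                img = raw.astype(np.float64)
            else:
                raise UnsupportedBitDepthError(f"{path}: pixel type {raw.dtype}")
    if not np.all(np.isfinite(img)):
        raise NonFiniteValueError(f"{path}: non-finite pixel values")
    return img


def write_image(image: np.ndarray, path, dialect: str | None = None) -> None:
    """Write an HU image under the named dialect (see module docstring)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise NonFiniteValueError("image has non-finite values")
    if dialect == "csv-matrix":
        np.savetxt(path, image, delimiter=",", fmt="%.17g")
        return
    stored = np.rint(image) + HU_OFFSET
    if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
        raise ValueError(
            "HU values outside the uint16 storable range [-1024, 64511]"
        )
    iio.imwrite(path, stored.astype(np.uint16))


def read_mask(path, dialect: str | None = None) -> np.ndarray:
    """Read a binary mask stored as 0/255 PNG or 0/1 csv-matrix."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv-matrix":
        vals = _read_csv_matrix(path)
        allowed = (0.0, 1.0)
    else:
        vals = np.asarray(iio.imread(path)).astype(np.float64)
        if vals.ndim != 2:
            raise MaskValueError(f"{path}: mask must be single-channel")
        allowed = (0.0, 255.0)
    bad = ~np.isin(vals, allowed)
    if bad.any():
        sample = vals[bad].flat[0]
        raise MaskValueError(
            f"{path}: mask value {sample!r} not in {set(allowed)}"
        )
    return vals == allowed[1]


def write_mask(mask: np.ndarray, path, dialect: str | None = None) -> None:
    """Write a binary mask (0/255 PNG or 0/1 csv-matrix); lossless round trip."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if dialect == "csv-matrix":
        np.savetxt(path, mask.astype(np.uint8), delimiter=",", fmt="%d")
    elif dialect == "png16":
        iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8))
    else:
        iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8), extension=".tiff")


def write_feature_table(rows: list[dict], path) -> None:
    """Write a feature table CSV with header ``patch_id,label,f0..f9``.

    Each row dict must have keys ``patch_id``, ``label`` and ``bins``
    (a length-10 sequence).
    """
    records = []
    for row in rows:
        rec = {"patch_id": row["patch_id"], "label": row["label"]}
        for i, v in enumerate(row["bins"]):
            rec[f"f{i}"] = float(v)
        records.append(rec)
    cols = ["patch_id", "label"] + [f"f{i}" for i in range(10)]
    pd.DataFrame.from_records(records)[cols].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a ``patch_id,label,f0..f9`` CSV into a DataFrame."""
    df = pd.read_csv(path)
    expected = ["patch_id", "label"] + [f"f{i}" for i in range(10)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise UnsupportedDialectError(f"{path}: missing columns {missing}")
    return df[expected]


def write_metrics(metrics: dict, path) -> None:
    """Write a metrics dict as deterministic JSON (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
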