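"""Extraction of fixed-size labeled tiles from class regions.

A patch is eligible only if its full ``patch_size x patch_size`` tile lies
inside the class mask — mixed-label tiles would make the supervised labels
ambiguous. Origins are top-left corners; tiles are half-open
``[r, r+s) x [c, c+s)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientOriginsError, PatchSizeError, ShapeMismatchError

DEFAULT_PATCH_SIZE = 25

LABELS = ("scar", "normal")


@dataclass
class Patch:
    """A labeled intensity tile.

    Attributes
    ----------
    pixels : ndarray, (patch_size, patch_size), HU
    label : {"scar", "normal"}
    origin : (row, col) of the top-left corner in the source image
    source_id : str, provenance tag (phantom seed, file stem, ...)
    """

    pixels: np.ndarray
    label: str
    origin: tuple[int, int]
    source_id: str = ""

    @property
    def patch_id(self) -> str:
        return f"{self.source_id or 'img'}:{self.label}:{self.origin[0]}_{self.origin[1]}"


def eligible_origins(mask: np.ndarray, patch_size: int) -> list[tuple[int, int]]:
    """All top-left corners whose tile lies entirely in true mask pixels.

    Returned in row-major order. Computed with an integral image, so cost
    is O(H*W) regardless of patch size.
    """
    mask = np.asarray(mask, dtype=bool)
    if patch_size < 1:
        raise PatchSizeError(f"patch_size must be >= 1, got {patch_size}")
    h, w = mask.shape
    if patch_size > h or patch_size > w:
        raise PatchSizeError(
            f"patch_size {patch_size} exceeds image shape {mask.shape}"
        )
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = mask.cumsum(axis=0).cumsum(axis=1)
    s = patch_size
    window = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    rows, cols = np.nonzero(window == s * s)
    return list(zip(rows.tolist(), cols.tolist()))


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    label: str,
    n: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    overlap_policy: str = "any",
    source_id: str = "",
) -> list[Patch]:
    """Sample ``n`` labeled patches whose tiles lie fully inside ``mask``.

    Origins are a seeded shuffle of :func:`eligible_origins`, taken without
    replacement. Under ``overlap_policy="disjoint"`` an origin whose tile
    overlaps an already accepted tile is skipped (greedy, in shuffled
    order); ``"any"`` allows overlapping tiles.

    Raises
    ------
    InsufficientOriginsError
        If fewer than ``n`` origins are usable; carries the available count.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ShapeMismatchError(f"image {image.shape} vs mask {mask.shape}")
    if overlap_policy not in ("any", "disjoint"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    if n == 0:
        return []
    origins = eligible_origins(mask, patch_size)
    if overlap_policy == "any" and len(origins) < n:
        raise InsufficientOriginsError(n, len(origins), f"label {label!r}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(origins))
    occupied = np.zeros(image.shape, dtype=bool)
    out: list[Patch] = []
    for idx in order:
        r, c = origins[idx]
        if overlap_policy == "disjoint":
            if occupied[r : r + patch_size, c : c + patch_size].any():
                continue
            occupied[r : r + patch_size, c : c + patch_size] = True
        out.append(
            Patch(
                pixels=image[r : r + patch_size, c : c + patch_size].copy(),
                label=label,
                origin=(r, c),
                source_id=source_id,
            )
        )
        if len(out) == n:
            return out
    raise InsufficientOriginsError(
        n, len(out), f"label {label!r}, policy {overlap_policy!r}"
    )


def save_patch_set(patch_list: list[Patch], out_dir) -> Path:
    """Serialize patches as csv-matrix tiles plus a manifest CSV.

    The manifest has columns ``patch_id,label,row,col,source_id`` and one
    tile file ``<index>.csv`` per patch, in manifest order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, p in enumerate(patch_list):
        tile = out_dir / f"{i:05d}.csv"
        np.savetxt(tile, p.pixels, delimiter=",", fmt="%.17g")
        records.append(
            {
                "patch_id": p.patch_id,
                "label": p.label,
                "row": p.origin[0],
                "col": p.origin[1],
                "source_id": p.source_id,
                "file": tile.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


def load_patch_set(manifest_path) -> list[Patch]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        pixels = np.loadtxt(
            manifest_path.parent / rec["file"], delimiter=",", ndmin=2
        )
        out.append(
            Patch(
                pixels=pixels,
                label=rec["label"],
                origin=(int(rec["row"]), int(rec["col"])),
                source_id=str(rec["source_id"]),
            )
        )
    return out
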