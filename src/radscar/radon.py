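"""Radon transform of square tiles: the sinogram ("Radon image").

For a projection angle theta (degrees), every pixel at position
``(row, col)`` contributes its full value to the signed offset

    t = (col - c) * cos(theta) + (row - c) * sin(theta)

where ``c = (n - 1) / 2`` is the tile center, and the value is split
linearly between the two unit-spaced offset bins bracketing ``t``
(1-D bilinear splatting). This is the adjoint formulation of
rotate-and-sum projection and has exact conservation and symmetry
properties:

* per-angle mass conservation — each pixel's splat weights sum to 1 and
  the offset axis is padded to the tile diagonal, so no mass leaves;
* projection at 0 deg equals the column sums, at 90 deg the row sums;
* the projection at theta + 180 deg is the offset-reversal of the
  projection at theta;
* linearity in the image.

Angles default to 0..179 deg in 1-degree steps, the conventional
half-circle sampling (theta and theta+180 are redundant up to reversal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyAngleSetError, NonSquareImageError
from .patches import Patch

DEFAULT_ANGLES = tuple(float(a) for a in range(180))


@dataclass
class Sinogram:
    """Projection grid indexed (offset_bin, angle_index).

    ``values[i, j]`` is the line-integral mass (HU*pixels) at signed
    offset ``offsets[i]`` from the tile center, for ``angles[j]`` degrees.
    Offsets are symmetric about 0 at unit spacing.
    """

    values: np.ndarray
    angles: np.ndarray
    offsets: np.ndarray


def _as_square_array(patch) -> np.ndarray:
    img = patch.pixels if isinstance(patch, Patch) else patch
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise NonSquareImageError(f"need a square 2-D tile, got shape {img.shape}")
    return img


def radon_transform(patch, angles=None) -> Sinogram:
    """Project a square tile (or :class:`~radscar.patches.Patch`) over angles.

    Parameters
    ----------
    patch : Patch or square 2-D array
    angles : sequence of degrees, optional (default 0..179 step 1)

    Returns
    -------
    Sinogram with ``values`` of shape ``(n_offsets, n_angles)``.
    """
    img = _as_square_array(patch)
    if angles is None:
        angles = DEFAULT_ANGLES
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size == 0:
        raise EmptyAngleSetError("need at least one projection angle")

    n = img.shape[0]
    # pad the offset axis to the tile diagonal so no mass leaves the frame
    m = int(np.ceil(n * np.sqrt(2.0) / 2.0))
    offsets = np.arange(-m, m + 1, dtype=np.float64)
    n_off = offsets.size
    n_ang = angles.size

    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    x = (cols - c).ravel()  # along +col axis
    y = (rows - c).ravel()  # along +row axis
    v = img.ravel()

    rad = np.deg2rad(angles)
    # t[p, j]: signed offset of pixel p at angle j
    t = np.outer(x, np.cos(rad)) + np.outer(y, np.sin(rad))
    shifted = t + m  # bin coordinate in [0, 2m]
    lo = np.floor(shifted).astype(np.int64)
    frac = shifted - lo

    ang_idx = np.broadcast_to(np.arange(n_ang), t.shape)
    vals = np.broadcast_to(v[:, None], t.shape)
    flat_lo = (lo * n_ang + ang_idx).ravel()
    size = n_off * n_ang
    sino = np.bincount(flat_lo, weights=(vals * (1.0 - frac)).ravel(), minlength=size)
    sino += np.bincount(
        flat_lo + n_ang, weights=(vals * frac).ravel(), minlength=size
    )[:size]
    return Sinogram(
        values=sino.reshape(n_off, n_ang), angles=angles.copy(), offsets=offsets
    )


def sinogram_to_image(s: Sinogram) -> np.ndarray:
    """Rescale the sinogram grid linearly onto [0, 255] for texture analysis.

    A constant sinogram maps to all zeros. The rescale is strictly
    monotone, so downstream LBP codes — which depend only on value order —
    are unaffected by the sinogram's absolute scale.
    """
    vals = np.asarray(s.values, dtype=np.float64)
    lo = vals.min()
    hi = vals.max()
    if hi == lo:
        return np.zeros_like(vals)
    return (vals - lo) * (255.0 / (hi - lo))


def save_sinogram(s: Sinogram, out_dir, stem: str) -> Path:
    """Write values as csv-matrix plus a JSON sidecar with angles/offsets."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    np.savetxt(csv_path, s.values, delimiter=",", fmt="%.17g")
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(
            {"angles": s.angles.tolist(), "offsets": s.offsets.tolist()},
            fh,
            sort_keys=True,
        )
        fh.write("\n")
    return csv_path


def load_sinogram(csv_path) -> Sinogram:
    import json

    csv_path = Path(csv_path)
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return Sinogram(
        values=values,
        angles=np.asarray(meta["angles"], dtype=np.float64),
        offsets=np.asarray(meta["offsets"], dtype=np.float64),
    )
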