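"""Synthetic short-axis cardiac-CT-like slices with ground-truth masks.

The real study population (delayed-enhancement cardiac CT of patients with
atrial fibrillation) is not publicly deposited, so this module generates
phantoms that emulate its intensity regime: an annular left-ventricular
myocardium whose healthy wall sits near 59 +/- 21 HU, with hyperenhanced
scar arcs whose mean exceeds the healthy mean by more than three standard
deviations — the condition under which the literature thresholding rule
can fire at all.

Two properties of real scar are emulated, nothing more:

* **intensity**: scar pixels are brighter (default mean + 4 SD);
* **texture**: the scar noise field is smoothed with a small moving-average
  window, giving it spatial correlation (and a lower point variance) that
  healthy myocardium, drawn i.i.d., lacks. This is what the Radon–LBP
  descriptor has to detect once intensity is normalized away.

Angles are measured in degrees, counterclockwise from the positive column
axis as seen on screen (i.e. with the row axis pointing down, visual CCW),
range [0, 360). Background (blood pool and exterior) is a constant 0 HU;
every statistic downstream is computed inside the myocardium mask, so the
background never enters the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from . import patches as _patches
from .errors import PhantomSpecError


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice.

    Attributes
    ----------
    image_size : int
        Side of the square image in pixels.
    center : (row, col) or None
        Annulus center; defaults to the image center.
    inner_radius, outer_radius : float
        Radii (pixels) bounding the myocardial annulus.
    myo_mean, myo_sd : float
        Healthy-myocardium intensity mean / SD in HU.
    scar_arcs : sequence of (start_deg, end_deg)
        Angular extents of scar; an arc with start > end wraps through 0.
    scar_mean : float or None
        Scar intensity mean in HU; defaults to ``myo_mean + 4 * myo_sd``
        and must exceed ``myo_mean + 3 * myo_sd``.
    scar_sd : float
        SD of the scar noise field *before* smoothing.
    scar_texture_scale : float
        Width (pixels) of the moving-average window applied to the scar
        noise field; values < 2 disable smoothing.
    seed : int
        Seed for the noise fields; the phantom is a pure function of spec.
    """

    image_size: int = 256
    center: tuple[float, float] | None = None
    inner_radius: float = 60.0
    outer_radius: float = 115.0
    myo_mean: float = 59.0
    myo_sd: float = 21.0
    scar_arcs: tuple = ((30.0, 90.0),)
    scar_mean: float | None = None
    scar_sd: float = 21.0
    scar_texture_scale: float = 3.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return tuple(self.center)
        c = self.image_size / 2.0
        return (c, c)

    def resolved_scar_mean(self) -> float:
        if self.scar_mean is not None:
            return float(self.scar_mean)
        return self.myo_mean + 4.0 * self.myo_sd

    def validate(self) -> None:
        if self.image_size < 1:
            raise PhantomSpecError("image_size must be positive")
        if not (0 < self.inner_radius < self.outer_radius < self.image_size / 2):
            raise PhantomSpecError(
                "need 0 < inner_radius < outer_radius < image_size/2, got "
                f"{self.inner_radius}, {self.outer_radius}, size {self.image_size}"
            )
        if self.myo_sd < 0 or self.scar_sd < 0:
            raise PhantomSpecError("noise SDs must be non-negative")
        if self.scar_texture_scale < 0:
            raise PhantomSpecError("scar_texture_scale must be >= 0")
        if self.scar_arcs and not (
            self.resolved_scar_mean() > self.myo_mean + 3.0 * self.myo_sd
        ):
            raise PhantomSpecError(
                "scar_mean must exceed myo_mean + 3*myo_sd so the intensity "
                "rule can detect scar"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = list(self.resolved_center())
        d["scar_mean"] = self.resolved_scar_mean()
        d["scar_arcs"] = [list(a) for a in self.scar_arcs]
        return d


def _arc_membership(angles_deg: np.ndarray, arcs) -> np.ndarray:
    member = np.zeros(angles_deg.shape, dtype=bool)
    for start, end in arcs:
        start %= 360.0
        end %= 360.0
        if start <= end:
            member |= (angles_deg >= start) & (angles_deg < end)
        else:  # wraps through 0 deg
            member |= (angles_deg >= start) | (angles_deg < end)
    return member


def generate_phantom(spec: PhantomSpec):
    """Render one phantom slice.

    Returns
    -------
    image : ndarray of float64, shape (size, size), HU
    myocardium : bool ndarray — the annulus
    scar : bool ndarray — annulus pixels whose polar angle lies in a scar arc
    """
    spec.validate()
    n = spec.image_size
    cr, cc = spec.resolved_center()
    rows, cols = np.mgrid[0:n, 0:n]
    dr = rows - cr
    dc = cols - cc
    radius = np.hypot(dr, dc)
    # visual CCW from +col axis; row axis points down, hence -dr
    angle = np.degrees(np.arctan2(-dr, dc)) % 360.0

    myocardium = (radius >= spec.inner_radius) & (radius <= spec.outer_radius)
    scar = myocardium & _arc_membership(angle, spec.scar_arcs)

    rng = np.random.default_rng(spec.seed)
    myo_field = rng.normal(spec.myo_mean, spec.myo_sd, size=(n, n))
    scar_field = rng.normal(spec.resolved_scar_mean(), spec.scar_sd, size=(n, n))
    window = int(round(spec.scar_texture_scale))
    if window >= 2:
        # smoothing the full field (not just scar pixels) keeps scar-edge
        # statistics identical to the interior
        scar_field = ndimage.uniform_filter(scar_field, size=window, mode="nearest")

    image = np.zeros((n, n), dtype=np.float64)
    image[myocardium] = myo_field[myocardium]
    image[scar] = scar_field[scar]
    return image, myocardium, scar


def phantom_patch_sets(
    spec: PhantomSpec,
    n_per_class: int,
    patch_size: int = 25,
    overlap_policy: str = "any",
):
    """Generate a phantom and sample labeled patches from its ground truth.

    Returns ``n_per_class`` patches fully inside the scar mask (label
    ``"scar"``) followed by ``n_per_class`` fully inside myocardium minus
    scar (label ``"normal"``). Sampling is a seeded shuffle of eligible
    origins, without replacement; seeds for the two classes are derived
    from ``spec.seed``.
    """
    image, myocardium, scar = generate_phantom(spec)
    if n_per_class == 0:
        return []
    normal_region = myocardium & ~scar
    sid = f"phantom-seed{spec.seed}"
    scar_patches = _patches.extract_patches(
        image, scar, "scar", n_per_class, patch_size=patch_size,
        seed=(spec.seed * 2 + 1) % 2**31, overlap_policy=overlap_policy,
        source_id=sid,
    )
    normal_patches = _patches.extract_patches(
        image, normal_region, "normal", n_per_class, patch_size=patch_size,
        seed=(spec.seed * 2 + 2) % 2**31, overlap_policy=overlap_policy,
        source_id=sid,
    )
    return scar_patches + normal_patches


def null_patch_sets(
    spec: PhantomSpec,
    n_per_class: int,
    patch_size: int = 25,
    overlap_policy: str = "any",
):
    """Negative-control sampler: both classes from the same distribution.

    Renders the phantom *without* scar arcs and draws ``2 * n_per_class``
    patches from healthy myocardium, arbitrarily labeling the first half
    "scar". Any downstream classifier should then sit at chance level and
    the class dissimilarity should be near zero; this is the calibration
    check that the pipeline does not manufacture signal.
    """
    null_spec = PhantomSpec(**{**spec.to_dict(), "scar_arcs": (), "center": spec.center})
    image, myocardium, _ = generate_phantom(null_spec)
    if n_per_class == 0:
        return []
    sid = f"phantom-null-seed{spec.seed}"
    drawn = _patches.extract_patches(
        image, myocardium, "normal", 2 * n_per_class, patch_size=patch_size,
        seed=(spec.seed * 2 + 3) % 2**31, overlap_policy=overlap_policy,
        source_id=sid,
    )
    out = []
    for i, p in enumerate(drawn):
        label = "scar" if i < n_per_class else "normal"
        out.append(
            _patches.Patch(
                pixels=p.pixels, label=label, origin=p.origin, source_id=sid
            )
        )
    return out
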