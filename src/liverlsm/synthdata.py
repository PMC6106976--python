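"""Synthetic CT-slice phantoms with ground truth.

Two generators cover the difficulties the segmentation pipeline targets:

* :func:`make_liver_phantom` draws a piecewise-near-constant "liver" (one
  or more discrete elliptical components) on a darker background, with
  optional dark internal vessels/tumors, an adjacent organ whose shared
  boundary is partially absent (a same-intensity bridge over a fraction of
  the interface, through which a leaking contour can escape), and additive
  Gaussian noise.  Ground truth is the liver envelope — the union of the
  components with internal structures NOT carved out.

* :func:`make_tumor_phantom` emulates the multiplicative inhomogeneity
  model I = b*J + n inside a rectangular ROI: a two-level piecewise
  constant true image J (liver parenchyma plus a low-contrast lesion)
  distorted by a smooth, strictly positive bias field b, plus additive
  zero-mean Gaussian noise.  The true bias is returned for recovery tests.

Phantoms are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, Image2D

__all__ = [
    "Blob",
    "AdjacentOrgan",
    "PhantomSpec",
    "TumorPhantomSpec",
    "make_liver_phantom",
    "leakage_phantom_spec",
    "make_tumor_phantom",
]


@dataclass(frozen=True)
class Blob:
    """A disc/ellipse: center (row, col), radii (r_row, r_col), intensity."""

    center: tuple[float, float]
    radius: tuple[float, float] | float
    intensity: float

    def radii(self) -> tuple[float, float]:
        r = self.radius
        return (float(r), float(r)) if np.isscalar(r) else (float(r[0]), float(r[1]))


@dataclass(frozen=True)
class AdjacentOrgan:
    """A neighboring organ blob plus the fraction of its interface with the
    liver over which the edge is absent (bridged at liver intensity)."""

    blob: Blob
    edge_gap_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.edge_gap_fraction <= 1.0:
            raise ValueError("edge_gap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the liver phantom.

    Defaults: a 128x128 slice, liver at 0.8 on a 0.2 background, noise
    sigma 0.02 — a high-contrast parenchyma/background pair with mild
    additive noise, the regime a pre-windowed portal-phase CT slice
    presents after [0,1] normalization.
    """

    shape: tuple[int, int] = (256, 256)
    liver_intensity: float = 0.8
    background_intensity: float = 0.2
    components: tuple[Blob, ...] = (Blob((128, 116), (92, 78), 0.8),)
    vessels: tuple[Blob, ...] = ()
    adjacent_organ: AdjacentOrgan | None = None
    #: additional structures outside the liver (other organs, bright
    #: vessels); rendered before noise, never part of the ground truth
    extra_structures: tuple[Blob, ...] = ()
    edge_blur_sigma: float = 0.8   # partial-volume blur of structure edges (px)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for v in (self.liver_intensity, self.background_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1]")
        if len(self.components) < 1:
            raise ValueError("at least one liver component is required")
        for b in self.components + self.vessels:
            if min(b.radii()) < 2:
                raise ValueError("blob radii must be >= 2 px")


@dataclass(frozen=True)
class TumorPhantomSpec:
    """Study conditions for the tumor-ROI phantom.

    Defaults: a 64x64 ROI, parenchyma at 0.6, a hypodense lesion of
    contrast 0.1 (clinically typical low-contrast CT metastasis after
    normalization), a linear bias field of amplitude 0.3 and noise sigma
    0.02 — the low-contrast inhomogeneous regime the tumor branch exists
    for.
    """

    shape: tuple[int, int] = (80, 80)
    liver_intensity: float = 0.6
    tumor_center: tuple[float, float] = (40, 40)
    tumor_radius: tuple[float, float] | float = (21, 18)
    contrast: float = 0.1          # lesion intensity offset; >0 means hypodense
    hypodense: bool = True
    #: optional ambiguous-margin arc: over this azimuthal span (degrees,
    #: centered on fade_arc_center_deg) the lesion contrast ramps to zero
    #: at the boundary across the outer fade_depth_px of the radius — an
    #: edge that genuinely vanishes, as complex lesions show.
    fade_arc_deg: float = 0.0
    fade_arc_center_deg: float = 0.0
    fade_depth_px: float = 6.0
    bias_type: str = "linear"      # "linear" | "quadratic"
    bias_amplitude: float = 0.3
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < abs(self.contrast) <= 0.3:
            raise ValueError("contrast must satisfy 0 < |contrast| <= 0.3")
        if self.bias_type not in ("linear", "quadratic"):
            raise ValueError("bias_type must be 'linear' or 'quadratic'")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")


def leakage_phantom_spec(seed: int = 3) -> PhantomSpec:
    """The level-set comparison phantom: a liver with a partially absent
    boundary toward a darker adjacent organ (a graded corridor carrying no
    edge) and a large mid-bright structure behind a weaker true edge.

    A region-driven balloon follows the bright structure regardless of its
    edge; an edge-driven balloon under a large force crosses the weaker
    boundaries given enough iterations; the combined force resists both.
    """
    return PhantomSpec(
        components=(Blob((120, 96), (76, 60), 0.8),),
        adjacent_organ=AdjacentOrgan(Blob((120, 200), (30, 22), 0.45), edge_gap_fraction=0.5),
        extra_structures=(Blob((224, 110), (30, 85), 0.65),),
        noise_sigma=0.02,
        seed=seed,
    )


def _ellipse_mask(shape: tuple[int, int], blob: Blob) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = blob.center
    ar, ac = blob.radii()
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def make_liver_phantom(spec: PhantomSpec) -> tuple[Image2D, BinaryMask]:
    """Render the phantom and its ground-truth liver envelope.

    Raises if liver components overlap each other (they must be discrete
    parts) — internal vessels/tumors, by contrast, are meant to overlap the
    liver and are painted inside it.
    """
    shape = spec.shape
    img = np.full(shape, spec.background_intensity, dtype=float)
    truth = np.zeros(shape, dtype=bool)
    for blob in spec.components:
        m = _ellipse_mask(shape, blob)
        if (truth & m).any():
            raise ValueError("liver components must not overlap")
        truth |= m
        img[m] = blob.intensity
    for vessel in spec.vessels:
        m = _ellipse_mask(shape, vessel)
        img[m] = vessel.intensity  # carved out of the image, not of the truth

    if spec.adjacent_organ is not None:
        organ = spec.adjacent_organ
        m = _ellipse_mask(shape, organ.blob)
        if (truth & m).any():
            raise ValueError("adjacent organ must not overlap the liver")
        img[m] = organ.blob.intensity
        if organ.edge_gap_fraction > 0:
            img = _bridge_edge(
                img, truth, m, spec.liver_intensity, organ.blob.intensity,
                organ.edge_gap_fraction,
            )
    for blob in spec.extra_structures:
        m = _ellipse_mask(shape, blob)
        img[m & ~truth] = blob.intensity

    if spec.edge_blur_sigma > 0:
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, spec.edge_blur_sigma, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return Image2D(img), BinaryMask(truth.astype(np.uint8))


def _bridge_edge(
    img: np.ndarray,
    liver: np.ndarray,
    organ: np.ndarray,
    liver_intensity: float,
    organ_intensity: float,
    gap_fraction: float,
) -> np.ndarray:
    """Erase a fraction of the liver/organ interface: within the gap
    window the connecting band carries a smooth intensity ramp from liver
    to organ level, so no gradient marks the boundary there."""
    from scipy import ndimage

    # the inter-structure band: pixels near both shapes but in neither
    d_liver = ndimage.distance_transform_edt(~liver)
    d_organ = ndimage.distance_transform_edt(~organ)
    band = (~liver) & (~organ) & (d_liver + d_organ <= d_liver[organ].min() + 1.5)
    if not band.any():
        return img
    rows = np.flatnonzero(band.any(axis=1))
    extent = rows.max() - rows.min() + 1
    half = max(1, int(round(0.5 * gap_fraction * extent)))
    mid = (rows.min() + rows.max()) // 2
    window = np.zeros_like(band)
    window[mid - half : mid + half + 1, :] = True
    sel = band & window
    img = img.copy()
    frac = d_liver[sel] / np.maximum(d_liver[sel] + d_organ[sel], 1e-9)
    img[sel] = liver_intensity + frac * (organ_intensity - liver_intensity)
    return img


def make_tumor_phantom(spec: TumorPhantomSpec) -> tuple[Image2D, BinaryMask, Image2D]:
    """Render I = b*J + n; return (image, lesion truth, true bias field)."""
    shape = spec.shape
    delta = abs(spec.contrast) * (-1 if spec.hypodense else 1)
    tumor = _ellipse_mask(shape, Blob(spec.tumor_center, spec.tumor_radius, 0.0))
    J = np.full(shape, spec.liver_intensity, dtype=float)
    if spec.fade_arc_deg > 0:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        r0, c0 = spec.tumor_center
        ar, ac = Blob(spec.tumor_center, spec.tumor_radius, 0.0).radii()
        rho = np.sqrt(((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2)
        theta = np.degrees(np.arctan2(rr - r0, cc - c0))
        dtheta = np.abs((theta - spec.fade_arc_center_deg + 180.0) % 360.0 - 180.0)
        # smooth azimuthal window: 1 inside the arc, 0 outside, 15 deg roll-off
        arc = np.clip((spec.fade_arc_deg / 2.0 + 15.0 - dtheta) / 15.0, 0.0, 1.0)
        depth_frac = spec.fade_depth_px / max(min(ar, ac), 1.0)
        radial = np.clip((1.0 - rho) / max(depth_frac, 1e-6), 0.0, 1.0)
        multiplier = 1.0 - arc * (1.0 - radial)
        J[tumor] = spec.liver_intensity + delta * multiplier[tumor]
    else:
        J[tumor] = spec.liver_intensity + delta

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = (cc - (shape[1] - 1) / 2) / max(shape[1] - 1, 1)   # in [-1/2, 1/2]
    v = (rr - (shape[0] - 1) / 2) / max(shape[0] - 1, 1)
    if spec.bias_type == "linear":
        profile = u + 0.5 * v
        profile = profile / max(abs(profile).max(), 1e-12)
    else:
        profile = u**2 + v**2
        profile = 2.0 * profile / max(profile.max(), 1e-12) - 1.0
    bias = 1.0 + 0.5 * spec.bias_amplitude * profile
    if (bias <= 0).any():
        raise ValueError("bias field must be strictly positive")

    rng = np.random.default_rng(spec.seed)
    img = bias * J
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return Image2D(img), BinaryMask(tumor.astype(np.uint8)), Image2D(bias)
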