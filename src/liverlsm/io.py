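"""Image/mask containers, file IO, and run configuration.

All pipeline stages operate on :class:`Image2D` (a float pixel grid with
physical spacing in mm/pixel) and :class:`BinaryMask` ({0,1} grids aligned
to an image).  Intensities are normalized to [0, 1] at load time; every
threshold in the pipeline (binarization divisor, region-growing tolerance)
is expressed on that scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Image2D",
    "BinaryMask",
    "RoiRect",
    "RunConfig",
    "normalize_intensities",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels
        Float array of shape (rows, cols); finite values only.
    spacing
        (row_mm, col_mm) physical size of one pixel, strictly positive.
    intensity_range
        Nominal intensity range after normalization, default (0, 1).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError("image must be 2D with at least 3 rows and 3 cols")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if len(self.spacing) != 2 or self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("spacing must be two strictly positive values")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        return Image2D(pixels, self.spacing, self.intensity_range)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} grid aligned to an :class:`Image2D`."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "values", v.astype(np.uint8))
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass(frozen=True)
class RoiRect:
    """Half-open pixel rectangle [row0, row1) x [col0, col1), 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError("rectangle must be non-degenerate with non-negative origin")
        if self.area < 9:
            raise ValueError("rectangle area must be at least 9 pixels")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"rectangle {self} exceeds image shape {shape}")

    def contains(self, other: "RoiRect") -> bool:
        return (
            self.row0 <= other.row0
            and self.col0 <= other.col0
            and other.row1 <= self.row1
            and other.col1 <= self.col1
        )


@dataclass
class RunConfig:
    """All tunable parameters of the liver and tumor pipelines.

    Defaults are the trained operating point: the preprocessing sigmoid
    (gamma=0.5, kappa=-1.5, beta=4) with a binarization divisor theta in
    [1.1, 1.5]; unified level-set weights mu=0.04, lambda=5 with a balloon
    force alpha=10 over 100 iterations for the liver; kernel parameters
    a=1, tau=4, rho=3 with nu=1, delta_reg=1 for the local-intensity
    clustering stage; 15 MAP / 15 EM iterations for the HMRF refinement;
    and balloon force vartheta=3 over 200 iterations for the tumor.
    """

    # preprocessing
    diffusion_iterations: int = 10
    diffusion_conductance: float = 0.1
    diffusion_time_step: float = 0.125
    gamma: float = 0.5          # Gaussian std (px) for edge-scale gradient
    kappa: float = -1.5         # sigmoid width (negative: high gradient -> dark)
    beta: float = 4.0           # sigmoid center
    theta: float = 1.25         # binarization divisor, operating range [1.1, 1.5]
    # region growing
    W: float = 0.5              # gray-level homogeneity tolerance on [0,1] images
    # liver level set
    mu: float = 0.04            # distance-regularization weight
    lam: float = 5.0            # length (curvature) weight
    alpha: float = 10.0         # balloon-force magnitude (liver)
    liver_iterations: int = 100
    omega: float = 4.0          # binary-step init height (>= 2)
    sigma: float = 1.0          # Gaussian std for the edge indicator
    dt: float = 5.0             # level-set time step
    epsilon: float = 1.5        # Dirac/Heaviside width (px)
    # tumor branch
    nu: float = 1.0             # LIC length weight
    delta_reg: float = 1.0      # LIC distance-regularization weight
    lic_iterations: int = 100
    a: float = 1.0              # kernel normalization constant
    tau: float = 4.0            # kernel Gaussian std
    rho: int = 3                # kernel truncation radius (px)
    map_iterations: int = 15
    em_iterations: int = 15
    potts_beta: float = 0.5     # HMRF pairwise clique weight
    vartheta: float = 3.0       # balloon-force magnitude (tumor)
    tumor_iterations: int = 200
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 1:
            raise ValueError("theta must be > 1")
        if self.omega < 2:
            raise ValueError("omega must be >= 2")
        for name in ("diffusion_iterations", "liver_iterations", "lic_iterations",
                     "map_iterations", "em_iterations", "tumor_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu * self.dt >= 0.25:
            raise ValueError("stability requires mu * dt < 0.25")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat YAML/JSON mapping of config keys; kwargs override."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def normalize_intensities(pixels: np.ndarray) -> np.ndarray:
    """Linearly rescale to [0, 1] by the array's own min/max.

    Constant arrays map to all zeros.  Idempotent: applying twice equals
    applying once.
    """
    px = np.asarray(pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def read_image(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    slice_index: int | None = None,
) -> Image2D:
    """Read a PNG/TIFF slice or one slice of a NIfTI volume as an Image2D.

    Intensities are rescaled to [0, 1] by the image's own min/max.  Spacing
    comes from the NIfTI header when present, else from ``spacing_override``,
    else defaults to (1, 1) mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    spacing = None
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("a slice index is required for a 3D NIfTI file")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
        zooms = img.header.get_zooms()[:2]
        if all(z > 0 for z in zooms):
            spacing = (float(zooms[0]), float(zooms[1]))
        pixels = np.asarray(data, dtype=float)
    else:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(path), dtype=float)
        if pixels.ndim == 3:  # collapse RGB(A) to luminance
            pixels = pixels[..., :3].mean(axis=-1)
    if spacing is None:
        spacing = tuple(spacing_override) if spacing_override is not None else (1.0, 1.0)
    return Image2D(normalize_intensities(pixels), spacing)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an Image2D as 8-bit PNG/TIFF (intensities scaled by 255)."""
    import imageio.v3 as iio

    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit image with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.values * 255).astype(np.uint8))


def read_mask(path: str | Path, spacing: Sequence[float] = (1.0, 1.0)) -> BinaryMask:
    """Read a mask image; any strictly positive pixel becomes foreground."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return BinaryMask((arr > 0).astype(np.uint8), tuple(spacing))
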