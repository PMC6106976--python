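"""End-to-end liver segmentation: preprocess -> region growing -> refinement."""

from __future__ import annotations

from typing import Sequence

from .io import BinaryMask, Image2D, RunConfig
from .levelset import LSMParams, refine_liver
from .preprocess import PreprocessParams, preprocess_pipeline
from .region_grow import SeedSet, region_grow

__all__ = ["segment_liver"]


def segment_liver(
    image: Image2D,
    seeds: SeedSet | Sequence[tuple[int, int]],
    config: RunConfig | None = None,
    variant: str = "unified",
) -> BinaryMask:
    """Segment the liver from a normalized CT slice.

    The slice is converted to a binary image by the hybrid preprocessing
    chain; seeded region growing on that binary image extracts the rough
    liver region (one seed per internally-connected white part); the
    unified level-set flow then refines the rough mask onto the true
    boundary and interior holes are filled.
    """
    cfg = config or RunConfig()
    pre = PreprocessParams(
        diffusion_iterations=cfg.diffusion_iterations,
        diffusion_conductance=cfg.diffusion_conductance,
        diffusion_time_step=cfg.diffusion_time_step,
        gamma=cfg.gamma, kappa=cfg.kappa, beta=cfg.beta, theta=cfg.theta,
    )
    binary = preprocess_pipeline(image, pre)
    rough = region_grow(Image2D(binary.values.astype(float), image.spacing), seeds, cfg.W)
    lsm = LSMParams(
        mu=cfg.mu, lam=cfg.lam, alpha=cfg.alpha, iterations=cfg.liver_iterations,
        dt=cfg.dt, epsilon=cfg.epsilon, sigma=cfg.sigma, variant=variant,
    )
    return refine_liver(rough, image, lsm, cfg.omega)
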