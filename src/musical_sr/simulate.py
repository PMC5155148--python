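"""Synthetic blinking-emitter image stacks with known ground truth.

Emitters switch independently between a bright and a dark state; a frame
records, for each pixel, background plus the sum of the PSFs of the emitters
that were bright in that frame, optionally with Poisson shot noise.  The
geometry builders (pair / rings / fork) reproduce the standard test scenes
of fluctuation-based super-resolution: two points at a controlled
separation, nested rings, and a filament that forks into a "Y".

The blinking model is i.i.d. Bernoulli(p_on) per emitter per frame — the
minimal model with statistically independent intermittency — with an
optional two-state Markov chain (k_on, k_off switching probabilities) for
more realistic correlated dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ImageStack
from .psf import PSFModel, evaluate_psf

__all__ = [
    "Emitter",
    "SyntheticScene",
    "SimulatedStack",
    "make_pair_scene",
    "make_ring_scene",
    "make_fork_scene",
    "simulate_stack",
    "expected_frame",
    "emitter_image",
    "scene_sbr",
    "calibrate_brightness",
]


@dataclass(frozen=True)
class Emitter:
    """A point emitter: continuous (y, x) position in pixel units."""

    position: tuple[float, float]
    brightness: float  # expected photons per bright frame (peak-pixel scale)
    p_on: float  # probability of being bright in any given frame

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if not 0 < self.p_on <= 1:
            raise ValueError("p_on must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticScene:
    emitters: tuple[Emitter, ...]
    image_shape: tuple[int, int]
    background: float  # expected photons per pixel per frame
    psf: PSFModel

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be non-negative")
        H, W = self.image_shape
        for e in self.emitters:
            y, x = e.position
            if not (0 <= y <= H - 1 and 0 <= x <= W - 1):
                raise ValueError(f"emitter at {e.position} outside image bounds")


@dataclass(frozen=True)
class SimulatedStack:
    stack: ImageStack
    blink_matrix: np.ndarray  # (n_emitters, K) boolean
    seed: int


def _psf_samples(
    psf: PSFModel, position, shape, oversample: int = 1
) -> np.ndarray:
    """PSF of one emitter sampled on the pixel grid (peak-normalized scale).

    ``oversample=1`` samples at pixel centers; an odd ``oversample`` > 1
    averages the PSF over an oversample x oversample sub-grid per pixel
    (area integration).
    """
    if oversample < 1 or oversample % 2 == 0:
        raise ValueError("oversample must be odd and >= 1")
    H, W = shape
    y0, x0 = position
    if oversample == 1:
        yy, xx = np.mgrid[0:H, 0:W]
        r = np.hypot(yy - y0, xx - x0) * psf.pixel_size
        return evaluate_psf(psf, r)
    sub = (np.arange(oversample) - (oversample - 1) / 2) / oversample
    acc = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    for dy in sub:
        for dx in sub:
            r = np.hypot(yy + dy - y0, xx + dx - x0) * psf.pixel_size
            acc += evaluate_psf(psf, r)
    return acc / oversample**2


def emitter_image(
    scene: SyntheticScene, emitter: Emitter, oversample: int = 1
) -> np.ndarray:
    """Expected image of one bright emitter alone, excluding background."""
    return emitter.brightness * _psf_samples(
        scene.psf, emitter.position, scene.image_shape, oversample
    )


def expected_frame(
    scene: SyntheticScene, bright: np.ndarray | None = None, oversample: int = 1
) -> np.ndarray:
    """Noise-free pixel expectation for one frame.

    ``bright`` is a boolean mask over emitters (default: all bright).
    """
    H, W = scene.image_shape
    image = np.full((H, W), float(scene.background))
    if bright is None:
        bright = np.ones(len(scene.emitters), dtype=bool)
    for emitter, b in zip(scene.emitters, bright):
        if b:
            image += emitter_image(scene, emitter, oversample)
    return image


def make_pair_scene(
    separation: float,
    psf: PSFModel,
    image_shape: tuple[int, int] = (15, 15),
    brightness: float = 100.0,
    p_on: float = 0.2,
    background: float = 10.0,
) -> SyntheticScene:
    """Two identical emitters separated horizontally, centred in the image.

    ``separation`` is in nm; it is converted to pixel units with the PSF's
    pixel size.  The midpoint of the pair is the image center.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    sep_px = separation / psf.pixel_size
    H, W = image_shape
    if sep_px >= min(H, W):
        raise ValueError("separation exceeds the field of view")
    cy = (H - 1) / 2.0
    cx = (W - 1) / 2.0
    emitters = (
        Emitter((cy, cx - sep_px / 2.0), brightness, p_on),
        Emitter((cy, cx + sep_px / 2.0), brightness, p_on),
    )
    return SyntheticScene(emitters, image_shape, background, psf)


def make_ring_scene(
    ring_centers,
    ring_radius: float,
    emitters_per_ring: int,
    psf: PSFModel,
    image_shape: tuple[int, int] = (32, 32),
    brightness: float = 100.0,
    p_on: float = 0.2,
    background: float = 10.0,
) -> SyntheticScene:
    """Emitters equally spaced in angle on one or more circles.

    ``ring_centers`` are (y, x) in pixel units; ``ring_radius`` is in nm.
    """
    radius_px = ring_radius / psf.pixel_size
    H, W = image_shape
    emitters = []
    for cy, cx in ring_centers:
        if (
            cy - radius_px < 0
            or cx - radius_px < 0
            or cy + radius_px > H - 1
            or cx + radius_px > W - 1
        ):
            raise ValueError("ring overlaps the image boundary")
        angles = 2.0 * np.pi * np.arange(emitters_per_ring) / emitters_per_ring
        for a in angles:
            emitters.append(
                Emitter(
                    (cy + radius_px * np.sin(a), cx + radius_px * np.cos(a)),
                    brightness,
                    p_on,
                )
            )
    return SyntheticScene(tuple(emitters), image_shape, background, psf)


def make_fork_scene(
    arm_angle: float,
    arm_length: float,
    emitter_spacing: float,
    psf: PSFModel,
    stem_length: float = 500.0,
    image_shape: tuple[int, int] = (32, 32),
    brightness: float = 100.0,
    p_on: float = 0.2,
    background: float = 10.0,
) -> SyntheticScene:
    """A filament that splits into two arms (a "Y" / fork).

    The stem runs upward (decreasing y) from below the image center and
    carries emitters every ``emitter_spacing`` nm, both endpoints included;
    each arm leaves the junction at ``+-arm_angle/2`` radians from the stem
    direction with emitters at spacing intervals, junction excluded.  Total
    emitter count is floor(stem/spacing)+1 + 2*floor(arm/spacing).
    """
    if arm_length <= 0 or emitter_spacing <= 0 or stem_length <= 0:
        raise ValueError("lengths and spacing must be positive")
    px = psf.pixel_size
    H, W = image_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    stem_px = stem_length / px
    base = np.array([cy + stem_px / 2.0, cx])
    stem_dir = np.array([-1.0, 0.0])
    junction = base + stem_px * stem_dir
    positions = []
    n_stem = int(np.floor(stem_length / emitter_spacing))
    for i in range(n_stem + 1):
        positions.append(base + (i * emitter_spacing / px) * stem_dir)
    n_arm = int(np.floor(arm_length / emitter_spacing))
    for sign in (+1.0, -1.0):
        theta = sign * arm_angle / 2.0
        c, s = np.cos(theta), np.sin(theta)
        direction = np.array(
            [c * stem_dir[0] - s * stem_dir[1], s * stem_dir[0] + c * stem_dir[1]]
        )
        for i in range(1, n_arm + 1):
            positions.append(junction + (i * emitter_spacing / px) * direction)
    emitters = tuple(Emitter((p[0], p[1]), brightness, p_on) for p in positions)
    return SyntheticScene(emitters, image_shape, background, psf)


def _blink_matrix(
    n_emitters: int,
    n_frames: int,
    p_on,
    rng: np.random.Generator,
    blinking: str = "bernoulli",
    k_on: float | None = None,
    k_off: float | None = None,
) -> np.ndarray:
    """Draw the (emitters x frames) bright-state matrix, emitter-major."""
    p = np.broadcast_to(np.asarray(p_on, dtype=float), (n_emitters,))
    if blinking == "bernoulli":
        return rng.random((n_emitters, n_frames)) < p[:, None]
    if blinking == "markov":
        if k_on is None or k_off is None:
            raise ValueError("markov blinking requires k_on and k_off")
        out = np.empty((n_emitters, n_frames), dtype=bool)
        for j in range(n_emitters):
            state = rng.random() < p[j]
            for k in range(n_frames):
                out[j, k] = state
                state = (rng.random() < k_on) if not state else not (
                    rng.random() < k_off
                )
        return out
    raise ValueError(f"unknown blinking model: {blinking!r}")


def simulate_stack(
    scene: SyntheticScene,
    n_frames: int,
    noise: str = "poisson",
    seed: int = 0,
    *,
    blinking: str = "bernoulli",
    k_on: float | None = None,
    k_off: float | None = None,
    oversample: int = 1,
    read_noise_sd: float = 0.0,
) -> SimulatedStack:
    """Render K frames of the scene.

    Per frame, each emitter is bright with probability ``p_on``
    independently (recorded in the blink matrix); the noise-free pixel
    expectation is background plus the sum of bright-emitter PSFs;
    ``noise="poisson"`` draws every pixel from a Poisson law with that mean.
    Identical (scene, n_frames, noise, seed) arguments reproduce the stack
    bit-exactly: blinking is drawn first (emitter-major), then pixel noise
    frame by frame, from a single seeded generator.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model: {noise!r}")
    rng = np.random.default_rng(seed)
    n_emitters = len(scene.emitters)
    p_on = np.array([e.p_on for e in scene.emitters]) if n_emitters else np.empty(0)
    blinks = _blink_matrix(n_emitters, n_frames, p_on, rng, blinking, k_on, k_off)
    H, W = scene.image_shape
    images = np.array(
        [emitter_image(scene, e, oversample) for e in scene.emitters]
    ).reshape(n_emitters, H, W)
    frames = np.empty((n_frames, H, W))
    for k in range(n_frames):
        mean = scene.background + np.tensordot(
            blinks[:, k].astype(float), images, axes=(0, 0)
        ) if n_emitters else np.full((H, W), float(scene.background))
        if noise == "poisson":
            frame = rng.poisson(mean).astype(float)
        else:
            frame = mean
        if read_noise_sd > 0:
            frame = np.clip(frame + rng.normal(0.0, read_noise_sd, (H, W)), 0, None)
        frames[k] = frame
    stack = ImageStack(frames, scene.psf.pixel_size)
    return SimulatedStack(stack, blinks, seed)


def scene_sbr(scene: SyntheticScene, oversample: int = 1) -> float:
    """Signal-to-background ratio of the scene.

    Declared convention: the peak expected pixel signal of an isolated
    bright emitter (the scene's brightest one) divided by the mean
    background level.
    """
    if scene.background <= 0:
        raise ValueError("SBR undefined for zero background")
    if not scene.emitters:
        raise ValueError("SBR undefined for an empty scene")
    peak = max(
        float(emitter_image(scene, e, oversample).max()) for e in scene.emitters
    )
    return peak / scene.background


def calibrate_brightness(scene: SyntheticScene, target_sbr: float) -> SyntheticScene:
    """Rescale every emitter's brightness so that scene_sbr == target_sbr."""
    if target_sbr <= 0:
        raise ValueError("target SBR must be positive")
    factor = target_sbr / scene_sbr(scene)
    emitters = tuple(
        replace(e, brightness=e.brightness * factor) for e in scene.emitters
    )
    return replace(scene, emitters=emitters)
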