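"""Sliding-window subspace (MUSIC-type) super-resolution reconstruction.

The algorithm operates on a stack of K frames of the same field of view in
which point emitters blink independently.  For each small "soft" window of
N = N_w x N_w pixels it builds the N x K data matrix (pixels x frames),
computes its eigenimages by singular value decomposition, and splits them at
a threshold sigma_0 into a signal subspace (large singular values; the
statistically prominent patterns) and a null subspace (the rest, dominated
by noise).  For every test point on a subpixel grid the PSF steering vector
is projected onto both subspaces, giving distances d_PR (to the range) and
d_PN (to the null space); the per-window indicator

    f(r) = (d_PR / d_PN) ** alpha

is large exactly where a hypothetical emitter's PSF is consistent with the
prominent patterns and orthogonal to the noise patterns.  Because d_PR in
the numerator down-weights windows that carry no signal at a test point,
sliding windows are stitched simply by summing their indicators at each
test point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psf import PSFModel, evaluate_psf, sample_psf_vector

__all__ = [
    "ImageStack",
    "SoftWindow",
    "WindowDecomposition",
    "ProjectionPair",
    "IndicatorMap",
    "make_soft_window",
    "extract_window_matrix",
    "compute_eigenimages",
    "split_subspaces",
    "project_psf",
    "indicator",
    "run_musical",
    "threshold_map",
    "DPN_FLOOR",
]

#: Floor applied to d_PN before division (steering vectors are unit norm).
DPN_FLOOR = 1e-12


@dataclass(frozen=True)
class ImageStack:
    """K frames of H x W non-negative pixel intensities plus pixel size (nm)."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValueError("stack must be a K x H x W array with K >= 1")
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite values")
        if np.any(data < 0):
            raise ValueError("stack contains negative intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class SoftWindow:
    """An N_w x N_w window: ordered pixel list plus per-pixel taper weights."""

    center_pixel: tuple[int, int]
    side: int
    pixel_list: np.ndarray  # (N, 2) int (y, x)
    weights: np.ndarray  # (N,) strictly positive

    def __post_init__(self) -> None:
        if self.side < 3 or self.side % 2 == 0:
            raise ValueError("window side must be odd and >= 3")
        if len(self.pixel_list) != self.side**2:
            raise ValueError("pixel_list must have side**2 entries")
        if np.any(np.asarray(self.weights) <= 0):
            raise ValueError("taper weights must be strictly positive")

    @property
    def n_pixels(self) -> int:
        return self.side**2


def make_soft_window(
    center_pixel: tuple[int, int], side: int = 7, taper: str = "uniform"
) -> SoftWindow:
    """Build a window centred on ``center_pixel`` in row-major pixel order.

    ``taper`` is ``"uniform"`` (all weights 1, the default) or ``"cosine"``
    (raised-cosine of the radial distance, positive everywhere inside the
    footprint).
    """
    half = (side - 1) // 2
    cy, cx = center_pixel
    ys, xs = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1]
    pixels = np.column_stack([ys.ravel(), xs.ravel()])
    if taper == "uniform":
        weights = np.ones(side**2)
    elif taper == "cosine":
        r = np.hypot(ys.ravel() - cy, xs.ravel() - cx)
        # strictly positive: cosine lobe over the circumscribed radius
        weights = 0.05 + 0.95 * np.cos(np.pi / 2.0 * r / (half * np.sqrt(2) + 0.5)) ** 2
    else:
        raise ValueError(f"unknown taper: {taper!r}")
    return SoftWindow((cy, cx), side, pixels, weights)


@dataclass
class WindowDecomposition:
    """Eigenimages (left singular vectors) of one window's data matrix.

    ``eigenimages`` holds a complete orthonormal basis of pixel space as
    columns: the thin-SVD left vectors first (singular values descending),
    padded with an orthonormal complement carrying sigma = 0 when K < N.
    """

    singular_values: np.ndarray  # (N,), descending, zero-padded
    eigenimages: np.ndarray  # (N, N) orthonormal columns
    frame_vectors: np.ndarray  # (min(N,K), K) thin right singular vectors
    sigma0: float | None = None
    signal_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    null_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_pixels(self) -> int:
        return self.eigenimages.shape[0]


@dataclass(frozen=True)
class ProjectionPair:
    """Norms of the steering vector's components in the two subspaces."""

    d_PR: float
    d_PN: float


@dataclass
class IndicatorMap:
    """Stitched super-resolved map on the s-times upsampled test-point grid."""

    grid: np.ndarray  # (H*s, W*s), non-negative
    pixel_size_out: float  # nm per output grid cell
    provenance: dict


def extract_window_matrix(
    stack: ImageStack, window: SoftWindow, frame_range: slice | None = None
) -> np.ndarray:
    """N x K matrix: column k = taper-weighted window pixels of frame k."""
    frames = stack.data if frame_range is None else stack.data[frame_range]
    if frames.shape[0] == 0:
        raise ValueError("empty frame range")
    ys = window.pixel_list[:, 0]
    xs = window.pixel_list[:, 1]
    H, W = stack.shape
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= H or xs.max() >= W:
        raise ValueError("window footprint extends outside the image")
    return frames[:, ys, xs].T * window.weights[:, None]


def compute_eigenimages(window_matrix: np.ndarray) -> WindowDecomposition:
    """SVD of the N x K window matrix; returns a pre-threshold decomposition.

    The rank is bounded by min(N, K); when K < N the left basis is completed
    to all of pixel space with zero singular values so that signal and null
    projections always satisfy d_PR**2 + d_PN**2 = 1.
    """
    G = np.asarray(window_matrix, dtype=float)
    if G.ndim != 2:
        raise ValueError("window matrix must be 2D")
    if not np.all(np.isfinite(G)):
        raise ValueError("window matrix contains non-finite values")
    N, K = G.shape
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    if K < N:
        # complete the orthonormal basis; extra directions carry sigma = 0
        full = np.linalg.qr(
            np.concatenate([U, np.eye(N)], axis=1)
        )[0][:, :N]
        full[:, :K] = U
        U = full
        s = np.concatenate([s, np.zeros(N - K)])
    return WindowDecomposition(singular_values=s, eigenimages=U, frame_vectors=Vt)


def _resolve_sigma0(rule, singular_values: np.ndarray) -> float:
    """Turn a sigma_0 rule into an absolute threshold for this window.

    Accepted forms: ``("abs", v)`` / ``"abs:v"`` for an absolute singular
    value, or ``("rel", tau)`` / ``"rel:tau"`` for tau * sigma_1 (the
    window's largest singular value).
    """
    if isinstance(rule, str):
        kind, _, value = rule.partition(":")
        rule = (kind, float(value))
    kind, value = rule
    if value < 0:
        raise ValueError("sigma0 rule value must be non-negative")
    if kind == "abs":
        return float(value)
    if kind == "rel":
        sigma1 = singular_values[0] if len(singular_values) else 0.0
        return float(value) * float(sigma1)
    raise ValueError(f"unknown sigma0 rule kind: {kind!r}")


def split_subspaces(
    decomposition: WindowDecomposition, sigma0_rule
) -> WindowDecomposition:
    """Assign eigenimages with sigma >= sigma_0 to signal, the rest to null."""
    sigma0 = _resolve_sigma0(sigma0_rule, decomposition.singular_values)
    idx = np.arange(len(decomposition.singular_values))
    signal = idx[decomposition.singular_values >= sigma0]
    decomposition.sigma0 = sigma0
    decomposition.signal_indices = signal
    decomposition.null_indices = idx[decomposition.singular_values < sigma0]
    return decomposition


def project_psf(
    decomposition: WindowDecomposition, steering: np.ndarray
) -> ProjectionPair:
    """Project a unit steering vector on the signal and null subspaces."""
    a = np.asarray(steering, dtype=float)
    if a.shape != (decomposition.n_pixels,):
        raise ValueError("steering vector length does not match the window")
    coeffs = decomposition.eigenimages.T @ a
    d_pr = float(np.linalg.norm(coeffs[decomposition.signal_indices]))
    d_pn = float(np.linalg.norm(coeffs[decomposition.null_indices]))
    return ProjectionPair(d_pr, d_pn)


def indicator(
    p: ProjectionPair,
    alpha: float = 4.0,
    *,
    traditional_music: bool = False,
    floor: float = DPN_FLOOR,
) -> float:
    """Per-test-point intensity: (d_PR / d_PN)**alpha with a division floor.

    ``traditional_music=True`` gives the classic MUSIC pseudospectrum
    1 / d_PN (numerator 1, alpha forced to 1).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    denom = max(p.d_PN, floor)
    if traditional_music:
        return 1.0 / denom
    return float((p.d_PR / denom) ** alpha)


def _steering_bank(
    psf: PSFModel, side: int, subpixel_factor: int, weights: np.ndarray
) -> np.ndarray:
    """Steering vectors for every test point in a window footprint.

    Test points sit at subpixel cell centers.  Because windows slide with
    integer stride over a regular pixel grid, the steering vector depends
    only on the test point's offset within the footprint; one (N, (side*s)^2)
    bank therefore serves every window.  Taper weights multiply the raw PSF
    samples before unit normalization, matching the weighting of the data.
    """
    half = (side - 1) // 2
    s = subpixel_factor
    # pixel centers relative to the window's top-left pixel
    py, px = np.mgrid[0:side, 0:side]
    py = py.ravel()[:, None]
    px = px.ravel()[:, None]
    # test-point positions relative to the same origin
    t = -0.5 + (np.arange(side * s) + 0.5) / s
    ty, tx = np.meshgrid(t, t, indexing="ij")
    ty = ty.ravel()[None, :]
    tx = tx.ravel()[None, :]
    dist_nm = np.hypot(py - ty, px - tx) * psf.pixel_size
    raw = evaluate_psf(psf, dist_nm) * weights[:, None]
    norms = np.linalg.norm(raw, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate steering vector in window footprint")
    return raw / norms


def run_musical(
    stack: ImageStack,
    psf: PSFModel,
    n_w: int = 7,
    alpha: float = 4.0,
    sigma0_rule="rel:0.02",
    subpixel_factor: int = 10,
    frame_range: slice | None = None,
    *,
    taper: str = "uniform",
    subtract_mean: bool = False,
    traditional_music: bool = False,
    min_null_fraction: float = 0.1,
) -> IndicatorMap:
    """Full reconstruction: decompose every window, project, stitch.

    Windows slide with stride 1 over every position where the full
    ``n_w x n_w`` footprint fits inside the image.  The output grid has
    ``subpixel_factor**2`` test points per camera pixel; each test point
    accumulates the sum of the indicators of all windows covering it.
    Windows that are identically zero, or whose null subspace is empty or
    near-empty under the sigma_0 rule, contribute nothing (the latter with
    a warning: orthogonality to only a few noise directions is satisfied on
    extended chance sets rather than at isolated points, so such windows
    carry no localization information).  ``min_null_fraction`` sets the
    smallest informative null subspace as a fraction of N (default 10%).
    """
    if n_w < 3 or n_w % 2 == 0:
        raise ValueError("window side must be odd and >= 3")
    if subpixel_factor < 1:
        raise ValueError("subpixel_factor must be >= 1")
    if abs(psf.pixel_size - stack.pixel_size) > 1e-9:
        raise ValueError("stack and PSF pixel sizes disagree")
    H, W = stack.shape
    if H < n_w or W < n_w:
        raise ValueError("stack smaller than the analysis window")
    frames = stack.data if frame_range is None else stack.data[frame_range]
    if frames.shape[0] == 0:
        raise ValueError("empty frame range")
    K = frames.shape[0]
    N = n_w * n_w
    if K < N:
        warnings.warn(
            f"K={K} frames < N={N} window pixels: rank is limited to K and "
            "the null space absorbs the deficit; K >= N is desirable",
            stacklevel=2,
        )
    half = (n_w - 1) // 2
    s = subpixel_factor
    window0 = make_soft_window((half, half), n_w, taper)
    bank = _steering_bank(psf, n_w, s, window0.weights)

    out = np.zeros((H * s, W * s))
    min_null = int(np.ceil(min_null_fraction * N)) if min_null_fraction > 0 else 0
    n_skipped = 0
    n_empty_null = 0
    for cy in range(half, H - half):
        for cx in range(half, W - half):
            win = frames[:, cy - half : cy + half + 1, cx - half : cx + half + 1]
            G = win.reshape(K, N).T * window0.weights[:, None]
            if subtract_mean:
                G = G - G.mean(axis=1, keepdims=True)
            if not G.any():
                n_skipped += 1
                continue
            decomp = split_subspaces(compute_eigenimages(G), sigma0_rule)
            if len(decomp.null_indices) < max(1, min_null):
                n_empty_null += 1
                continue
            U = decomp.eigenimages
            d_pr = np.linalg.norm(U[:, decomp.signal_indices].T @ bank, axis=0)
            d_pn = np.linalg.norm(U[:, decomp.null_indices].T @ bank, axis=0)
            d_pn = np.maximum(d_pn, DPN_FLOOR)
            if traditional_music:
                values = 1.0 / d_pn
            else:
                values = (d_pr / d_pn) ** alpha
            tile = values.reshape(n_w * s, n_w * s)
            y0 = (cy - half) * s
            x0 = (cx - half) * s
            out[y0 : y0 + n_w * s, x0 : x0 + n_w * s] += tile
    if n_empty_null:
        warnings.warn(
            f"{n_empty_null} window(s) had an empty or near-empty null "
            "subspace under the sigma0 rule and were skipped",
            stacklevel=2,
        )
    provenance = {
        "n_w": n_w,
        "alpha": alpha,
        "sigma0_rule": sigma0_rule if isinstance(sigma0_rule, str) else list(sigma0_rule),
        "subpixel_factor": s,
        "frame_range": [frame_range.start, frame_range.stop] if frame_range else None,
        "n_frames_used": K,
        "taper": taper,
        "subtract_mean": subtract_mean,
        "traditional_music": traditional_music,
        "min_null_fraction": min_null_fraction,
        "windows_skipped_zero": n_skipped,
        "windows_empty_null": n_empty_null,
        "pixel_size_in": stack.pixel_size,
    }
    return IndicatorMap(out, stack.pixel_size / s, provenance)


def threshold_map(
    map_: IndicatorMap, fraction: float = 0.4, percentile: float = 99.9
) -> IndicatorMap:
    """Zero out values below ``fraction`` times a high-percentile intensity.

    Used to suppress diffuse background (for example freely diffusing
    labelled monomers in live cells): with the defaults, values below 0.4
    times the 99.9th-percentile intensity are floored to 0.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    cut = fraction * np.percentile(map_.grid, percentile)
    grid = np.where(map_.grid < cut, 0.0, map_.grid)
    provenance = dict(map_.provenance)
    provenance["threshold"] = {"fraction": fraction, "percentile": percentile}
    return IndicatorMap(grid, map_.pixel_size_out, provenance)
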