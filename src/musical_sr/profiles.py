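"""Quantification of reconstructed maps: line profiles, FWHM, contrast,
periodicity, and nearest-maximum distances.

All positions are physical (nm); profiles are sampled from the upsampled
indicator map by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import IndicatorMap

__all__ = [
    "LineProfile",
    "FWHMResult",
    "sample_line_profile",
    "measure_fwhm",
    "average_aligned_profiles",
    "two_peak_contrast",
    "profile_periodogram",
    "closest_maxima_distance",
    "local_maxima_1d",
]


@dataclass(frozen=True)
class LineProfile:
    """Intensity samples at uniformly spaced positions (nm) along a line."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.size < 3 or pos.size != val.size:
            raise ValueError("profile needs >= 3 matched samples")
        steps = np.diff(pos)
        if np.ptp(steps) > 1e-9 * max(1.0, abs(steps[0])):
            raise ValueError("profile positions must be uniformly spaced")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class FWHMResult:
    fwhm: float  # nm
    peak_position: float  # nm
    peak_value: float


def sample_line_profile(
    map_: IndicatorMap, p_start, p_end, n_samples: int
) -> LineProfile:
    """Bilinear samples along the segment p_start -> p_end (grid indices).

    Endpoints are (row, col) positions on the output grid; returned
    positions are nm from ``p_start`` using the map's output pixel size.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    a = np.asarray(p_start, dtype=float)
    b = np.asarray(p_end, dtype=float)
    hi = np.array(map_.grid.shape) - 1
    for p in (a, b):
        if np.any(p < 0) or np.any(p > hi):
            raise ValueError(f"endpoint {tuple(p)} outside the map")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = a[:, None] + (b - a)[:, None] * t[None, :]
    values = map_coordinates(map_.grid, coords, order=1, mode="nearest")
    length_nm = float(np.linalg.norm(b - a)) * map_.pixel_size_out
    return LineProfile(t * length_nm, values)


def measure_fwhm(profile: LineProfile, baseline: float = 0.0) -> FWHMResult:
    """FWHM by linear interpolation of the half-max crossings.

    The global maximum must be interior.  ``baseline`` (same units as the
    profile values) is subtracted before halving; the default 0 measures
    raw half-maximum with no background correction.
    """
    v = profile.values - baseline
    i = int(np.argmax(v))
    if i == 0 or i == len(v) - 1:
        raise ValueError("profile maximum lies on the boundary")
    half = v[i] / 2.0
    pos = profile.positions

    def crossing(direction: int) -> float:
        # walk away from the peak; interpolate at the first drop below half
        j = i + direction
        while 0 <= j < len(v):
            if v[j] < half:
                inner = j - direction  # still >= half
                frac = (v[inner] - half) / (v[inner] - v[j])
                return float(pos[inner] + frac * (pos[j] - pos[inner]))
            j += direction
        raise ValueError("no half-maximum crossing on one side")

    left = crossing(-1)
    right = crossing(+1)
    return FWHMResult(
        fwhm=float(right - left),
        peak_position=float(profile.positions[i]),
        peak_value=float(profile.values[i]),
    )


def average_aligned_profiles(profiles: list[LineProfile]) -> LineProfile:
    """Align each profile's maximum at position 0, then average pointwise.

    Alignment is at integer-sample resolution; the mean is taken over the
    overlap common to all shifted profiles.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    spacing = profiles[0].spacing
    for p in profiles[1:]:
        if abs(p.spacing - spacing) > 1e-9 * spacing:
            raise ValueError("profiles must share a common sample spacing")
    peaks = [int(np.argmax(p.values)) for p in profiles]
    left = min(peaks)
    right = min(len(p.values) - 1 - i for p, i in zip(profiles, peaks))
    idx = np.arange(-left, right + 1)
    stackv = np.stack([p.values[i + idx] for p, i in zip(profiles, peaks)])
    return LineProfile(idx * spacing, stackv.mean(axis=0))


def local_maxima_1d(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (plateaus report their start)."""
    v = np.asarray(values, dtype=float)
    out = []
    n = len(v)
    j = 1
    while j < n - 1:
        if v[j] > v[j - 1]:
            k = j
            while k + 1 < n and v[k + 1] == v[j]:
                k += 1
            if k < n - 1 and v[k + 1] < v[j]:
                out.append(j)
            j = k + 1
        else:
            j += 1
    return np.array(out, dtype=int)


def two_peak_contrast(profile: LineProfile) -> tuple[float, bool]:
    """Michelson-type contrast of the two dominant peaks of a profile.

    contrast = (mean(peak1, peak2) - dip) / (mean(peak1, peak2) + dip)
    where the dip is the profile minimum between the two largest local
    maxima.  Returns ``(contrast, resolved)``; with fewer than two local
    maxima the structure is unresolved and ``(0.0, False)`` is returned.
    """
    peaks = local_maxima_1d(profile.values)
    if len(peaks) < 2:
        return 0.0, False
    order = peaks[np.argsort(profile.values[peaks])[::-1][:2]]
    i, j = sorted(order)
    p_mean = float(profile.values[[i, j]].mean())
    dip = float(profile.values[i : j + 1].min())
    if p_mean + dip == 0:
        return 0.0, False
    return (p_mean - dip) / (p_mean + dip), True


def profile_periodogram(profile: LineProfile):
    """Discrete Fourier power spectrum of the mean-removed profile.

    Returns ``(frequencies, power, dominant_period)``: frequencies in
    cycles per nm (rfft bins, no zero padding), and the period 1/f of the
    strongest nonzero-frequency component in nm.
    """
    v = profile.values
    if len(v) < 8:
        raise ValueError("periodogram needs >= 8 samples")
    centered = v - v.mean()
    power = np.abs(np.fft.rfft(centered)) ** 2
    freqs = np.fft.rfftfreq(len(v), d=profile.spacing)
    if np.all(power[1:] <= 1e-12 * max(1.0, power.max())):
        return freqs, power, np.inf
    k = 1 + int(np.argmax(power[1:]))
    return freqs, power, 1.0 / freqs[k]


def closest_maxima_distance(
    map_: IndicatorMap,
    line_points,
    direction,
    max_distance_nm: float | None = None,
    step_nm: float | None = None,
) -> np.ndarray:
    """Distance (nm) from each point to the nearest 1D local maximum along
    +-direction.

    For every (row, col) grid point, the map is sampled along the line
    through the point with the given unit direction; the returned value is
    the distance to the local maximum of that 1D profile closest to the
    point (0 if the point itself sits on a maximum), or NaN if none exists
    within ``max_distance_nm``.
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    step_px = (step_nm / map_.pixel_size_out) if step_nm else 0.5
    hi = np.array(map_.grid.shape) - 1
    if max_distance_nm is None:
        max_distance_nm = float(hi.min()) * map_.pixel_size_out / 2.0
    n_steps = int(max_distance_nm / (step_px * map_.pixel_size_out))
    t = np.arange(-n_steps, n_steps + 1) * step_px
    out = []
    for point in np.atleast_2d(np.asarray(line_points, dtype=float)):
        coords = point[:, None] + d[:, None] * t[None, :]
        inside = np.all((coords >= 0) & (coords <= hi[:, None]), axis=0)
        values = map_coordinates(map_.grid, coords[:, inside], order=1, mode="nearest")
        tt = t[inside]
        peaks = local_maxima_1d(values)
        if len(peaks) == 0:
            out.append(np.nan)
        else:
            out.append(float(np.min(np.abs(tt[peaks])) * map_.pixel_size_out))
    return np.array(out)
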