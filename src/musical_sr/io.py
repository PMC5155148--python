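"""Stack/map I/O (multi-page TIFF), run configuration and provenance."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import ImageStack, IndicatorMap

__all__ = ["RunConfig", "read_stack", "write_stack", "write_map", "load_config"]

_VERSION = "0.1.0"


@dataclasses.dataclass
class RunConfig:
    """Validated parameters of one reconstruction run."""

    input: str | None = None
    output: str | None = None
    pixel_size_nm: float = 65.0
    na: float = 1.49
    wavelength_nm: float = 593.0
    psf_model: str = "airy"
    window: int = 7
    alpha: float = 4.0
    sigma0: str = "rel:0.02"
    subpixel: int = 10
    frames: str | None = None  # "start:end"
    threshold: str | None = None  # "fraction:percentile"
    seed: int = 0
    log_level: str = "info"

    def validate(self) -> "RunConfig":
        errors = []
        for key in ("pixel_size_nm", "na", "wavelength_nm", "alpha"):
            if getattr(self, key) <= 0:
                errors.append(f"{key} must be positive")
        if self.window < 3 or self.window % 2 == 0:
            errors.append("window must be odd and >= 3")
        if self.subpixel < 1:
            errors.append("subpixel must be >= 1")
        if self.psf_model not in ("airy", "gaussian"):
            errors.append("psf_model must be 'airy' or 'gaussian'")
        kind = self.sigma0.partition(":")[0]
        if kind not in ("rel", "abs"):
            errors.append("sigma0 must look like rel:<tau> or abs:<value>")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return self

    @property
    def frame_slice(self) -> slice | None:
        if self.frames is None:
            return None
        start, _, stop = self.frames.partition(":")
        return slice(int(start) if start else None, int(stop) if stop else None)

    @property
    def threshold_pair(self) -> tuple[float, float] | None:
        if self.threshold is None:
            return None
        frac, _, pct = self.threshold.partition(":")
        return float(frac), float(pct)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides.

    Explicit keyword overrides (CLI flags) beat file values, which beat the
    documented defaults.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(loaded) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values).validate()


def read_stack(path: str | Path, pixel_size_nm: float) -> ImageStack:
    """Read a grayscale multi-page TIFF as an ImageStack (frames in file order).

    The pixel size always comes from the caller; TIFF resolution tags, when
    present and inconsistent, trigger a warning only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tags = tif.pages[0].tags
        if "XResolution" in tags and "ResolutionUnit" in tags:
            num, den = tags["XResolution"].value
            unit = tags["ResolutionUnit"].value
            # unit 3 = cm; pixels/cm -> nm/pixel
            if unit == 3 and num:
                tag_nm = 1e7 * den / num
                if abs(tag_nm - pixel_size_nm) > 0.01 * pixel_size_nm:
                    warnings.warn(
                        f"TIFF resolution tag implies {tag_nm:.1f} nm/pixel but "
                        f"{pixel_size_nm} nm was configured; using the "
                        "configured value",
                        stacklevel=2,
                    )
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {data.shape}: expected grayscale pages"
        )
    return ImageStack(data.astype(float), pixel_size_nm)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write frames as a float32 multi-page TIFF."""
    tifffile.imwrite(path, stack.data.astype(np.float32))


def write_map(
    map_: IndicatorMap,
    path: str | Path,
    log_scale: bool = False,
    config: RunConfig | None = None,
) -> None:
    """Write the indicator map as float32 TIFF with a JSON provenance sidecar.

    With ``log_scale`` a second file ``<stem>_log10.tif`` holding
    log10(1 + map) is written for display.
    """
    path = Path(path)
    if not np.all(np.isfinite(map_.grid)):
        raise ValueError("map contains non-finite values")
    tifffile.imwrite(path, map_.grid.astype(np.float32))
    if log_scale:
        log_path = path.with_name(path.stem + "_log10.tif")
        tifffile.imwrite(log_path, np.log10(1.0 + map_.grid).astype(np.float32))
    sidecar = {
        "software_version": _VERSION,
        "pixel_size_out_nm": map_.pixel_size_out,
        "provenance": _jsonable(map_.provenance),
    }
    if config is not None:
        sidecar["config"] = _jsonable(config.to_dict())
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
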