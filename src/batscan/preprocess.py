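"""Deterministic image conditioning before feature extraction.

Resampling to 1x1 mm in-plane (slice spacing preserved — a zero third
component in the target spacing means "keep"), a 19-image-type filter
bank, and fixed-bin-width gray-level discretization.

The display window (center 40, width 400 HU) is carried in the config for
provenance but never applied before extraction: it would clip the entire
adipose range (-190..-10 HU) to a constant and destroy every texture
feature.  Features are computed on raw HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pywt
from scipy import ndimage

from .grid import VolumeGrid

#: The filter bank: 19 image types (original + 18 filtered).  Together
#: with the per-class feature counts this reproduces the 1,743-feature
#: census: 19 x (18 first-order + 73 texture) + 14 shape.
WAVELET_SUBBANDS = tuple(
    "wavelet-" + "".join(b) for b in
    ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
)
LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
LOG_NAMES = tuple(f"log-sigma-{s:g}mm" for s in LOG_SIGMAS_MM)
FILTER_BANK = (
    ("original",)
    + WAVELET_SUBBANDS
    + LOG_NAMES
    + ("square", "squareroot", "logarithm", "exponential", "gradient")
)


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (0.0, 1.0, 1.0)  # (slice,row,col); 0 = keep
    interpolation_order: int = 3  # cubic B-spline
    window_center: float = 40.0
    window_width: float = 400.0
    filter_bank: tuple[str, ...] = FILTER_BANK
    bin_width: float = 25.0
    max_levels: int = 64
    wavelet: str = "coif1"

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(s < 0 for s in self.target_spacing):
            raise ValueError("target spacing components must be >= 0 (0 = keep)")
        unknown = set(self.filter_bank) - set(FILTER_BANK)
        if unknown:
            raise ValueError(f"unknown filter names: {sorted(unknown)}")
        if len(self.filter_bank) != 19:
            raise ValueError("filter bank must yield exactly 19 image types")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def resample(vol: VolumeGrid, config: PreprocessConfig, mask: np.ndarray | None = None):
    """Resample to the target spacing with B-spline interpolation.

    A zero component in ``target_spacing`` keeps that axis untouched.
    Masks are resampled nearest-neighbor and re-binarized.  Returns the
    resampled grid, or ``(grid, mask)`` when a mask is given.
    """
    config.validate()
    target = tuple(
        vol.spacing[i] if config.target_spacing[i] == 0 else config.target_spacing[i]
        for i in range(3)
    )
    factors = tuple(vol.spacing[i] / target[i] for i in range(3))
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        out, out_mask = vol.like(vol.values.copy()), mask
    else:
        values = ndimage.zoom(vol.values, factors, order=config.interpolation_order,
                              mode="nearest", grid_mode=True)
        out = VolumeGrid(values, target, vol.origin)
        out_mask = None
        if mask is not None:
            out_mask = ndimage.zoom(mask.astype(np.uint8), factors, order=0,
                                    mode="nearest", grid_mode=True) > 0
    if mask is None:
        return out
    return out, out_mask


def _swt_subbands(values: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """One-level undecimated (stationary) 3D wavelet transform.

    Axes are padded to even length (edge mode) and cropped back.  Sub-band
    names use L (approximation) / H (detail) per array axis.
    """
    pads = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    crop = tuple(slice(0, s) for s in values.shape)
    out = {}
    for key, arr in coeffs.items():
        name = "wavelet-" + "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[crop]
    return out


def _intensity_filter(name: str, v: np.ndarray) -> np.ndarray:
    """Pointwise intensity remaps, each rescaled back into the input range.

    With c = max|v| over the volume:
      square      : v^2 / c
      squareroot  : sign(v) * sqrt(c * |v|)
      logarithm   : sign(v) * c * log(|v| + 1) / log(c + 1)
      exponential : exp(v * log(c) / c)
    """
    c = float(np.max(np.abs(v)))
    if name == "square":
        return np.zeros_like(v) if c == 0 else v**2 / c
    if name == "squareroot":
        return np.sign(v) * np.sqrt(c * np.abs(v))
    if name == "logarithm":
        if c == 0:
            return np.zeros_like(v)
        return np.sign(v) * c * np.log1p(np.abs(v)) / np.log1p(c)
    if name == "exponential":
        if c == 0:
            return np.ones_like(v)
        return np.exp(v * np.log(c) / c)
    raise ValueError(name)


def apply_filter_bank(vol: VolumeGrid, config: PreprocessConfig | None = None) -> dict[str, VolumeGrid]:
    """All 19 image types for one (already resampled) volume.

    Deterministic: identical input gives bit-identical outputs.
    """
    config = config or PreprocessConfig()
    config.validate()
    v = vol.values
    out: dict[str, VolumeGrid] = {}
    wavelets = None
    for name in config.filter_bank:
        if name == "original":
            arr = v.copy()
        elif name.startswith("wavelet-"):
            if wavelets is None:
                wavelets = _swt_subbands(v, config.wavelet)
            arr = wavelets[name]
        elif name.startswith("log-sigma-"):
            sigma_mm = float(name[len("log-sigma-"):-2])
            sigma_vox = [sigma_mm / s for s in vol.spacing]
            # scale-normalized LoG; sign flipped so bright blobs score high
            arr = -(sigma_mm**2) * ndimage.gaussian_laplace(v, sigma=sigma_vox, mode="nearest")
        elif name == "gradient":
            axes = [ax for ax in range(3) if v.shape[ax] >= 2]
            grads = np.gradient(v, *[vol.spacing[ax] for ax in axes], axis=axes) if axes else []
            if len(axes) == 1:
                grads = [grads]
            arr = np.sqrt(sum(g**2 for g in grads)) if axes else np.zeros_like(v)
        else:
            arr = _intensity_filter(name, v)
        out[name] = vol.like(arr)
    return out


def effective_bin_width(values: np.ndarray, bin_width: float, max_levels: int | None) -> float:
    """Widen the bin width when needed to cap the number of gray levels.

    Fixed 25 HU bins are meaningful on calibrated CT but can explode the
    level count on nonlinearly filtered images; the cap keeps matrices
    tractable without changing the original-image discretization.
    """
    if max_levels is None:
        return bin_width
    rng = float(values.max() - values.min())
    return max(bin_width, rng / max_levels)


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray-level discretization inside a mask.

    level(v) = floor((v - min_in_mask) / bin_width) + 1, so levels run
    from 1 to floor(range / bin_width) + 1.  Voxels outside the mask are
    level 0.  Returns (level array, level count).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    inside = values[mask]
    levels = np.zeros(values.shape, dtype=np.int32)
    levels[mask] = np.floor((inside - inside.min()) / bin_width).astype(np.int32) + 1
    return levels, int(levels.max())
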