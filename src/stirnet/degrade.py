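"""Low-radiation-dose simulation.

Radiation dose in a cine CT study can be cut three ways, each with its own
image cost, and all three are simulated here:

* **low tube current** — dose scales linearly with tube current I (mAs) while
  image noise grows as the inverse square root; the added noise standard
  deviation follows

      sigma = K * sqrt(1/I - 1/I0)

  with I0 the reference (full-dose) current and K a scanner constant
  calibrated in phantom studies (K = 103.09 mA^1/2 for the protocol emulated
  here, I0 = 190 mAs).  The noise field is spatially correlated ("spectrum"
  Gaussian noise): white noise smoothed by a Gaussian kernel and rescaled so
  its empirical standard deviation hits the target sigma exactly.

* **low temporal sampling** — every scale-th frame is kept (frame interval
  multiplied by the scale), emulating longer gaps between exposures.

* **low spatial sampling** — grid-wise pixel skipping along X and Y,
  emulating fewer beams/receptors.

Down-sampled volumes are interpolated back to the original size with a
bicubic spline so restoration networks see full-size inputs.  Noise is added
to the full-dose volume first, in HU, before any down-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .volume import CTPVolume

__all__ = [
    "DoseParams",
    "SamplingSpec",
    "noise_sigma",
    "add_correlated_noise",
    "downsample_temporal",
    "downsample_spatial",
    "upsample_bicubic",
    "simulate_low_dose",
]

REFERENCE_CURRENT_MAS = 190.0
NOISE_CONSTANT_K = 103.09  # mA^(1/2), scanner calibration


@dataclass(frozen=True)
class DoseParams:
    """Tube-current noise parameters.

    I          : simulated tube current (mAs), 0 < I <= I0
    I0         : reference full-dose current (mAs)
    K          : noise calibration constant (mA^1/2)
    corr_sigma : Gaussian correlation width of the noise field (pixels)
    seed       : RNG seed for the noise realization
    """

    I: float = REFERENCE_CURRENT_MAS
    I0: float = REFERENCE_CURRENT_MAS
    K: float = NOISE_CONSTANT_K
    corr_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.I <= self.I0):
            raise InvalidInputError(f"require 0 < I <= I0, got I={self.I}, I0={self.I0}")
        if self.K <= 0:
            raise InvalidInputError("noise constant K must be > 0")
        if self.corr_sigma < 0:
            raise InvalidInputError("corr_sigma must be >= 0")


@dataclass(frozen=True)
class SamplingSpec:
    """Down-sampling factor and the axes it applies to.

    scale    : 1 (S1, none), 2 (S2, halved) or 3 (S3, thirded)
    axis_set : subset of {"x", "y", "t"}
    """

    scale: int = 1
    axis_set: frozenset[str] = frozenset({"x", "y", "t"})

    def __post_init__(self) -> None:
        if self.scale not in (1, 2, 3):
            raise InvalidInputError(f"sampling scale must be 1, 2 or 3, got {self.scale}")
        axes = frozenset(a.lower() for a in self.axis_set)
        if not axes <= {"x", "y", "t"}:
            raise InvalidInputError(f"axis_set must be a subset of x/y/t, got {self.axis_set}")
        object.__setattr__(self, "axis_set", axes)


def noise_sigma(params: DoseParams) -> float:
    """Added-noise standard deviation (HU) for the simulated tube current."""
    return params.K * np.sqrt(1.0 / params.I - 1.0 / params.I0)


def add_correlated_noise(vol: CTPVolume, params: DoseParams) -> CTPVolume:
    """Add spatially correlated Gaussian noise, frame by frame.

    Per frame: white Gaussian noise is smoothed with an isotropic Gaussian
    kernel of width ``corr_sigma``, mean-centred (noise carries no DC
    offset), and rescaled so its empirical standard deviation equals
    ``noise_sigma(params)`` exactly.  Frames get independent realizations
    (no temporal correlation).  Deterministic given the seed.
    """
    sigma = noise_sigma(params)
    if sigma == 0.0:
        return vol.copy()
    rng = np.random.default_rng(params.seed)
    data = vol.data.copy()
    for t in range(vol.nt):
        white = rng.standard_normal((vol.nx, vol.ny))
        if params.corr_sigma > 0:
            fld = ndimage.gaussian_filter(white, params.corr_sigma, mode="reflect")
        else:
            fld = white
        fld = fld - fld.mean()
        std = fld.std()
        if std == 0.0:  # degenerate single-pixel frame
            fld = np.zeros_like(fld)
        else:
            fld *= sigma / std
        data[:, :, t] += fld.astype(np.float32)
    return vol.with_data(data)


def downsample_temporal(vol: CTPVolume, scale: int) -> CTPVolume:
    """Keep frames 0, scale, 2*scale, ...; the frame interval grows by scale."""
    if scale not in (1, 2, 3):
        raise InvalidInputError(f"scale must be 1, 2 or 3, got {scale}")
    if scale == 1:
        return vol.copy()
    if vol.nt < scale:
        raise InvalidInputError(f"cannot keep any frame: nt={vol.nt} < scale={scale}")
    return vol.with_data(vol.data[:, :, ::scale], dt=vol.dt * scale)


def downsample_spatial(vol: CTPVolume, scale: int) -> CTPVolume:
    """Grid-wise pixel skipping: keep rows/columns 0, scale, 2*scale, ..."""
    if scale not in (1, 2, 3):
        raise InvalidInputError(f"scale must be 1, 2 or 3, got {scale}")
    if scale == 1:
        return vol.copy()
    return vol.with_data(vol.data[::scale, ::scale, :])


def _upsample_axis_coords(target_len: int, source_len: int) -> np.ndarray:
    """Target index -> source coordinate.

    Kept samples sit at original positions {0, s, 2s, ...} with retention
    stride s = ceil(target/source); recovering original index j therefore
    means evaluating the coarse signal at coordinate j / s."""
    if target_len == source_len:
        return np.arange(source_len, dtype=np.float64)
    stride = -(-target_len // source_len)  # ceil
    return np.arange(target_len, dtype=np.float64) / stride


def upsample_bicubic(vol: CTPVolume, target_shape: tuple[int, int, int],
                     dt: float | None = None) -> CTPVolume:
    """Bicubic (cubic-spline) interpolation back to ``target_shape``.

    Kept samples are treated as lying on the coarse grid {0, s, 2s, ...} of
    the original coordinate system; borders replicate the edge sample.
    Constant inputs map to constant outputs.
    """
    if len(target_shape) != 3:
        raise InvalidInputError("target_shape must be (nx, ny, nt)")
    if any(t < s for t, s in zip(target_shape, vol.shape)):
        raise InvalidInputError(
            f"target shape {target_shape} smaller than current {vol.shape}")
    if target_shape == vol.shape:
        return vol.copy()
    coords = np.meshgrid(
        *[_upsample_axis_coords(t, s) for t, s in zip(target_shape, vol.shape)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(coords), order=3, mode="nearest")
    new_dt = dt if dt is not None else vol.dt * vol.nt / target_shape[2]
    return vol.with_data(data, dt=new_dt)


def simulate_low_dose(vol: CTPVolume, dose: DoseParams,
                      sampling: SamplingSpec) -> CTPVolume:
    """Full degradation: correlated noise, then down-sampling along the
    requested axes, then bicubic re-interpolation to the original shape."""
    original_shape = vol.shape
    original_dt = vol.dt
    out = add_correlated_noise(vol, dose)
    if sampling.scale > 1:
        if "t" in sampling.axis_set:
            out = downsample_temporal(out, sampling.scale)
        if {"x", "y"} & sampling.axis_set:
            if not {"x", "y"} <= sampling.axis_set:
                # one spatial axis only
                sl = [slice(None), slice(None), slice(None)]
                axis = 0 if "x" in sampling.axis_set else 1
                sl[axis] = slice(None, None, sampling.scale)
                out = out.with_data(out.data[tuple(sl)])
            else:
                out = downsample_spatial(out, sampling.scale)
        out = upsample_bicubic(out, original_shape, dt=original_dt)
    return out
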