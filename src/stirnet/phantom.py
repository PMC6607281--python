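"""Synthetic CTP phantoms with indicator-dilution kinetics.

No public CTP dataset accompanies the restoration problem this package
addresses, so every downstream stage (degradation, patching, network
training, metrics, perfusion) is exercised on a digital phantom: an
elliptical "brain" containing a few elliptical tissue compartments whose
time-attenuation curves follow the standard indicator-dilution model,

    C_t(t) = (CBF / 60) * (C_a * R)(t),      R(t) = exp(-t / MTT),

with a gamma-variate arterial input function (AIF)

    C_a(t) = A * (t - t0)^alpha * exp(-(t - t0) / beta)   for t > t0.

Because CBF and MTT are prescribed per region, the ground-truth perfusion
maps are known exactly (CBV = CBF * MTT / 60), which is what makes the
perfusion endpoint testable.

Default geometry mirrors a clinical single-slice cine study: 512 x 512
pixels, 119 frames over ~45 s; reduced sizes are used everywhere speed
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .volume import CTPVolume

__all__ = [
    "AIFSpec",
    "TissueRegion",
    "PhantomSpec",
    "PerfusionGroundTruth",
    "make_aif",
    "make_tissue_curve",
    "generate_phantom",
    "elliptical_mask",
    "default_phantom_spec",
]

#: Pre-contrast attenuation of brain tissue (HU); air outside the head.
DEFAULT_TISSUE_BASELINE = 40.0
BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class AIFSpec:
    """Gamma-variate arterial input function parameters.

    amplitude : A (HU * s^-alpha) — overall scale
    t0        : bolus arrival delay (s)
    alpha     : shape (dimensionless); peak sits at t0 + alpha*beta
    beta      : time scale (s)
    """

    amplitude: float = 66.14
    t0: float = 5.0
    alpha: float = 3.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise InvalidInputError("AIF amplitude, alpha and beta must be > 0")
        if self.t0 < 0:
            raise InvalidInputError("AIF delay t0 must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time of the AIF maximum: t0 + alpha * beta."""
        return self.t0 + self.alpha * self.beta

    @classmethod
    def with_peak(cls, peak_value: float = 300.0, t0: float = 5.0,
                  alpha: float = 3.0, beta: float = 1.5) -> "AIFSpec":
        """Choose the amplitude so the curve peaks at ``peak_value`` HU."""
        tp = alpha * beta
        amplitude = peak_value / (tp ** alpha * np.exp(-alpha))
        return cls(amplitude=amplitude, t0=t0, alpha=alpha, beta=beta)


@dataclass(frozen=True)
class TissueRegion:
    """A tissue compartment with homogeneous kinetics.

    mask     : boolean (nx, ny) membership map
    cbf      : cerebral blood flow, mL/100g/min (phantom units)
    mtt      : mean transit time, s
    baseline : pre-contrast attenuation, HU
    name     : label used in reports
    """

    mask: np.ndarray
    cbf: float
    mtt: float
    baseline: float = DEFAULT_TISSUE_BASELINE
    name: str = "tissue"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise InvalidInputError("region mask must be 2D")
        if self.cbf < 0:
            raise InvalidInputError("cbf must be >= 0")
        if self.mtt <= 0:
            raise InvalidInputError("mtt must be > 0")

    @property
    def cbv(self) -> float:
        """Cerebral blood volume implied by the central-volume theorem."""
        return self.cbf * self.mtt / 60.0


@dataclass(frozen=True)
class PhantomSpec:
    nx: int = 512
    ny: int = 512
    nt: int = 119
    dt: float = 45.0 / 119.0
    aif: AIFSpec = field(default_factory=AIFSpec.with_peak)
    regions: tuple[TissueRegion, ...] = ()
    seed: int = 0
    pixel_size: float = 0.43
    residue: str = "exponential"  # or "box", for deconvolution stress tests

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nt) < 1:
            raise InvalidInputError("nx, ny, nt must all be >= 1")
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if self.residue not in {"exponential", "box"}:
            raise InvalidInputError(f"unknown residue model {self.residue!r}")


@dataclass
class PerfusionGroundTruth:
    """Per-pixel CBF/CBV maps known by construction; zero outside regions."""

    cbf_map: np.ndarray
    cbv_map: np.ndarray

    def __post_init__(self) -> None:
        self.cbf_map = np.asarray(self.cbf_map, dtype=np.float64)
        self.cbv_map = np.asarray(self.cbv_map, dtype=np.float64)
        if self.cbf_map.shape != self.cbv_map.shape:
            raise InvalidInputError("cbf_map and cbv_map must share a shape")
        if (self.cbf_map < 0).any() or (self.cbv_map < 0).any():
            raise InvalidInputError("ground-truth perfusion maps must be non-negative")


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def make_aif(spec: AIFSpec, times: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate AIF at ``times`` (s, strictly increasing)."""
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or times.size == 0:
        raise InvalidInputError("times must be a non-empty 1D vector")
    if (times < 0).any():
        raise InvalidInputError("times must be non-negative")
    if times.size > 1 and not (np.diff(times) > 0).all():
        raise InvalidInputError("times must be strictly increasing")
    tau = times - spec.t0
    curve = np.zeros_like(times)
    post = tau > 0
    curve[post] = spec.amplitude * tau[post] ** spec.alpha * np.exp(-tau[post] / spec.beta)
    return curve


def residue_function(times: np.ndarray, mtt: float, kind: str = "exponential") -> np.ndarray:
    """Tracer residue R(t): fraction still in tissue t seconds after arrival."""
    times = np.asarray(times, dtype=np.float64)
    if kind == "exponential":
        return np.exp(-times / mtt)
    if kind == "box":
        return (times < mtt).astype(np.float64)
    raise InvalidInputError(f"unknown residue model {kind!r}")


def make_tissue_curve(aif: np.ndarray, cbf: float, mtt: float, dt: float,
                      residue: str = "exponential") -> np.ndarray:
    """Tissue concentration by causal discrete convolution of AIF and residue.

    C_t[i] = (cbf / 60) * dt * sum_j C_a[j] * R[i - j], truncated to the AIF
    length.  The 60 converts CBF from per-minute to per-second flow, so that
    the areas satisfy the central-volume identity
    integral(C_t) / integral(C_a) = cbf * mtt / 60 = CBV.
    """
    aif = np.asarray(aif, dtype=np.float64)
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if mtt <= 0:
        raise InvalidInputError("mtt must be > 0")
    if cbf < 0:
        raise InvalidInputError("cbf must be >= 0")
    t = np.arange(aif.size, dtype=np.float64) * dt
    r = residue_function(t, mtt, residue)
    return (cbf / 60.0) * dt * np.convolve(aif, r)[: aif.size]


# ---------------------------------------------------------------------------
# Geometry helpers and the default brain-like layout
# ---------------------------------------------------------------------------

def elliptical_mask(nx: int, ny: int, cx: float, cy: float,
                    rx: float, ry: float, angle: float = 0.0) -> np.ndarray:
    """Boolean mask of an ellipse centred at (cx, cy) with semi-axes (rx, ry)."""
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x - cx) * ca + (y - cy) * sa
    v = -(x - cx) * sa + (y - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def default_phantom_spec(nx: int = 512, ny: int = 512, nt: int = 119,
                         dt: float | None = None, seed: int = 0,
                         residue: str = "exponential") -> PhantomSpec:
    """Brain-like layout: gray-matter shell, white-matter core, ischemic lesion.

    Kinetic defaults are typical clinical magnitudes: gray matter CBF 60 /
    MTT 4 s, white matter CBF 25 / MTT 4.8 s, lesion CBF 10 / MTT 10 s.
    Geometry scales with (nx, ny) so reduced-size phantoms keep the same
    tissue proportions and edge structure; the seed jitters ellipse centres
    and radii by a few percent, so different seeds yield distinct anatomies
    (e.g. a held-out test phantom).
    """
    if dt is None:
        dt = 45.0 / nt
    rng = np.random.default_rng(seed)

    def j(value: float, rel: float = 0.04) -> float:
        return value * (1.0 + rel * (2.0 * rng.random() - 1.0))

    brain = elliptical_mask(nx, ny, j(nx * 0.5), j(ny * 0.5), j(nx * 0.42), j(ny * 0.36),
                            angle=j(0.05, 2.0))
    white = elliptical_mask(nx, ny, j(nx * 0.5), j(ny * 0.5), j(nx * 0.26), j(ny * 0.21),
                            angle=j(0.3))
    lesion = elliptical_mask(nx, ny, j(nx * 0.68), j(ny * 0.64), j(nx * 0.09), j(ny * 0.07),
                             angle=j(-0.5))
    gray = brain & ~white & ~lesion
    white_only = white & ~lesion
    lesion_only = lesion & brain
    regions = (
        TissueRegion(mask=gray, cbf=60.0, mtt=4.0, baseline=42.0, name="gray"),
        TissueRegion(mask=white_only, cbf=25.0, mtt=4.8, baseline=34.0, name="white"),
        TissueRegion(mask=lesion_only, cbf=10.0, mtt=10.0, baseline=38.0, name="lesion"),
    )
    return PhantomSpec(nx=nx, ny=ny, nt=nt, dt=dt, regions=regions, seed=seed,
                       residue=residue)


def generate_phantom(spec: PhantomSpec) -> tuple[CTPVolume, PerfusionGroundTruth]:
    """Render the phantom volume and its ground-truth perfusion maps.

    Every voxel inside a region carries exactly ``baseline + tissue curve``
    for that region's kinetics; voxels outside any region sit at the air
    value.  Deterministic given the spec (the seed is carried for
    reproducibility bookkeeping of derived experiments).
    """
    regions = spec.regions if spec.regions else default_phantom_spec(
        spec.nx, spec.ny, spec.nt, spec.dt, spec.seed, spec.residue).regions

    occupancy = np.zeros((spec.nx, spec.ny), dtype=np.int32)
    for region in regions:
        if region.mask.shape != (spec.nx, spec.ny):
            raise InvalidInputError(
                f"region {region.name!r} mask shape {region.mask.shape} "
                f"does not fit the {spec.nx} x {spec.ny} plane")
        occupancy += region.mask
    if (occupancy > 1).any():
        raise InvalidInputError("tissue region masks overlap")

    times = np.arange(spec.nt, dtype=np.float64) * spec.dt
    aif = make_aif(spec.aif, times)

    data = np.full((spec.nx, spec.ny, spec.nt), BACKGROUND_HU, dtype=np.float32)
    cbf_map = np.zeros((spec.nx, spec.ny))
    cbv_map = np.zeros((spec.nx, spec.ny))
    for region in regions:
        trace = region.baseline + make_tissue_curve(
            aif, region.cbf, region.mtt, spec.dt, spec.residue)
        data[region.mask, :] = trace.astype(np.float32)
        cbf_map[region.mask] = region.cbf
        cbv_map[region.mask] = region.cbv

    vol = CTPVolume(data=data, dt=spec.dt, pixel_size=spec.pixel_size)
    return vol, PerfusionGroundTruth(cbf_map=cbf_map, cbv_map=cbv_map)
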