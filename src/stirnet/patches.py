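"""Cross-section patch representation.

The restorer never sees 3D data directly.  The X x Y x T volume is sliced
into three families of 2D images:

* ``XY`` — the T spatial frames (nx x ny each),
* ``XT`` — one image per y column (nx x nt): a spatial line over time,
* ``YT`` — one image per x row (ny x nt).

The XT/YT sections put the temporal dimension on an image axis, which is
what lets a purely 2D convolutional network exploit temporal structure.
Images are cropped into fixed-size square patches (default 41 x 41, stride
21) on an *edge-covering* grid: stride multiples plus, when the tiling
stops short, one final patch clamped to the far edge, so the whole image is
covered.  With this rule a 512-pixel axis yields 24 starts and a 512 x 512
image yields 576 patches — the convention consistent with published patch
totals for this geometry (1,428 training frames -> 822,528 patches).

Degraded patches are paired with clean ("label") patches cut at identical
coordinates; intensities are mapped from the HU display window (default
[0, 255]) to [0, 1] for network I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .volume import CTPVolume

__all__ = [
    "CROSS_SECTIONS",
    "PatchGrid",
    "PatchPair",
    "extract_cross_sections",
    "stack_to_volume",
    "patch_starts",
    "make_grid",
    "patch_count",
    "extract_patches",
    "extract_patch_pairs",
    "reassemble_patches",
    "normalize",
    "denormalize",
    "brain_crop_bounds",
]

CROSS_SECTIONS = ("xy", "xt", "yt")

PATCH_SIZE = 41
PATCH_STRIDE = 21

#: HU display window mapped onto [0, 1] for network I/O; metrics use the
#: same 0-255 scale.
HU_WINDOW = (0.0, 255.0)


def _check_section(section: str) -> str:
    section = section.lower()
    if section not in CROSS_SECTIONS:
        raise InvalidInputError(f"cross-section must be one of {CROSS_SECTIONS}, got {section!r}")
    return section


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize(x: np.ndarray, window: tuple[float, float] = HU_WINDOW,
              clip: bool = False) -> np.ndarray:
    """Affine map of the HU window onto [0, 1]; optionally clipped."""
    lo, hi = window
    out = (np.asarray(x, dtype=np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0) if clip else out


def denormalize(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Inverse of :func:`normalize` (without clipping)."""
    lo, hi = window
    return np.asarray(x, dtype=np.float64) * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Cross-section slicing
# ---------------------------------------------------------------------------

def extract_cross_sections(vol: CTPVolume, section: str,
                           crop: tuple[slice, slice] | None = None) -> list[np.ndarray]:
    """Slice the volume into a list of 2D images along one cross-section.

    ``crop`` restricts the two *spatial* axes only (temporal axes are never
    cropped): a pair of slices over (x, y).
    """
    section = _check_section(section)
    data = vol.data
    if crop is not None:
        sx, sy = crop
        if (sx.start or 0) < 0 or (sy.start or 0) < 0 \
                or (sx.stop is not None and sx.stop > vol.nx) \
                or (sy.stop is not None and sy.stop > vol.ny):
            raise InvalidInputError(f"crop {crop} lies outside the {vol.nx} x {vol.ny} plane")
        data = data[sx, sy, :]
    if section == "xy":
        return [data[:, :, t] for t in range(data.shape[2])]
    if section == "xt":
        return [data[:, y, :] for y in range(data.shape[1])]
    return [data[x, :, :] for x in range(data.shape[0])]


def stack_to_volume(images: list[np.ndarray], section: str,
                    dt: float, pixel_size: float = 0.43) -> CTPVolume:
    """Inverse of :func:`extract_cross_sections` (for uncropped slicing)."""
    section = _check_section(section)
    if not images:
        raise InvalidInputError("no images to stack")
    shape0 = images[0].shape
    if any(im.shape != shape0 for im in images):
        raise InvalidInputError("images must share a shape")
    arr = np.stack(images, axis=0)
    if section == "xy":
        data = np.moveaxis(arr, 0, 2)       # (t, x, y) -> (x, y, t)
    elif section == "xt":
        data = np.moveaxis(arr, 0, 1)       # (y, x, t) -> (x, y, t)
    else:
        data = arr                          # (x, y, t)
    return CTPVolume(data=data, dt=dt, pixel_size=pixel_size)


def brain_crop_bounds(mask: np.ndarray, size: int = 300) -> tuple[slice, slice]:
    """A ``size`` x ``size`` crop window centred on the mask bounding box,
    clamped to the image; used to keep only brain pixels in XT/YT sections."""
    xs, ys = np.nonzero(mask)
    if xs.size == 0:
        raise InvalidInputError("mask is empty")
    nx, ny = mask.shape
    out = []
    for coords, n in ((xs, nx), (ys, ny)):
        centre = (coords.min() + coords.max()) // 2
        half = min(size, n) // 2
        start = int(np.clip(centre - half, 0, n - min(size, n)))
        out.append(slice(start, start + min(size, n)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Patch grids
# ---------------------------------------------------------------------------

def patch_starts(axis_len: int, patch_size: int = PATCH_SIZE,
                 stride: int = PATCH_STRIDE) -> np.ndarray:
    """Edge-covering start positions along one axis.

    Multiples of ``stride`` whose patch fits, plus one final start at
    ``axis_len - patch_size`` when the stride tiling does not already reach
    the far edge.
    """
    if patch_size > axis_len:
        raise InvalidInputError(f"patch_size {patch_size} exceeds axis length {axis_len}")
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    starts = list(range(0, axis_len - patch_size + 1, stride))
    if starts[-1] != axis_len - patch_size:
        starts.append(axis_len - patch_size)
    return np.asarray(starts, dtype=np.int64)


@dataclass(frozen=True)
class PatchGrid:
    """The start-position lattice of patches over one image shape."""

    section: str
    image_shape: tuple[int, int]
    patch_size: int = PATCH_SIZE
    stride: int = PATCH_STRIDE
    row_starts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    col_starts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_section(self.section)
        if self.row_starts is None:
            object.__setattr__(self, "row_starts",
                               patch_starts(self.image_shape[0], self.patch_size, self.stride))
        if self.col_starts is None:
            object.__setattr__(self, "col_starts",
                               patch_starts(self.image_shape[1], self.patch_size, self.stride))

    @property
    def patches_per_image(self) -> int:
        return len(self.row_starts) * len(self.col_starts)

    def to_dict(self) -> dict:
        return {
            "section": self.section,
            "image_shape": list(self.image_shape),
            "patch_size": self.patch_size,
            "stride": self.stride,
            "row_starts": self.row_starts.tolist(),
            "col_starts": self.col_starts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatchGrid":
        return cls(section=d["section"], image_shape=tuple(d["image_shape"]),
                   patch_size=d["patch_size"], stride=d["stride"],
                   row_starts=np.asarray(d["row_starts"]),
                   col_starts=np.asarray(d["col_starts"]))


def make_grid(section: str, image_shape: tuple[int, int],
              patch_size: int = PATCH_SIZE, stride: int = PATCH_STRIDE) -> PatchGrid:
    return PatchGrid(section=_check_section(section), image_shape=tuple(image_shape),
                     patch_size=patch_size, stride=stride)


def patch_count(image_shape: tuple[int, int], n_images: int,
                patch_size: int = PATCH_SIZE, stride: int = PATCH_STRIDE) -> int:
    """Total number of patches cut from ``n_images`` images of a given shape
    (pure grid arithmetic; nothing is materialized)."""
    rows = len(patch_starts(image_shape[0], patch_size, stride))
    cols = len(patch_starts(image_shape[1], patch_size, stride))
    return rows * cols * n_images


@dataclass
class PatchPair:
    """One degraded/clean patch pair on normalized [0, 1] intensity."""

    input_patch: np.ndarray
    label_patch: np.ndarray
    row_i: int
    col_i: int
    slice_index: int

    def __post_init__(self) -> None:
        if self.input_patch.shape != self.label_patch.shape:
            raise InvalidInputError("input and label patches must share a shape")


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """All grid patches of one image, shape (n_row, n_col, p, p)."""
    p = grid.patch_size
    out = np.empty((len(grid.row_starts), len(grid.col_starts), p, p), dtype=image.dtype)
    for i, r in enumerate(grid.row_starts):
        for j, c in enumerate(grid.col_starts):
            out[i, j] = image[r:r + p, c:c + p]
    return out


def extract_patch_pairs(clean: list[np.ndarray], degraded: list[np.ndarray],
                        section: str = "xy", patch_size: int = PATCH_SIZE,
                        stride: int = PATCH_STRIDE,
                        window: tuple[float, float] = HU_WINDOW,
                        clip: bool = True) -> list[PatchPair]:
    """Pair degraded patches with clean labels at identical coordinates.

    Intensities are normalized to [0, 1] with the configured HU window
    (clipped by default — network inputs live in [0, 1]).
    """
    if len(clean) != len(degraded):
        raise InvalidInputError(
            f"clean ({len(clean)}) and degraded ({len(degraded)}) image lists differ in length")
    pairs: list[PatchPair] = []
    for k, (c_img, d_img) in enumerate(zip(clean, degraded)):
        if c_img.shape != d_img.shape:
            raise InvalidInputError(f"image {k}: clean {c_img.shape} != degraded {d_img.shape}")
        grid = make_grid(section, c_img.shape, patch_size, stride)
        c_n = normalize(c_img, window, clip=clip)
        d_n = normalize(d_img, window, clip=clip)
        for i, r in enumerate(grid.row_starts):
            for j, col in enumerate(grid.col_starts):
                pairs.append(PatchPair(
                    input_patch=d_n[r:r + patch_size, col:col + patch_size].astype(np.float32),
                    label_patch=c_n[r:r + patch_size, col:col + patch_size].astype(np.float32),
                    row_i=i, col_i=j, slice_index=k))
    return pairs


def reassemble_patches(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Invert :func:`extract_patches`, averaging overlapping pixels.

    ``patches`` has shape (n_row, n_col, p, p) and must cover the full grid.
    """
    expected = (len(grid.row_starts), len(grid.col_starts),
                grid.patch_size, grid.patch_size)
    if patches.shape != expected:
        raise InvalidInputError(
            f"patch array shape {patches.shape} does not match grid {expected}")
    p = grid.patch_size
    acc = np.zeros(grid.image_shape, dtype=np.float64)
    weight = np.zeros(grid.image_shape, dtype=np.float64)
    for i, r in enumerate(grid.row_starts):
        for j, c in enumerate(grid.col_starts):
            acc[r:r + p, c:c + p] += patches[i, j]
            weight[r:r + p, c:c + p] += 1.0
    if (weight == 0).any():
        raise InvalidInputError("grid does not cover the image")
    return acc / weight
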