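"""The CTP volume container and its file formats.

A CT perfusion (CTP) acquisition is a cine scan of one axial brain slice: the
same ``X x Y`` plane imaged repeatedly over ~45 s while a contrast bolus
transits the vasculature.  The whole study is therefore a 3D array
``X x Y x T`` of attenuation values (Hounsfield-like units) plus two pieces of
metadata: the frame interval ``dt`` (s) and the in-plane pixel size (mm).

Volumes are stored as 3D NIfTI files (time as the third dimension, ``dt``
recorded both in the header ``pixdim`` slot and in a JSON sidecar) or as a
directory of per-frame 16-bit PNGs with an index manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, VolumeIOError

__all__ = ["CTPVolume", "read_volume", "write_volume"]


@dataclass
class CTPVolume:
    """A single-slice CTP study: ``data[x, y, t]`` in HU.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nt)
        Attenuation values.  Stored as float32.
    dt : float
        Frame interval in seconds.
    pixel_size : float
        In-plane resolution in mm (isotropic).
    """

    data: np.ndarray
    dt: float
    pixel_size: float = 0.43

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"CTPVolume expects a 3D (X, Y, T) array, got ndim={self.data.ndim}"
            )
        if self.dt <= 0:
            raise InvalidInputError(f"frame interval dt must be > 0, got {self.dt}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("CTPVolume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nt(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.nt, dtype=np.float64) * self.dt

    def with_data(self, data: np.ndarray, dt: float | None = None) -> "CTPVolume":
        """A copy carrying ``data`` (and optionally a new dt), keeping metadata."""
        return replace(self, data=np.asarray(data, dtype=np.float32),
                       dt=self.dt if dt is None else dt)

    def copy(self) -> "CTPVolume":
        return replace(self, data=self.data.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _write_nifti(vol: CTPVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([vol.pixel_size, vol.pixel_size, 1.0, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header["pixdim"][3] = vol.dt
    img.header["descrip"] = f"dt={vol.dt:.6g}s".encode()
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"dt": vol.dt, "pixel_size": vol.pixel_size, "shape": list(vol.shape)}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))


def _read_nifti(path: Path) -> CTPVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D (X, Y, T) NIfTI, got ndim={data.ndim}")
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        dt = float(meta["dt"])
        pixel_size = float(meta.get("pixel_size", 0.43))
    else:
        dt = float(img.header["pixdim"][3]) or 1.0
        pixel_size = float(img.header["pixdim"][1]) or 0.43
    return CTPVolume(data=data, dt=dt, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# PNG-stack I/O: one 16-bit PNG per frame + a JSON manifest with the affine
# scale needed to recover HU values.
# ---------------------------------------------------------------------------

def _write_png_stack(vol: CTPVolume, directory: Path) -> None:
    import imageio.v3 as iio

    directory.mkdir(parents=True, exist_ok=True)
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    span = hi - lo if hi > lo else 1.0
    scale = 65535.0 / span
    frames = []
    for t in range(vol.nt):
        name = f"frame_{t:04d}.png"
        frame = np.round((vol.data[:, :, t] - lo) * scale).astype(np.uint16)
        iio.imwrite(directory / name, frame)
        frames.append(name)
    manifest = {
        "frames": frames,
        "dt": vol.dt,
        "pixel_size": vol.pixel_size,
        "intensity_offset": lo,
        "intensity_scale": 1.0 / scale,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _read_png_stack(directory: Path) -> CTPVolume:
    import imageio.v3 as iio

    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise VolumeIOError(f"{directory}: PNG stack is missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    frames = []
    shape = None
    for name in manifest["frames"]:
        frame = np.asarray(iio.imread(directory / name), dtype=np.float64)
        if frame.ndim != 2:
            raise VolumeIOError(f"{directory / name}: frames must be single-channel 2D")
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise VolumeIOError(f"{directory / name}: frame shape {frame.shape} != {shape}")
        frames.append(frame)
    data = np.stack(frames, axis=-1)
    data = data * float(manifest["intensity_scale"]) + float(manifest["intensity_offset"])
    return CTPVolume(
        data=data.astype(np.float32),
        dt=float(manifest["dt"]),
        pixel_size=float(manifest.get("pixel_size", 0.43)),
    )


def write_volume(vol: CTPVolume, path: str | Path) -> None:
    """Write ``vol`` as NIfTI (``.nii``/``.nii.gz``) or as a PNG-stack directory."""
    path = Path(path)
    try:
        if path.suffix in {".nii", ".gz"} or "".join(path.suffixes).endswith(".nii.gz"):
            _write_nifti(vol, path)
        else:
            _write_png_stack(vol, path)
    except (OSError, ValueError) as exc:  # pragma: no cover - environment-specific
        raise VolumeIOError(f"{path}: {exc}") from exc


def read_volume(path: str | Path) -> CTPVolume:
    """Read a CTPVolume from NIfTI or a PNG-stack directory (see :func:`write_volume`)."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"{path}: no such file or directory")
    try:
        if path.is_dir():
            return _read_png_stack(path)
        return _read_nifti(path)
    except VolumeIOError:
        raise
    except Exception as exc:
        raise VolumeIOError(f"{path}: {exc}") from exc
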