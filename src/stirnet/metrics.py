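"""Image-quality metrics and significance testing.

Restoration quality is judged against the full-dose volume with two
standard metrics, computed on the 0-255 display scale used for network I/O:

* **PSNR** = 20 * log10(Imax / rmse), with Imax fixed to the dynamic range
  L = 255 so slices are comparable to each other (a per-image maximum would
  move the yardstick between slices);
* **SSIM** — the product of luminance, contrast and structure terms over a
  moving window (default 8 x 8, uniform weights),

      l = (2 mx my + c1) / (mx^2 + my^2 + c1)
      c = (2 sx sy + c2) / (sx^2 + sy^2 + c2)
      s = (sxy + c3) / (sx sy + c3)

  with stabilizers c1 = (0.01 L)^2 = 6.5025, c2 = (0.03 L)^2 = 58.5225 and
  c3 = c2 / 2 = 29.26125 at L = 255.  Local moments are population
  statistics (uniform box filter), matching the plain-formula presentation.

Per-slice improvements (restored minus degraded) are compared with a
one-tailed paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DegenerateInputError, InvalidInputError
from .volume import CTPVolume

__all__ = [
    "SSIMConstants",
    "MetricsReport",
    "psnr",
    "ssim",
    "paired_one_tailed_ttest",
    "evaluate_volumes",
]

DYNAMIC_RANGE = 255.0
SSIM_WINDOW = 8


@dataclass(frozen=True)
class SSIMConstants:
    """SSIM stabilizers derived from the dynamic range L."""

    L: float = DYNAMIC_RANGE

    @property
    def c1(self) -> float:
        return (0.01 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.L) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def psnr(ground_truth: np.ndarray, estimate: np.ndarray,
         L: float = DYNAMIC_RANGE) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    gt = np.asarray(ground_truth, dtype=np.float64)
    est = np.asarray(estimate, dtype=np.float64)
    if gt.shape != est.shape:
        raise InvalidInputError(f"shape mismatch {gt.shape} vs {est.shape}")
    if L <= 0:
        raise InvalidInputError("dynamic range L must be > 0")
    rmse = math.sqrt(float(np.mean((gt - est) ** 2)))
    if rmse == 0.0:
        return math.inf
    return 20.0 * math.log10(L / rmse)


def ssim(x: np.ndarray, y: np.ndarray,
         constants: SSIMConstants = SSIMConstants(),
         window: int = SSIM_WINDOW) -> float:
    """Mean structural similarity over uniform local windows; 1 iff x == y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidInputError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise InvalidInputError("ssim expects 2D images")
    if window > min(x.shape):
        raise InvalidInputError(
            f"window {window} larger than image {x.shape}")

    def box(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    mx, my = box(x), box(y)
    # population local moments
    vx = box(x * x) - mx * mx
    vy = box(y * y) - my * my
    cxy = box(x * y) - mx * my
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    sx, sy = np.sqrt(vx), np.sqrt(vy)

    c1, c2, c3 = constants.c1, constants.c2, constants.c3
    l_term = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
    c_term = (2 * sx * sy + c2) / (vx + vy + c2)
    s_term = (cxy + c3) / (sx * sy + c3)
    return float(np.mean(l_term * c_term * s_term))


def paired_one_tailed_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired t-test of H1: mean(b - a) > 0; returns (t, df, one-tailed p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired samples must be equal-length 1D vectors")
    n = a.size
    if n < 2:
        raise InvalidInputError("need at least two pairs")
    diff = b - a
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateInputError("differences have zero variance")
    res = stats.ttest_rel(b, a, alternative="greater")
    return float(res.statistic), n - 1, float(res.pvalue)


@dataclass
class MetricsReport:
    """Per-slice PSNR/SSIM of degraded (lr) and restored volumes vs ground
    truth, with improvements, aggregates and paired t-tests."""

    per_slice: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_slice.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"summary": self.summary}


def _finite(values: np.ndarray) -> np.ndarray:
    return values[np.isfinite(values)]


def evaluate_volumes(gt: CTPVolume, lr: CTPVolume, restored: CTPVolume,
                     L: float = DYNAMIC_RANGE, window: int = SSIM_WINDOW,
                     hu_window: tuple[float, float] = (0.0, 255.0)) -> MetricsReport:
    """Per-XY-slice PSNR/SSIM report on the 0-255 display scale.

    All three volumes are mapped through the same clipped HU display window
    before scoring, so degraded and restored arms see identical scaling.
    """
    if not (gt.shape == lr.shape == restored.shape):
        raise InvalidInputError(
            f"volume shapes differ: {gt.shape}, {lr.shape}, {restored.shape}")

    lo, hi = hu_window
    scale = L / (hi - lo)

    def disp(frame: np.ndarray) -> np.ndarray:
        return np.clip((frame.astype(np.float64) - lo) * scale, 0.0, L)

    rows = []
    for t in range(gt.nt):
        g = disp(gt.data[:, :, t])
        l_img = disp(lr.data[:, :, t])
        r_img = disp(restored.data[:, :, t])
        psnr_lr = psnr(g, l_img, L)
        psnr_re = psnr(g, r_img, L)
        ssim_lr = ssim(g, l_img, SSIMConstants(L), window)
        ssim_re = ssim(g, r_img, SSIMConstants(L), window)
        rows.append({
            "slice": t,
            "psnr_lr": psnr_lr, "psnr_restored": psnr_re,
            "psnr_improvement": psnr_re - psnr_lr,
            "ssim_lr": ssim_lr, "ssim_restored": ssim_re,
            "ssim_improvement": ssim_re - ssim_lr,
        })
    df = pd.DataFrame(rows)

    summary: dict = {}
    for metric in ("psnr", "ssim"):
        for arm in ("lr", "restored", "improvement"):
            col = f"{metric}_{arm}"
            vals = _finite(df[col].to_numpy())
            summary[f"{col}_mean"] = float(vals.mean()) if vals.size else math.inf
            summary[f"{col}_var"] = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
        try:
            finite = df[np.isfinite(df[f"{metric}_lr"]) & np.isfinite(df[f"{metric}_restored"])]
            t_stat, df_t, p = paired_one_tailed_ttest(
                finite[f"{metric}_lr"].to_numpy(), finite[f"{metric}_restored"].to_numpy())
            summary[f"{metric}_ttest"] = {"t": t_stat, "df": df_t, "p": p}
        except (DegenerateInputError, InvalidInputError):
            summary[f"{metric}_ttest"] = None
    return MetricsReport(per_slice=df, summary=summary)
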