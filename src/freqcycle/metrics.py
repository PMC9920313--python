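"""Image-quality metrics for translated volumes.

MAE, MSE, NMSE, PSNR and SSIM between a reference CT and a prediction, plus
Dice overlap, HU histograms and axial line profiles for domain-specific
evaluation.  The evaluation convention of the reference protocol is HU-scale
intensities clipped to [0, 3000]; :func:`evaluate_pair` applies it and
records it in the report so conventions never drift silently.

Definitions (ref = CT, pred = generated, N voxels):

    MAE  = (1/N) sum |ref - pred|
    MSE  = (1/N) sum (ref - pred)^2
    NMSE = sum (ref - pred)^2 / sum ref^2        (numerator NOT divided by N)
    PSNR = 20 log10(max(ref)) - 10 log10(MSE)    [dB]
    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
           ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with c1 = (0.01 R)^2, c2 = (0.03 R)^2 for data range R.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BodyMask, Volume3D

__all__ = [
    "MetricReport",
    "mae",
    "mse",
    "nmse",
    "psnr",
    "ssim",
    "dice",
    "hu_histogram",
    "line_profile",
    "evaluate_pair",
    "DEFAULT_CLIP_RANGE",
    "DEFAULT_DATA_RANGE",
]

DEFAULT_CLIP_RANGE = (0.0, 3000.0)
DEFAULT_DATA_RANGE = 3000.0


def _arrays(ref, pred, mask):
    a = ref.data if isinstance(ref, Volume3D) else np.asarray(ref, dtype=np.float64)
    b = pred.data if isinstance(pred, Volume3D) else np.asarray(pred, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: ref {a.shape} vs pred {b.shape}")
    if mask is not None:
        m = mask.data if isinstance(mask, BodyMask) else np.asarray(mask).astype(bool)
        if m.shape != a.shape:
            raise ValueError(f"mask shape {m.shape} does not match volumes {a.shape}")
        if not m.any():
            raise ValueError("mask selects no voxels")
        return a[m], b[m]
    return a.ravel(), b.ravel()


def mae(ref, pred, mask=None) -> float:
    a, b = _arrays(ref, pred, mask)
    return float(np.mean(np.abs(a - b)))


def mse(ref, pred, mask=None) -> float:
    a, b = _arrays(ref, pred, mask)
    d = a - b
    return float(np.mean(d * d))


def nmse(ref, pred, mask=None) -> float:
    a, b = _arrays(ref, pred, mask)
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ZeroDivisionError("NMSE undefined: reference has zero signal power")
    d = a - b
    return float(np.sum(d * d) / denom)


def psnr(ref, pred, mask=None) -> float:
    """PSNR in dB with ref_max taken from the (masked) reference itself.

    A zero-MSE (perfect) prediction yields +inf rather than an exception.
    """
    a, b = _arrays(ref, pred, mask)
    ref_max = float(a.max())
    if ref_max <= 0:
        raise ValueError("PSNR undefined: reference maximum is not positive")
    m = float(np.mean((a - b) ** 2))
    if m == 0.0:
        return math.inf
    return 20.0 * math.log10(ref_max) - 10.0 * math.log10(m)


def _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2):
    return ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    )


def ssim(ref, pred, mask=None, mode: str = "windowed", data_range: float = DEFAULT_DATA_RANGE,
         window: int = 7) -> float:
    """Structural similarity.

    ``global`` evaluates the single-window formula once with whole-volume
    statistics; ``windowed`` averages it over uniform ``window``-cubed local
    neighbourhoods (the common IQA practice), optionally restricted to a mask.
    """
    if mode not in ("global", "windowed"):
        raise ValueError(f"mode must be 'global' or 'windowed', got {mode!r}")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    if mode == "global":
        a, b = _arrays(ref, pred, mask)
        cov = float(np.mean((a - a.mean()) * (b - b.mean())))
        return float(_ssim_formula(a.mean(), b.mean(), a.var(), b.var(), cov, c1, c2))

    a = ref.data if isinstance(ref, Volume3D) else np.asarray(ref, dtype=np.float64)
    b = pred.data if isinstance(pred, Volume3D) else np.asarray(pred, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: ref {a.shape} vs pred {b.shape}")
    size = min(window, *a.shape)
    u = lambda x: ndimage.uniform_filter(x, size=size)
    mu_x, mu_y = u(a), u(b)
    var_x = u(a * a) - mu_x * mu_x
    var_y = u(b * b) - mu_y * mu_y
    cov = u(a * b) - mu_x * mu_y
    smap = _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2)
    if mask is not None:
        m = mask.data if isinstance(mask, BodyMask) else np.asarray(mask).astype(bool)
        if m.shape != a.shape:
            raise ValueError(f"mask shape {m.shape} does not match volumes {a.shape}")
        if not m.any():
            raise ValueError("mask selects no voxels")
        return float(smap[m].mean())
    return float(smap.mean())


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = mask_a.data if isinstance(mask_a, BodyMask) else np.asarray(mask_a).astype(bool)
    b = mask_b.data if isinstance(mask_b, BodyMask) else np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def hu_histogram(vol, lo: float = -500.0, hi: float = 500.0, bins: int = 100, mask=None):
    """Counts over uniform bins on [lo, hi); out-of-range voxels are excluded.

    Returns (counts, bin_edges).
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if not lo < hi:
        raise ValueError(f"lo must be < hi, got ({lo}, {hi})")
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=np.float64)
    if mask is not None:
        m = mask.data if isinstance(mask, BodyMask) else np.asarray(mask).astype(bool)
        data = data[m]
    data = data.ravel()
    in_range = (data >= lo) & (data < hi)
    edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(data[in_range], bins=edges)
    return counts, edges


def line_profile(vol, axial_slice: int, start, end, n_samples: int = 100) -> np.ndarray:
    """HU values along an in-plane segment of one axial slice.

    ``start`` / ``end`` are (x, y) voxel coordinates; samples are linearly
    spaced with bilinear interpolation.
    """
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=np.float64)
    if not 0 <= axial_slice < data.shape[0]:
        raise ValueError(f"axial slice {axial_slice} out of bounds for {data.shape[0]} slices")
    sl = data[axial_slice]
    ny, nx = sl.shape
    for name, (x, y) in (("start", start), ("end", end)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(f"{name} point {(x, y)} outside slice bounds ({nx}x{ny})")
    xs = np.linspace(start[0], end[0], n_samples)
    ys = np.linspace(start[1], end[1], n_samples)
    return ndimage.map_coordinates(sl, np.vstack([ys, xs]), order=1, mode="nearest")


@dataclass(frozen=True)
class MetricReport:
    """All similarity metrics of one (ref, pred) pair plus the convention used."""

    mae: float
    mse: float
    nmse: float
    psnr: float
    ssim: float
    clip_range: tuple
    mask_used: bool
    ssim_mode: str = "windowed"
    dice_per_label: dict | None = None

    def as_dict(self) -> dict:
        d = {
            "mae": self.mae,
            "mse": self.mse,
            "nmse": self.nmse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "clip_range": list(self.clip_range),
            "mask_used": self.mask_used,
            "ssim_mode": self.ssim_mode,
        }
        if self.dice_per_label is not None:
            d["dice_per_label"] = dict(self.dice_per_label)
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def evaluate_pair(ref, pred, mask=None, clip_range=DEFAULT_CLIP_RANGE,
                  ssim_mode: str = "windowed",
                  data_range: float | None = None) -> MetricReport:
    """Clip both volumes to ``clip_range``, apply the optional mask, and
    compute all five metrics under one recorded convention."""
    lo, hi = clip_range
    if not lo < hi:
        raise ValueError(f"invalid clip range {clip_range}")
    a = ref.data if isinstance(ref, Volume3D) else np.asarray(ref, dtype=np.float64)
    b = pred.data if isinstance(pred, Volume3D) else np.asarray(pred, dtype=np.float64)
    ca, cb = np.clip(a, lo, hi), np.clip(b, lo, hi)
    rng = data_range if data_range is not None else float(hi - lo)
    return MetricReport(
        mae=mae(ca, cb, mask),
        mse=mse(ca, cb, mask),
        nmse=nmse(ca, cb, mask),
        psnr=psnr(ca, cb, mask),
        ssim=ssim(ca, cb, mask, mode=ssim_mode, data_range=rng),
        clip_range=(float(lo), float(hi)),
        mask_used=mask is not None,
        ssim_mode=ssim_mode,
    )
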