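"""3D volume container and deterministic spatial/intensity preprocessing.

A :class:`Volume3D` is the universal currency of the toolkit: a 3D scalar
grid on the Hounsfield-unit (HU) or normalized [-1, 1] scale, with voxel
spacing and origin in millimetres.  Array data is indexed (z, y, x) while
spacing/origin follow the medical-imaging metadata convention (x, y, z) —
exactly what NIfTI/NRRD/MetaImage headers store.

I/O goes through SimpleITK, so NIfTI (.nii/.nii.gz), NRRD (.nrrd) and
MetaImage (.mha/.mhd) are all supported with their metadata intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BodyMask",
    "read_volume",
    "write_volume",
    "resample_to_spacing",
    "compute_body_mask",
    "apply_mask",
    "truncate_fov",
    "clip_and_scale",
    "AIR_HU",
    "DEFAULT_BODY_THRESHOLD_HU",
]

AIR_HU = -1000.0
DEFAULT_BODY_THRESHOLD_HU = -300.0

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


@dataclass
class Volume3D:
    """A 3D scalar volume with spatial metadata.

    Attributes
    ----------
    data : ndarray, shape (z, y, x)
        Voxel intensities, HU or normalized.
    spacing : tuple of float
        Voxel size (x, y, z) in mm; all strictly positive.
    origin : tuple of float
        Physical position (x, y, z) of the first voxel centre, in mm.
    scale_tag : {"hu", "normalized"}
        Intensity scale; "normalized" implies all values in [-1, 1].
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    scale_tag: str = "hu"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"every axis must have >= 1 voxel, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.scale_tag not in ("hu", "normalized"):
            raise ValueError(f"scale_tag must be 'hu' or 'normalized', got {self.scale_tag!r}")
        if self.scale_tag == "normalized":
            lo, hi = self.data.min(), self.data.max()
            if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
                raise ValueError(
                    f"normalized volume must lie in [-1, 1], got range [{lo:g}, {hi:g}]"
                )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray, scale_tag: str | None = None) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin, scale_tag or self.scale_tag)


@dataclass
class BodyMask:
    """Boolean mask, shape-congruent with its companion :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape


def _check_ext(path: str) -> None:
    p = str(path).lower()
    if not any(p.endswith(e) for e in _SUPPORTED_EXT):
        raise IOError(
            f"unsupported volume format for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path) -> Volume3D:
    """Read a NIfTI/NRRD/MetaImage file into a :class:`Volume3D` (HU scale).

    Raises
    ------
    IOError
        If the file is missing or unreadable.
    ValueError
        If the image is not 3-dimensional.
    """
    _check_ext(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError
        raise IOError(f"could not read volume from {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path!r} is {img.GetDimension()}D; expected a 3D volume")
    data = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    return Volume3D(data, spacing=img.GetSpacing(), origin=img.GetOrigin(), scale_tag="hu")


def read_mask(path) -> BodyMask:
    """Read a 0/1 mask volume."""
    vol = read_volume(path)
    return BodyMask(vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def _to_sitk(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.data)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume; format inferred from the extension."""
    _check_ext(path)
    try:
        sitk.WriteImage(_to_sitk(vol), str(path))
    except Exception as exc:
        raise IOError(f"could not write volume to {path!r}: {exc}") from exc


def write_mask(mask: BodyMask, path) -> None:
    vol = Volume3D(mask.data.astype(np.float64), mask.spacing, mask.origin, "hu")
    write_volume(vol, path)


def resample_to_spacing(vol, target_spacing, interpolation: str = "linear"):
    """Resample a volume (or mask) to ``target_spacing`` (x, y, z) mm.

    Output shape per axis is round(in_shape * in_spacing / target_spacing),
    at least 1.  Intensity volumes use linear interpolation; masks must use
    nearest-neighbour to avoid label bleeding.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")

    is_mask = isinstance(vol, BodyMask)
    src = Volume3D(vol.data.astype(np.float64), vol.spacing, vol.origin) if is_mask else vol
    if target_spacing == src.spacing:
        out = src.copy()
        return BodyMask(out.data > 0.5, out.spacing, out.origin) if is_mask else out

    # sitk sizes are (x, y, z); array shape is (z, y, x)
    in_size_xyz = src.data.shape[::-1]
    out_size = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(in_size_xyz, src.spacing, target_spacing)
    )
    interp = sitk.sitkNearestNeighbor if (interpolation == "nearest" or is_mask) else sitk.sitkLinear
    img = _to_sitk(src)
    res = sitk.Resample(
        img,
        out_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target_spacing,
        img.GetDirection(),
        float(src.data.min()),
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(res)
    if is_mask:
        return BodyMask(data > 0.5, spacing=target_spacing, origin=src.origin)
    return Volume3D(data, spacing=target_spacing, origin=src.origin, scale_tag=src.scale_tag)


def compute_body_mask(vol: Volume3D, air_threshold: float = DEFAULT_BODY_THRESHOLD_HU) -> BodyMask:
    """Patient-body mask: largest 26-connected component above ``air_threshold``
    with per-axial-slice hole filling.

    Raises
    ------
    ValueError
        If the volume is not on the HU scale or no voxel exceeds the threshold.
    """
    if vol.scale_tag != "hu":
        raise ValueError("body mask derivation expects a volume on the HU scale")
    fg = vol.data > air_threshold
    if not fg.any():
        raise ValueError(f"empty body mask: no voxel above {air_threshold} HU")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    for z in range(fg.shape[0]):
        fg[z] = ndimage.binary_fill_holes(fg[z])
    return BodyMask(fg, spacing=vol.spacing, origin=vol.origin)


def apply_mask(vol: Volume3D, mask: BodyMask, fill_value: float = AIR_HU) -> Volume3D:
    """Set voxels outside the mask to ``fill_value``; inside voxels unchanged."""
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {vol.shape}")
    out = np.where(mask.data, vol.data, float(fill_value))
    return vol.with_data(out)


def _axis_extents(vol: Volume3D):
    """Physical start and length per array axis (z, y, x), treating the origin
    as the edge of the first voxel."""
    sp_zyx = vol.spacing[::-1]
    or_zyx = vol.origin[::-1]
    return [(or_zyx[a], sp_zyx[a] * vol.shape[a]) for a in range(3)]


def truncate_fov(ct: Volume3D, cbct: Volume3D, fill_value: float = AIR_HU) -> Volume3D:
    """Crop (and air-pad) the CT so its physical extent matches the CBCT's.

    All arithmetic is origin + spacing * shape per axis; where the CBCT
    extends beyond the CT, the output is padded with ``fill_value``.

    Raises
    ------
    ValueError
        If the two extents have no physical overlap.
    """
    ct_ext = _axis_extents(ct)
    cb_ext = _axis_extents(cbct)
    sp_zyx = ct.spacing[::-1]

    slices, pads, new_origin_zyx = [], [], []
    for a in range(3):
        ct_lo, ct_len = ct_ext[a]
        cb_lo, cb_len = cb_ext[a]
        if cb_lo >= ct_lo + ct_len or cb_lo + cb_len <= ct_lo:
            raise ValueError("CT and CBCT extents do not overlap; cannot truncate field-of-view")
        i_lo = int(round((cb_lo - ct_lo) / sp_zyx[a]))
        n = max(1, int(round(cb_len / sp_zyx[a])))
        pad_lo = max(0, -i_lo)
        start = max(0, i_lo)
        stop = min(ct.shape[a], i_lo + n)
        pad_hi = max(0, (i_lo + n) - ct.shape[a])
        slices.append(slice(start, stop))
        pads.append((pad_lo, pad_hi))
        new_origin_zyx.append(ct_lo + i_lo * sp_zyx[a])

    out = ct.data[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, constant_values=float(fill_value))
    return Volume3D(out, spacing=ct.spacing, origin=tuple(new_origin_zyx[::-1]),
                    scale_tag=ct.scale_tag)


def clip_and_scale(vol: Volume3D, clip_lo: float, clip_hi: float, direction: str) -> Volume3D:
    """Map HU <-> normalized [-1, 1] through a clip-and-linear-scale window.

    ``to_normalized`` clips to [clip_lo, clip_hi] then maps linearly onto
    [-1, 1]; ``to_hu`` is the exact inverse on [-1, 1] (inputs outside by
    more than 1e-6 are rejected).
    """
    clip_lo, clip_hi = float(clip_lo), float(clip_hi)
    if not clip_lo < clip_hi:
        raise ValueError(f"clip_lo must be < clip_hi, got ({clip_lo}, {clip_hi})")
    if direction == "to_normalized":
        clipped = np.clip(vol.data, clip_lo, clip_hi)
        out = (clipped - clip_lo) / (clip_hi - clip_lo) * 2.0 - 1.0
        # guard rounding at the boundaries
        out = np.clip(out, -1.0, 1.0)
        return vol.with_data(out, scale_tag="normalized")
    if direction == "to_hu":
        lo, hi = vol.data.min(), vol.data.max()
        if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
            raise ValueError(
                f"to_hu input must lie in [-1, 1] (tolerance 1e-6), got [{lo:g}, {hi:g}]"
            )
        data = np.clip(vol.data, -1.0, 1.0)
        out = (data + 1.0) / 2.0 * (clip_hi - clip_lo) + clip_lo
        return vol.with_data(out, scale_tag="hu")
    raise ValueError(f"direction must be 'to_normalized' or 'to_hu', got {direction!r}")
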