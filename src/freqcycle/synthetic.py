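"""Synthetic paired CT / CBCT volumes and an anthropomorphic phantom analogue.

Clinical CBCT/CT cohorts are private, so every other module in this toolkit
is exercised on generated data: a CT-like phantom (ellipsoidal body with two
lungs, a heart, rib-like bone arcs, a spine and an optional tumor, each at a
standard tissue HU target plus mild texture noise) and a CBCT-like
degradation of it (HU miscalibration, axial streaks, blur, noise, optional
smooth deformation).  Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume3D, write_volume

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "LABELS",
    "make_phantom_ct",
    "degrade_to_cbct",
    "make_dataset",
]

#: integer ids of the phantom label map
LABELS = {
    "air": 0,
    "body": 1,
    "lung_left": 2,
    "lung_right": 3,
    "heart": 4,
    "bone": 5,
    "tumor": 6,
}

_DEFAULT_HU = {
    "air": -1000.0,
    "body": 40.0,
    "lung": -750.0,
    "bone": 700.0,
    "heart": 50.0,
    "tumor": 30.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of the CT-like phantom.

    ``shape`` is (z, y, x) voxels; ``spacing`` (x, y, z) mm.  HU targets are
    standard tissue values and configurable.  ``tumor_radius`` (voxels) of 0
    removes the tumor.  ``organ_scale`` jitters all organ semi-axes (used to
    emulate inter-patient variation).
    """

    shape: tuple = (32, 96, 96)
    spacing: tuple = (1.2695, 1.2695, 3.0)
    hu: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    tumor_radius: float = 4.0
    tumor_center: tuple | None = None  # (z, y, x) voxels; default inside right lung
    texture_sigma: float = 10.0
    organ_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(n < 8 for n in self.shape):
            raise ValueError(f"phantom shape must be 3 axes of >= 8 voxels, got {self.shape}")
        for k, v in self.hu.items():
            if not (-1000.0 <= v <= 3000.0):
                raise ValueError(f"HU target {k}={v} outside [-1000, 3000]")
        if not (0.5 <= self.organ_scale <= 1.15):
            raise ValueError("organ_scale outside the range that keeps organs nested in the body")


@dataclass(frozen=True)
class DegradationSpec:
    """CBCT-like degradation knobs; the all-zero spec is the identity."""

    hu_shift: float = 40.0
    hu_scale: float = 1.0
    streak_amplitude: float = 60.0
    streak_count: int = 24
    blur_sigma: float = 1.0  # mm
    noise_sigma: float = 20.0  # HU
    deform_amplitude: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self):
        for name in ("streak_amplitude", "streak_count", "blur_sigma",
                     "noise_sigma", "deform_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def identity(cls, seed: int = 0) -> "DegradationSpec":
        return cls(hu_shift=0.0, hu_scale=1.0, streak_amplitude=0.0, streak_count=0,
                   blur_sigma=0.0, noise_sigma=0.0, deform_amplitude=0.0, seed=seed)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=np.float64)
    return (((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2) <= 1.0


def make_phantom_ct(spec: PhantomSpec | None = None):
    """Build the phantom CT and its label map.

    Returns
    -------
    (Volume3D, ndarray)
        HU volume and integer label map (ids per :data:`LABELS`).
    """
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.shape
    s = spec.organ_scale
    rng = np.random.default_rng(spec.seed)

    cz, cy, cx = nz / 2.0, ny / 2.0, nx / 2.0
    body_semi = (0.47 * nz, 0.40 * ny, 0.44 * nx)
    body = _ellipsoid(spec.shape, (cz, cy, cx), body_semi)

    lung_semi = (s * 0.32 * nz, s * 0.24 * ny, s * 0.15 * nx)
    lung_l = _ellipsoid(spec.shape, (cz, cy - 0.04 * ny, cx - 0.20 * nx), lung_semi)
    lung_r = _ellipsoid(spec.shape, (cz, cy - 0.04 * ny, cx + 0.20 * nx), lung_semi)
    heart = _ellipsoid(spec.shape, (cz, cy + 0.02 * ny, cx - 0.04 * nx),
                       (s * 0.18 * nz, s * 0.15 * ny, s * 0.12 * nx))

    # spine: posterior cylinder; ribs: partial shell of a slightly shrunk body
    zz, yy, xx = np.indices(spec.shape, dtype=np.float64)
    spine = (((yy - (cy + 0.30 * ny)) ** 2 + (xx - cx) ** 2) <= (0.05 * nx * nx * 0.05)) & body
    shell_out = _ellipsoid(spec.shape, (cz, cy, cx), tuple(a * 0.97 for a in body_semi))
    shell_in = _ellipsoid(spec.shape, (cz, cy, cx), tuple(a * 0.90 for a in body_semi))
    bands = (np.sin(zz / max(nz / 6.0, 1.0) * math.pi) > 0.2)
    ribs = shell_out & ~shell_in & bands
    bone = (spine | ribs) & body

    for name, organ in (("lungs", lung_l | lung_r), ("heart", heart)):
        if organ.any() and not (organ <= body).all():
            raise ValueError(f"phantom geometry error: {name} do not fit inside the body")

    hu = spec.hu
    vol = np.full(spec.shape, hu["air"], dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)
    # paint shallow -> deep so the deepest enclosing structure wins
    for mask, label, value in (
        (body, LABELS["body"], hu["body"]),
        (bone, LABELS["bone"], hu["bone"]),
        (lung_l, LABELS["lung_left"], hu["lung"]),
        (lung_r, LABELS["lung_right"], hu["lung"]),
        (heart, LABELS["heart"], hu["heart"]),
    ):
        vol[mask] = value
        labels[mask] = label

    if spec.tumor_radius > 0:
        center = spec.tumor_center or (cz, cy - 0.04 * ny, cx + 0.20 * nx)
        r = spec.tumor_radius
        tumor = _ellipsoid(spec.shape, center, (r, r, r))
        if not tumor.any():
            raise ValueError("phantom geometry error: tumor lies outside the volume")
        vol[tumor] = hu["tumor"]
        labels[tumor] = LABELS["tumor"]

    texture = rng.normal(0.0, spec.texture_sigma, size=spec.shape)
    vol = np.where(labels > 0, vol + texture, vol)
    return Volume3D(vol, spacing=spec.spacing, origin=(0.0, 0.0, 0.0), scale_tag="hu"), labels


def _streak_field(shape, spec: DegradationSpec, rng) -> np.ndarray:
    """In-plane radial streak pattern: narrow angular rays of alternating sign,
    shared across axial slices (cone-beam streaks are roughly axially coherent)."""
    nz, ny, nx = shape
    yy, xx = np.indices((ny, nx), dtype=np.float64)
    phi = np.arctan2(yy - ny / 2.0, xx - nx / 2.0)
    pattern = np.zeros((ny, nx))
    width = 0.03  # radians
    for i in range(spec.streak_count):
        theta = rng.uniform(-math.pi, math.pi)
        sign = 1.0 if i % 2 == 0 else -1.0
        d = np.angle(np.exp(1j * (phi - theta)))
        pattern += sign * np.exp(-(d * d) / (2 * width * width))
    return np.broadcast_to(pattern * spec.streak_amplitude, shape).copy()


def degrade_to_cbct(ct: Volume3D, spec: DegradationSpec | None = None) -> Volume3D:
    """Apply the CBCT-like degradation chain, in order: HU miscalibration
    (scale then shift), radial streaks, Gaussian blur, additive noise,
    optional smooth deformation.  Deterministic given ``spec.seed``."""
    spec = spec or DegradationSpec()
    rng = np.random.default_rng(spec.seed)
    out = ct.data * spec.hu_scale + spec.hu_shift

    if spec.streak_amplitude > 0 and spec.streak_count > 0:
        out = out + _streak_field(ct.shape, spec, rng)

    if spec.blur_sigma > 0:
        sigma_vox = [spec.blur_sigma / ct.spacing[2],  # z
                     spec.blur_sigma / ct.spacing[1],  # y
                     spec.blur_sigma / ct.spacing[0]]  # x
        out = ndimage.gaussian_filter(out, sigma=sigma_vox)

    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=ct.shape)

    if spec.deform_amplitude > 0:
        coarse = [4, 6, 6]
        zz, yy, xx = np.indices(ct.shape, dtype=np.float64)
        coords = [zz, yy, xx]
        sp_zyx = ct.spacing[::-1]
        for a in range(3):
            low = rng.normal(0.0, 1.0, size=coarse)
            disp = ndimage.zoom(low, [ct.shape[i] / coarse[i] for i in range(3)], order=3)
            peak = np.abs(disp).max() or 1.0
            coords[a] = coords[a] + disp / peak * (spec.deform_amplitude / sp_zyx[a])
        out = ndimage.map_coordinates(out, coords, order=1, mode="nearest")

    return Volume3D(out, spacing=ct.spacing, origin=ct.origin, scale_tag="hu")


def make_dataset(n_patients: int, out_dir, scans_per_patient: tuple = (1, 2),
                 phantom_spec: PhantomSpec | None = None,
                 degradation_spec: DegradationSpec | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Write a small synthetic cohort plus one held-out phantom pair.

    Per patient: ``scans_per_patient = (n_ct, n_cbct)`` volumes with dates
    laid out so the weak-pair procedure sees both qualifying (<= 1 day) and
    non-qualifying (> 1 day) CBCTs.  Emits a metadata CSV with columns
    patient_id, modality, date, path (the dataset_prep interface) and
    returns it as a DataFrame.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise IOError(f"parent of output directory {out_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)

    base = phantom_spec or PhantomSpec()
    deg = degradation_spec or DegradationSpec()
    rng = np.random.default_rng(seed)
    base_date = np.datetime64("2021-01-04")
    n_ct, n_cbct = scans_per_patient
    rows = []

    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        scale = float(np.clip(rng.normal(1.0, 0.03), 0.9, 1.1))
        pspec = replace(base, organ_scale=scale, seed=int(rng.integers(2 ** 31)))
        ct, _ = make_phantom_ct(pspec)
        day0 = base_date + np.timedelta64(7 * p, "D")
        for i in range(n_ct):
            path = out_dir / f"{pid}_ct_{i}.nii.gz"
            write_volume(ct, path)
            rows.append((pid, "CT", str(day0 + np.timedelta64(3 * i, "D")), str(path)))
        # CBCT day offsets: first within one day of the CT, later ones beyond
        offsets = [1 if j == 0 else 2 + 3 * j for j in range(n_cbct)]
        for j, off in enumerate(offsets):
            dspec = replace(deg, seed=int(rng.integers(2 ** 31)))
            cbct = degrade_to_cbct(ct, dspec)
            path = out_dir / f"{pid}_cbct_{j}.nii.gz"
            write_volume(cbct, path)
            rows.append((pid, "CBCT", str(day0 + np.timedelta64(off, "D")), str(path)))

    # held-out phantom pair, same acquisition day
    ph_spec = replace(base, seed=int(rng.integers(2 ** 31)))
    ph_ct, _ = make_phantom_ct(ph_spec)
    ph_cbct = degrade_to_cbct(ph_ct, replace(deg, seed=int(rng.integers(2 ** 31))))
    ct_path = out_dir / "phantom_ct.nii.gz"
    cbct_path = out_dir / "phantom_cbct.nii.gz"
    write_volume(ph_ct, ct_path)
    write_volume(ph_cbct, cbct_path)
    ph_day = str(base_date + np.timedelta64(365, "D"))
    rows.append(("phantom", "CT", ph_day, str(ct_path)))
    rows.append(("phantom", "CBCT", ph_day, str(cbct_path)))

    df = pd.DataFrame(rows, columns=["patient_id", "modality", "date", "path"])
    df.to_csv(out_dir / "metadata.csv", index=False)
    return df
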