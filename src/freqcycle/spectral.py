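"""Generalized frequency representation and frequency structure loss.

The structure loss at the core of this toolkit compares two volumes in the
frequency domain: each volume is mapped to the centred magnitude of its
orthonormal 3D DFT, compressed by tanh into [0, 1), and the loss is the
elementwise L1 (or squared L2) difference of the two representations.
Because the magnitude spectrum is invariant to circular spatial translation,
the loss constrains image *content* without demanding voxelwise spatial
correspondence — which is what makes it usable on unpaired data.

Two DFT scaling conventions are available:

- ``"ortho"`` (default): 1/sqrt(L*M*N), the unitary DFT (Parseval holds);
- ``"forward"``: 1/(L*M*N), the plain forward-normalised DFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume3D

__all__ = [
    "SpectralRepresentation",
    "orthonormal_dft3d",
    "frequency_representation",
    "frequency_distance",
]

_CONVENTIONS = ("ortho", "forward")


def _as_array(vol) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    if data.size == 0 or any(n < 1 for n in data.shape):
        raise ValueError("volume must have at least one voxel per axis")
    return np.asarray(data, dtype=np.float64)


@dataclass(frozen=True)
class SpectralRepresentation:
    """tanh-compressed centred magnitude spectrum of a volume.

    ``rep`` has the same shape as the source volume and every element lies
    in [0, 1) mathematically (tanh of a finite non-negative magnitude);
    in floating point, magnitudes above ~19 saturate to exactly 1.0.
    """

    rep: np.ndarray
    shape: tuple
    convention_tag: str


def orthonormal_dft3d(vol, convention: str = "ortho") -> np.ndarray:
    """Full complex 3D DFT, scaled and cyclically shifted so the
    zero-frequency component sits at index (L//2, M//2, N//2).
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    data = _as_array(vol)
    spec = np.fft.fftn(data, norm=convention)
    return np.fft.fftshift(spec)


def frequency_representation(vol, convention: str = "ortho") -> SpectralRepresentation:
    """rep = tanh(|centred scaled DFT|); phase is discarded entirely."""
    spec = orthonormal_dft3d(vol, convention=convention)
    rep = np.tanh(np.abs(spec))
    return SpectralRepresentation(rep=rep, shape=rep.shape, convention_tag=convention)


def frequency_distance(a, b, norm: str = "l1", reduction: str = "sum",
                       convention: str = "ortho") -> float:
    """Distance between the frequency representations of two volumes.

    ``norm="l1"`` returns sum |rep_a - rep_b| (the canonical structure
    loss when ``reduction="sum"``); ``norm="l2"`` returns the sum of
    squared differences.  ``reduction="mean"`` divides by the voxel count.
    The result is non-negative and symmetric in (a, b).
    """
    if norm not in ("l1", "l2"):
        raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
    if reduction not in ("sum", "mean"):
        raise ValueError(f"reduction must be 'sum' or 'mean', got {reduction!r}")
    da, db = _as_array(a), _as_array(b)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch: {da.shape} vs {db.shape}")
    ra = frequency_representation(da, convention=convention).rep
    rb = frequency_representation(db, convention=convention).rep
    diff = ra - rb
    val = np.abs(diff).sum() if norm == "l1" else (diff * diff).sum()
    if reduction == "mean":
        val /= da.size
    return float(val)
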