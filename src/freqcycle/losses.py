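"""CycleGAN training objective: adversarial, cycle-consistency and
frequency structure terms.

The combined objective minimised by the generators is

    L = L_adv(G, D_Y) + L_adv(F, D_X)
        + lambda_A * ||F(G(x)) - x||_1 + lambda_B * ||G(F(y)) - y||_1
        + lambda_fA * d(G(x), x) + lambda_fB * d(F(y), y)

where d is the frequency structure loss (see :mod:`freqcycle.spectral`).
With lambda_fA = lambda_fB = 0 this reduces exactly to the plain CycleGAN
objective.

Every function here accepts either plain numpy arrays / Volume3D (returning
floats) or autodiff ``Tensor`` inputs (returning a differentiable Tensor),
so the same definitions serve both evaluation and training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .nn.functional import frequency_representation_t
from .spectral import frequency_distance
from .volume import Volume3D

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "adversarial_loss",
    "cycle_consistency_loss",
    "total_objective",
    "structure_loss_interface",
    "STRUCTURE_LOSSES",
]

STRUCTURE_LOSSES = ("none", "frequency_l1", "frequency_l2")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective; defaults follow the published recipe
    (cycle lambdas 5, frequency lambdas 5)."""

    lambda_A: float = 5.0
    lambda_B: float = 5.0
    lambda_fA: float = 5.0
    lambda_fB: float = 5.0

    def __post_init__(self):
        for name in ("lambda_A", "lambda_B", "lambda_fA", "lambda_fB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    """Raw loss terms plus the weighted total of one optimisation step."""

    adv_G: float
    adv_F: float
    cycle_A: float
    cycle_B: float
    freq_A: float
    freq_B: float
    total: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("adv_G", "adv_F", "cycle_A", "cycle_B", "freq_A", "freq_B", "total")}


def _values(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    if isinstance(x, Volume3D):
        return x.data
    return np.asarray(x, dtype=np.float64)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _mean(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def adversarial_loss(d_real, d_fake, variant: str = "least_squares", side: str = "discriminator"):
    """Adversarial loss over discriminator score grids, as a minimised quantity.

    - ``vanilla``/discriminator: -mean(log d_real) - mean(log(1 - d_fake))
      (negated log-likelihood of the classic GAN objective);
    - ``vanilla``/generator: -mean(log d_fake), the non-saturating form;
    - ``least_squares``/discriminator: mean((d_real - 1)^2) + mean(d_fake^2);
    - ``least_squares``/generator: mean((d_fake - 1)^2).

    The vanilla variant requires scores interpretable as probabilities in
    (0, 1); least squares accepts raw scores.
    """
    if variant not in ("vanilla", "least_squares"):
        raise ValueError(f"unknown adversarial variant {variant!r}")
    if side not in ("generator", "discriminator"):
        raise ValueError(f"side must be 'generator' or 'discriminator', got {side!r}")

    if variant == "vanilla":
        for name, scores in (("d_real", d_real), ("d_fake", d_fake)):
            if scores is None:
                continue
            v = _values(scores)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            if v.min() <= 0.0 or v.max() >= 1.0:
                raise ValueError(
                    f"vanilla adversarial loss needs {name} in the open interval (0, 1)"
                )

    if side == "generator":
        if d_fake is None:
            raise ValueError("generator side requires d_fake")
        if variant == "vanilla":
            return -_mean(_log(d_fake)) if _is_tensor(d_fake) else float(-np.mean(np.log(_values(d_fake))))
        diff = d_fake - 1.0 if _is_tensor(d_fake) else _values(d_fake) - 1.0
        return _mean(diff * diff)

    if d_real is None or d_fake is None:
        raise ValueError("discriminator side requires both d_real and d_fake")
    if variant == "vanilla":
        if _is_tensor(d_real, d_fake):
            return -_mean(_log(d_real)) - _mean(_log(1.0 - d_fake))
        return float(-np.mean(np.log(_values(d_real))) - np.mean(np.log(1.0 - _values(d_fake))))
    if _is_tensor(d_real, d_fake):
        dr = d_real - 1.0
        return _mean(dr * dr) + _mean(d_fake * d_fake)
    dr = _values(d_real) - 1.0
    df = _values(d_fake)
    return float(np.mean(dr * dr) + np.mean(df * df))


def cycle_consistency_loss(original, reconstructed):
    """Mean absolute difference between a volume and its two-hop reconstruction."""
    if _is_tensor(original, reconstructed):
        a = original if isinstance(original, Tensor) else Tensor(_values(original))
        b = reconstructed if isinstance(reconstructed, Tensor) else Tensor(_values(reconstructed))
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        return (a - b).abs().mean()
    a, b = _values(original), _values(reconstructed)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def total_objective(adv_G, adv_F, cycle_A, cycle_B, freq_A, freq_B,
                    weights: LossWeights) -> LossBreakdown:
    """Weighted sum of the six raw loss terms.

    total = adv_G + adv_F + lambda_A*cycle_A + lambda_B*cycle_B
            + lambda_fA*freq_A + lambda_fB*freq_B

    With the frequency lambdas at 0 this is exactly the plain CycleGAN
    objective.  Raises on any non-finite part, naming the offending term.
    """
    parts = {"adv_G": adv_G, "adv_F": adv_F, "cycle_A": cycle_A,
             "cycle_B": cycle_B, "freq_A": freq_A, "freq_B": freq_B}
    vals = {}
    for name, p in parts.items():
        v = float(p.item()) if isinstance(p, Tensor) else float(p)
        if not math.isfinite(v):
            raise ValueError(f"non-finite loss term {name!r}: {v}")
        vals[name] = v
    total = (vals["adv_G"] + vals["adv_F"]
             + weights.lambda_A * vals["cycle_A"] + weights.lambda_B * vals["cycle_B"]
             + weights.lambda_fA * vals["freq_A"] + weights.lambda_fB * vals["freq_B"])
    return LossBreakdown(total=total, **vals)


def structure_loss_interface(name: str, a, b, convention: str = "ortho"):
    """Pluggable structure loss between a generator's input and its translation.

    ``none`` is the baseline CycleGAN (always 0); ``frequency_l1`` /
    ``frequency_l2`` are the frequency structure loss with the matching norm
    and sum reduction.  Tensor inputs yield a differentiable result.
    """
    if name not in STRUCTURE_LOSSES:
        raise ValueError(f"unknown structure loss {name!r}; choose from {STRUCTURE_LOSSES}")
    if name == "none":
        return 0.0
    norm = "l1" if name == "frequency_l1" else "l2"
    if _is_tensor(a, b):
        ta = a if isinstance(a, Tensor) else Tensor(_values(a))
        tb = b if isinstance(b, Tensor) else Tensor(_values(b))
        if ta.shape != tb.shape:
            raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
        diff = frequency_representation_t(ta, convention) - frequency_representation_t(tb, convention)
        return diff.abs().sum() if norm == "l1" else (diff * diff).sum()
    da, db = _values(a), _values(b)
    return frequency_distance(da, db, norm=norm, reduction="sum", convention=convention)
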