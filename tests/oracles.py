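"""Independent brute-force oracles used by the test suite.

The naive DFT here is written from the definition (explicit loops over the
output frequencies, direct summation over the input grid) so it shares no
code path with the FFT-based implementation it checks.
"""

import numpy as np


def naive_dft3d(data: np.ndarray, convention: str = "ortho") -> np.ndarray:
    """Triple-sum 3D DFT with centred zero frequency.

    F(u,v,w) = scale * sum_{x,y,z} I(x,y,z) exp(-2*pi*i*(ux/L + vy/M + wz/N)),
    cyclically shifted so the zero-frequency bin sits at (L//2, M//2, N//2).
    """
    L, M, N = data.shape
    if convention == "ortho":
        scale = 1.0 / np.sqrt(L * M * N)
    elif convention == "forward":
        scale = 1.0 / (L * M * N)
    else:
        raise ValueError(convention)
    x = np.arange(L)
    y = np.arange(M)
    z = np.arange(N)
    out = np.zeros((L, M, N), dtype=complex)
    for u in range(L):
        for v in range(M):
            for w in range(N):
                phase = (u * x[:, None, None] / L
                         + v * y[None, :, None] / M
                         + w * z[None, None, :] / N)
                out[u, v, w] = scale * np.sum(data * np.exp(-2j * np.pi * phase))
    # shift: frequency k moves to index k + n//2 (mod n) per axis
    shifted = np.zeros_like(out)
    for u in range(L):
        for v in range(M):
            for w in range(N):
                shifted[(u + L // 2) % L, (v + M // 2) % M, (w + N // 2) % N] = out[u, v, w]
    return shifted


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
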