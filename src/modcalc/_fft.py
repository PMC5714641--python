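"""Padded frequency-space convolution and regularized deconvolution.

Kernels are small 2D arrays centered on their middle pixel. Convolution is
linear (zero-padded, "same" output). Deconvolution divides in frequency
space; spectral components where the kernel transfer function falls below a
relative threshold are set to zero rather than amplified.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len, rfft2, irfft2

DEFAULT_EPS_REL = 1e-3


def _padded_transfer(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    kh, kw = kernel.shape
    ky, kx = kh // 2, kw // 2
    pad = np.zeros(shape)
    pad[:kh, :kw] = kernel
    pad = np.roll(pad, (-ky, -kx), axis=(0, 1))  # kernel center at index (0, 0)
    return rfft2(pad)


def _fft_shapes(shape, kshape):
    return tuple(next_fast_len(n + k - 1) for n, k in zip(shape, kshape))


def convolve2d_same(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if not np.any(kernel):
        raise ValueError("all-zero kernel")
    full = _fft_shapes(values.shape, kernel.shape)
    K = _padded_transfer(kernel, full)
    pad = np.zeros(full)
    pad[: values.shape[0], : values.shape[1]] = values
    out = irfft2(rfft2(pad) * K, s=full)
    return out[: values.shape[0], : values.shape[1]]


def deconvolve2d_same(values: np.ndarray, kernel: np.ndarray,
                      eps_rel: float = DEFAULT_EPS_REL) -> np.ndarray:
    if not np.any(kernel):
        raise ValueError("all-zero kernel")
    full = _fft_shapes(values.shape, kernel.shape)
    K = _padded_transfer(kernel, full)
    keep = np.abs(K) > eps_rel * np.abs(K).max()
    pad = np.zeros(full)
    pad[: values.shape[0], : values.shape[1]] = values
    F = rfft2(pad)
    out_hat = np.where(keep, F / np.where(keep, K, 1.0), 0.0)
    out = irfft2(out_hat, s=full)
    return out[: values.shape[0], : values.shape[1]]
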