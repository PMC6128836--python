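"""Origin-centred FFT helpers.

All images and volumes are stored with the real-space origin (and the DC
Fourier component) at the array centre voxel ``box // 2``.  These wrappers
hide the fftshift bookkeeping.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cfft2", "icfft2", "cfftn", "icfftn", "freq_grid_2d", "radius_grid"]


def cfft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))


def icfft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a)))


def cfftn(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def icfftn(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a)))


def freq_grid_2d(box: int, pixel_size: float):
    """Centred spatial-frequency grids (gy, gx) in 1/Angstrom for a box² image."""
    f = (np.arange(box) - box // 2) / (box * pixel_size)
    gy, gx = np.meshgrid(f, f, indexing="ij")
    return gy, gx


def radius_grid(shape) -> np.ndarray:
    """Voxel-frequency radius |k| on a centred grid of the given shape."""
    axes = [np.arange(n) - n // 2 for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m.astype(float) ** 2 for m in mesh))
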