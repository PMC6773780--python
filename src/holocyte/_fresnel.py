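"""Single-FFT Fresnel transform with centred coordinates.

The transform maps a field sampled at pitch dx over an N x N grid to the
observation plane a distance d away, with output pitch dxi = lambda*d/(N*dx):

    U2(m,n) = exp[i pi (m^2 dxi^2 + n^2 deta^2)/(lambda d)]
              * F{ U1(k,l) * exp[i pi (k^2 dx^2 + l^2 dy^2)/(lambda d)] }

with k,l,m,n centred indices in [-N/2, N/2). The FFT is orthonormal and the
chirps have unit modulus, so the transform is unitary (energy-preserving)
and has an exact elementwise inverse.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fresnel_transform", "inverse_fresnel_transform", "quadratic_chirp"]


def quadratic_chirp(n: int, pitch_um: float, wavelength_um: float, d_um: float) -> np.ndarray:
    """exp[i pi (x^2 + y^2) / (lambda d)] on centred coordinates."""
    x = (np.arange(n) - n // 2) * pitch_um
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    return np.exp(1j * np.pi * r2 / (wavelength_um * d_um))


def _fft_centered(data: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(data), norm="ortho"))


def _ifft_centered(data: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(data), norm="ortho"))


def fresnel_transform(
    data: np.ndarray, pitch_in_um: float, wavelength_um: float, d_um: float
) -> tuple[np.ndarray, float]:
    """Propagate ``data`` over distance ``d_um``; returns (field, output pitch)."""
    if d_um == 0:
        return data.copy(), pitch_in_um
    n = data.shape[0]
    pitch_out = wavelength_um * abs(d_um) / (n * pitch_in_um)
    chirp_in = quadratic_chirp(n, pitch_in_um, wavelength_um, d_um)
    chirp_out = quadratic_chirp(n, pitch_out, wavelength_um, d_um)
    out = chirp_out * _fft_centered(data * chirp_in)
    return out, pitch_out


def inverse_fresnel_transform(
    data: np.ndarray, pitch_in_um: float, wavelength_um: float, d_um: float
) -> tuple[np.ndarray, float]:
    """Exact inverse of :func:`fresnel_transform` at the same distance.

    ``pitch_in_um`` is the pitch of ``data`` (the observation plane); the
    returned pitch is the source-plane pitch lambda*d/(N*pitch_in).
    """
    if d_um == 0:
        return data.copy(), pitch_in_um
    n = data.shape[0]
    pitch_out = wavelength_um * abs(d_um) / (n * pitch_in_um)
    chirp_obs = quadratic_chirp(n, pitch_in_um, wavelength_um, d_um)
    chirp_src = quadratic_chirp(n, pitch_out, wavelength_um, d_um)
    out = np.conj(chirp_src) * _ifft_centered(data * np.conj(chirp_obs))
    return out, pitch_out
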