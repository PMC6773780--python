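"""Off-axis hologram formation from an OPD map.

An OPD map is turned into a unit-amplitude phase object O = exp(i 2pi OPD /
lambda), interfered with a tilted plane reference wave R, and recorded as
the intensity I_H = |R + O|^2 = |R|^2 + |O|^2 + R*O + O*R. The reference
tilt is chosen so the real-image term R*O appears at positive spatial
frequency; by default the sideband sits at the (N/4, N/4) frequency bins —
maximal separation from the DC term while keeping its bandwidth inside the
Nyquist square. Optional Fresnel propagation places the object out of
focus, and a simple camera model adds Gaussian or Poisson noise and
bit-depth quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._fresnel import inverse_fresnel_transform

__all__ = [
    "NoiseModel",
    "OpticalConfig",
    "ComplexField",
    "Hologram",
    "object_wave",
    "reference_wave",
    "propagate",
    "record_hologram",
    "DEFAULT_CAMERA_NOISE",
]


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: ``gaussian`` (sigma = sigma_frac * max intensity) or
    ``poisson`` (photon scale = expected counts at unit intensity)."""

    kind: str = "gaussian"
    sigma_frac: float = 0.02
    poisson_scale: float = 1e4

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ValueError("noise kind must be 'gaussian' or 'poisson'")


DEFAULT_CAMERA_NOISE = NoiseModel(kind="gaussian", sigma_frac=0.02)


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry of the simulated microscope.

    ``tilt_kx``/``tilt_ky`` are dimensionless wave-vector fractions of the
    reference beam; ``None`` selects the default placing the sideband at
    the (N/4, N/4) frequency bins. ``prop_distance_um`` is the
    camera-to-object reconstruction distance (0 = in-focus recording).
    """

    wavelength_nm: float = 666.0
    pixel_pitch_um: float = 0.09
    tilt_kx: float | None = None
    tilt_ky: float | None = None
    prop_distance_um: float = 0.0
    bit_depth: int = 12
    noise_model: NoiseModel | None = None
    quantize: bool = False

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not 1 <= self.bit_depth <= 32:
            raise ValueError("bit_depth must be in [1, 32]")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / 1000.0

    def resolved_tilt(self) -> tuple[float, float]:
        """Tilt components, substituting the N/4-bin default where unset."""
        default = self.wavelength_um / (4.0 * self.pixel_pitch_um)
        kx = default if self.tilt_kx is None else self.tilt_kx
        ky = default if self.tilt_ky is None else self.tilt_ky
        return kx, ky

    def fringe_freq_cpp(self) -> tuple[float, float]:
        """Carrier frequency in cycles per pixel (x, y)."""
        kx, ky = self.resolved_tilt()
        return (
            kx * self.pixel_pitch_um / self.wavelength_um,
            ky * self.pixel_pitch_um / self.wavelength_um,
        )


@dataclass
class ComplexField:
    """Complex wavefront on a square grid with sampling metadata."""

    data: np.ndarray
    pixel_pitch_um: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("field grid must be square")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("field contains non-finite entries")

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class Hologram:
    """Recorded intensity frame plus the optical configuration snapshot."""

    data: np.ndarray
    config: OpticalConfig
    clipped_px: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("hologram intensity must be non-negative")


def object_wave(opd_nm: np.ndarray, cfg: OpticalConfig) -> ComplexField:
    """Unit-amplitude phase object exp(i 2pi OPD / lambda)."""
    opd = np.asarray(opd_nm, dtype=float)
    if not np.all(np.isfinite(opd)):
        raise ValueError("OPD map contains non-finite values")
    phase = 2.0 * np.pi * opd / cfg.wavelength_nm
    return ComplexField(np.exp(1j * phase), cfg.pixel_pitch_um, cfg.wavelength_nm)


def _tilt_ramp(shape: tuple[int, int], cfg: OpticalConfig) -> np.ndarray:
    kx, ky = cfg.resolved_tilt()
    x = np.arange(shape[1]) * cfg.pixel_pitch_um
    y = np.arange(shape[0]) * cfg.pixel_pitch_um
    return (2.0 * np.pi / cfg.wavelength_um) * (kx * x[None, :] + ky * y[:, None])


def reference_wave(cfg: OpticalConfig, grid_shape: tuple[int, int]) -> ComplexField:
    """Unit-amplitude plane reference wave.

    Sign convention: R = exp(-i * ramp) so that the real-image term R*O of
    the recorded hologram carries the +ramp phase, i.e. the sideband lands
    at positive frequency. The digital reference replica R_D used during
    demodulation is this same wave.
    """
    fx, fy = cfg.fringe_freq_cpp()
    if abs(fx) >= 0.5 or abs(fy) >= 0.5:
        raise ValueError(
            f"reference tilt puts the carrier at ({fx:.3f}, {fy:.3f}) cycles/px, "
            "outside the Nyquist square"
        )
    return ComplexField(
        np.exp(-1j * _tilt_ramp(grid_shape, cfg)), cfg.pixel_pitch_um, cfg.wavelength_nm
    )


def propagate(fieldobj: ComplexField, d_um: float) -> ComplexField:
    """Propagate a field by ``d_um`` (unitary single-FFT Fresnel transform).

    Defined as the exact inverse of the reconstruction-direction Fresnel
    transform at the same distance, so reconstructing a propagated field
    recovers the original. ``d_um = 0`` is the identity.
    """
    out, pitch = inverse_fresnel_transform(
        fieldobj.data, fieldobj.pixel_pitch_um, fieldobj.wavelength_nm / 1000.0, d_um
    )
    return ComplexField(out, pitch, fieldobj.wavelength_nm)


def record_hologram(
    obj: ComplexField,
    ref: ComplexField,
    cfg: OpticalConfig | None = None,
    seed: int | None = None,
) -> Hologram:
    """Interfere object and reference waves into an intensity frame.

    I_H = |R + O|^2, which expands to the four-term sum |R|^2 + |O|^2 +
    R*O + O*R. Camera noise and quantization are applied afterwards when
    enabled in the configuration; Gaussian noise is clipped at zero (the
    number of clipped pixels is recorded on the hologram).
    """
    if obj.data.shape != ref.data.shape:
        raise ValueError("object and reference grids differ")
    if cfg is None:
        cfg = OpticalConfig(
            wavelength_nm=obj.wavelength_nm, pixel_pitch_um=obj.pixel_pitch_um
        )
    intensity = np.abs(ref.data + obj.data) ** 2
    clipped = 0
    if cfg.noise_model is not None:
        rng = np.random.default_rng(seed)
        nm = cfg.noise_model
        if nm.kind == "gaussian":
            sigma = nm.sigma_frac * float(intensity.max())
            intensity = intensity + rng.normal(0.0, sigma, size=intensity.shape)
            clipped = int(np.count_nonzero(intensity < 0))
            intensity = np.clip(intensity, 0.0, None)
        else:  # poisson
            intensity = rng.poisson(intensity * nm.poisson_scale).astype(float)
            intensity /= nm.poisson_scale
    if cfg.quantize or cfg.noise_model is not None:
        levels = 2**cfg.bit_depth - 1
        peak = float(intensity.max())
        if peak > 0:
            intensity = np.round(intensity / peak * levels) / levels * peak
    return Hologram(intensity, replace(cfg), clipped_px=clipped, noise_seed=seed)
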