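"""Centered Fourier spectra, their log-amplitude, and filter reconstruction.

All detection and restoration happens on LogF, the natural log of the
centered amplitude spectrum; phase is never touched. Multiplying the complex
spectrum by the real filter image Phi scales amplitude only, and the
restored/noise images come back through the inverse FFT. Because the source
image is real, the amplitude spectrum is centrosymmetric about the DC pixel;
Phi is symmetrized (min of each reflected pair) before reconstruction so the
filtered spectrum stays Hermitian and both outputs stay real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import HeightImage

__all__ = [
    "CenteredSpectrum",
    "LogF",
    "PhiImage",
    "forward_spectrum",
    "log_amplitude",
    "symmetrize_phi",
    "synthesize_images",
]

#: relative amplitude floor substituted before taking the log
AMPLITUDE_FLOOR_FRAC = 1e-12


@dataclass
class CenteredSpectrum:
    """Complex 2D spectrum with the zero-frequency pixel at the center.

    ``dc`` is ``(rows // 2, cols // 2)`` after the quadrant swap.
    """

    values: np.ndarray
    dc: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LogF:
    """Natural log of the centered amplitude spectrum.

    ``floor`` records the amplitude substituted for near-zero entries so no
    value is -Inf.
    """

    values: np.ndarray
    floor: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def dc(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


@dataclass
class PhiImage:
    """Per-pixel spectral attenuation ratio exp(S') / exp(S), in (0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals <= 0.0) or np.any(vals > 1.0 + 1e-12):
            raise ValueError("Phi values must lie in (0, 1]")
        self.values = vals


def forward_spectrum(image: HeightImage) -> CenteredSpectrum:
    """Unnormalized forward FFT with quadrants swapped so DC sits centrally."""
    values = np.fft.fftshift(np.fft.fft2(image.data))
    rows, cols = values.shape
    return CenteredSpectrum(values, (rows // 2, cols // 2))


def log_amplitude(spec: CenteredSpectrum) -> LogF:
    """Elementwise ln of the amplitude, floored at 1e-12 x the peak amplitude.

    Raises on an all-zero spectrum (i.e. an all-zero image).
    """
    amp = np.abs(spec.values)
    peak = float(amp.max())
    if peak == 0.0:
        raise ValueError("empty image: all-zero spectrum has no log-amplitude")
    floor = AMPLITUDE_FLOOR_FRAC * peak
    return LogF(np.log(np.maximum(amp, floor)), floor=floor)


def reflect_index(
    p: tuple[int, int], dc: tuple[int, int], shape: tuple[int, int]
) -> tuple[int, int]:
    """Negated-frequency partner of a shifted-grid index, modulo the grid.

    The discrete frequency grid is periodic, so the partner of the Nyquist
    row/column of an even dimension wraps back onto itself; every pixel
    therefore has a partner inside the grid (possibly itself).
    """
    return ((2 * dc[0] - p[0]) % shape[0], (2 * dc[1] - p[1]) % shape[1])


def symmetrize_phi(phi: PhiImage, dc: tuple[int, int]) -> PhiImage:
    """Enforce centrosymmetry by taking the min over each reflected pair.

    Reflection is point reflection through the DC pixel, modulo the grid
    (the Nyquist row/column of an even dimension is its own mirror line), so
    the filtered spectrum of a real image stays Hermitian everywhere. The
    min is the conservative choice: a pixel never keeps more amplitude than
    either half of the pair detected as clean. Idempotent.
    """
    vals = phi.values
    rows, cols = vals.shape
    ri = (2 * dc[0] - np.arange(rows)) % rows
    rj = (2 * dc[1] - np.arange(cols)) % cols
    out = np.minimum(vals, vals[np.ix_(ri, rj)])
    return PhiImage(out)


def synthesize_images(
    spec: CenteredSpectrum, phi: PhiImage
) -> tuple[HeightImage, HeightImage]:
    """Split the raw image into restored and noise parts through Phi.

    restored = Re IFFT(F * Phi), noise = Re IFFT(F * (1 - Phi)); by linearity
    restored + noise reproduces the raw image exactly. ``phi`` must already be
    symmetrized or the inverse transforms acquire an imaginary residue, which
    is checked and rejected.
    """
    raw = np.fft.ifft2(np.fft.ifftshift(spec.values))
    scale = float(np.abs(raw).max())
    restored_c = np.fft.ifft2(np.fft.ifftshift(spec.values * phi.values))
    noise_c = np.fft.ifft2(np.fft.ifftshift(spec.values * (1.0 - phi.values)))
    tol = 1e-8 * max(scale, 1e-300)
    residue = max(float(np.abs(restored_c.imag).max()), float(np.abs(noise_c.imag).max()))
    if residue > tol:
        raise ValueError(
            f"asymmetric filter: imaginary residue {residue:.3e} exceeds {tol:.3e}"
        )
    restored = HeightImage(restored_c.real)
    noise = HeightImage(noise_c.real)
    return restored, noise
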