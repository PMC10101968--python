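"""Digital holography layer: angular-spectrum propagation, Tamura-based
autofocusing, and off-axis hologram synthesis/demodulation.

These are the optical computations sitting upstream of the phase maps in
a real off-axis holographic microscope. The implementation covers exactly
what round-trip testing needs: an interference pattern |O + R|² with a
tilted plane reference can be demodulated back to the object field by
selecting the +1 diffraction order in the Fourier spectrum, numerically
refocused by minimizing the Tamura coefficient of the amplitude along z,
and its argument taken as the phase map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_PITCH_UM, DEFAULT_WAVELENGTH_UM


@dataclass
class ComplexField:
    """Sampled complex optical field on a square grid."""

    values: np.ndarray
    pixel_pitch: float = DEFAULT_PITCH_UM
    wavelength: float = DEFAULT_WAVELENGTH_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"field must be square 2D, got {self.values.shape}")
        if self.values.shape[0] < 16:
            raise ValueError("field must be at least 16x16 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("field contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def energy(self) -> float:
        return float((self.amplitude**2).sum())


@dataclass
class Hologram:
    """Off-axis intensity interferogram with a known carrier frequency."""

    intensity: np.ndarray
    carrier: tuple[float, float]  # cycles/pixel along the two axes
    pixel_pitch: float = DEFAULT_PITCH_UM
    wavelength: float = DEFAULT_WAVELENGTH_UM

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if (self.intensity < 0).any():
            raise ValueError("hologram intensity must be non-negative")
        mag = math.hypot(*self.carrier)
        if not 0.0 < mag < 0.5:
            raise ValueError(
                f"carrier magnitude {mag:.3f} must be sub-Nyquist (0, 0.5) cycles/px"
            )


def propagate_angular_spectrum(field: ComplexField, distance_um: float) -> ComplexField:
    """Exact angular-spectrum transfer over ``distance_um``.

    Evanescent components (spatial frequencies beyond 1/λ) are suppressed;
    over the propagating band the transfer is unitary, so energy is
    conserved and propagation by +d then −d is the identity.
    """
    if not math.isfinite(distance_um):
        raise ValueError("propagation distance must be finite")
    n = field.values.shape[0]
    f = np.fft.fftfreq(n, d=field.pixel_pitch)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    arg = 1.0 / field.wavelength**2 - fx**2 - fy**2
    propagating = arg > 0
    kz = np.zeros_like(arg)
    kz[propagating] = 2.0 * np.pi * np.sqrt(arg[propagating])
    transfer = np.where(propagating, np.exp(1j * kz * distance_um), 0.0)
    spectrum = np.fft.fft2(field.values)
    out = np.fft.ifft2(spectrum * transfer)
    return ComplexField(out, field.pixel_pitch, field.wavelength)


def tamura_coefficient(amplitude_image: np.ndarray) -> float:
    """TC = sqrt(std(A)/mean(A)) of a non-negative amplitude image.

    Scale-invariant contrast measure; minimized at best focus for pure
    phase objects, whose in-focus amplitude is flat.
    """
    a = np.asarray(amplitude_image, dtype=np.float64)
    if (a < 0).any():
        raise ValueError("amplitude must be non-negative")
    mean = a.mean()
    if mean == 0:
        raise ValueError("all-zero amplitude image: Tamura coefficient undefined")
    return float(np.sqrt(a.std() / mean))


def autofocus(
    field: ComplexField,
    z_min: float,
    z_max: float,
    n_steps: int = 41,
) -> tuple[float, ComplexField]:
    """Find the refocusing distance minimizing the Tamura coefficient.

    Coarse grid search over ``n_steps`` distances followed by a 3-point
    parabolic refinement around the grid minimum.
    """
    if not z_min < z_max:
        raise ValueError("need z_min < z_max")
    if n_steps < 3:
        raise ValueError("need at least 3 search steps")
    zs = np.linspace(z_min, z_max, n_steps)
    tcs = np.empty(n_steps)
    for i, z in enumerate(zs):
        tcs[i] = tamura_coefficient(
            propagate_angular_spectrum(field, float(z)).amplitude
        )
        if not math.isfinite(tcs[i]):
            raise ValueError(f"non-finite Tamura coefficient at z = {zs[i]:.3g} µm")
    if tcs.max() - tcs.min() < 1e-12:
        raise ValueError("flat focus profile: no minimum (degenerate field)")
    k = int(np.argmin(tcs))
    z_focus = float(zs[k])
    if 0 < k < n_steps - 1:
        y0, y1, y2 = tcs[k - 1 : k + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            z_focus += 0.5 * (y0 - y2) / denom * (zs[1] - zs[0])
    return z_focus, propagate_angular_spectrum(field, z_focus)


def synthesize_offaxis_hologram(
    object_field: ComplexField, reference_carrier: tuple[float, float]
) -> Hologram:
    """Interference |O + R|² with a unit-amplitude tilted plane reference."""
    mag = math.hypot(*reference_carrier)
    if not 0.0 < mag < 0.5:
        raise ValueError(
            f"carrier magnitude {mag:.3f} must be sub-Nyquist (0, 0.5) cycles/px"
        )
    n = object_field.values.shape[0]
    x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ref = np.exp(2j * np.pi * (reference_carrier[0] * x + reference_carrier[1] * y))
    intensity = np.abs(object_field.values + ref) ** 2
    return Hologram(
        intensity,
        tuple(reference_carrier),
        object_field.pixel_pitch,
        object_field.wavelength,
    )


def demodulate(hologram: Hologram, bandpass_radius: float) -> ComplexField:
    """Recover the object field from the +1 diffraction order.

    A hard circular band-pass of ``bandpass_radius`` (cycles/pixel) is
    centered on the carrier in the Fourier spectrum, and the passband is
    translated back to baseband. The radius must stay below the carrier
    separation or the orders overlap.
    """
    mag = math.hypot(*hologram.carrier)
    if bandpass_radius >= mag:
        raise ValueError(
            f"bandpass radius {bandpass_radius} reaches the carrier separation "
            f"{mag:.3f}: diffraction orders overlap"
        )
    n = hologram.intensity.shape[0]
    spectrum = np.fft.fft2(hologram.intensity)
    f = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    # the O·R̄ term carries the object spectrum shifted by −carrier;
    # select it there on the periodic frequency torus
    dx = (fx + hologram.carrier[0] + 0.5) % 1.0 - 0.5
    dy = (fy + hologram.carrier[1] + 0.5) % 1.0 - 0.5
    mask = dx**2 + dy**2 <= bandpass_radius**2
    filtered = np.where(mask, spectrum, 0.0)
    sideband = np.fft.ifft2(filtered)
    # remodulate the sideband back to baseband
    x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    demod = sideband * np.exp(
        2j * np.pi * (hologram.carrier[0] * x + hologram.carrier[1] * y)
    )
    return ComplexField(demod, hologram.pixel_pitch, hologram.wavelength)
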