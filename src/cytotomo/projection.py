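"""Straight-ray forward model: RI tomogram → quantitative phase maps.

A cell rolling in the microfluidic channel rotates about the x-axis while
the optical axis is z. Under the straight-ray (projection) approximation
the phase delay at rolling angle θ is

    φ_θ(x, y) = (2π/λ) · Σ_z Δn_θ(x, y, z) · voxel_pitch,

where Δn_θ is the RI contrast of the volume rotated by θ about x. This is
the same light-propagation model the filtered-back-projection inverse
assumes, and the 0° projection is the 2D baseline image used to compare
2D-feature against 3D-feature classification.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import DEFAULT_WAVELENGTH_UM, QPM, RITomogram


def rotate_volume(tomogram: RITomogram, angle_deg: float) -> RITomogram:
    """Rotate a tomogram about the x-axis through the exact volume center.

    Trilinear interpolation; voxels rotated in from outside the box are
    filled with the medium RI n0.
    """
    if not math.isfinite(angle_deg):
        raise ValueError(f"rotation angle must be finite, got {angle_deg}")
    if angle_deg % 360.0 == 0.0:
        return tomogram.copy()
    delta = tomogram.delta_n
    support = delta > 0
    if not support.any():
        return tomogram.copy()

    # restrict work to the region the support can sweep: rotation about x
    # never moves voxels in x and preserves the (y, z) radius from the
    # center, so a center-symmetric (y, z) crop containing the support
    # circle together with the support's x-range is angle-invariant
    nx, ny, nz = delta.shape
    coords = np.argwhere(support)
    x_lo, x_hi = int(coords[:, 0].min()), int(coords[:, 0].max()) + 1
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    radius = np.sqrt(((coords[:, 1] - cy) ** 2 + (coords[:, 2] - cz) ** 2).max())
    my = max(0, int(np.floor(cy - radius - 2.0)))
    mz = max(0, int(np.floor(cz - radius - 2.0)))
    crop = (slice(x_lo, x_hi), slice(my, ny - my), slice(mz, nz - mz))

    rotated_crop = ndimage.rotate(
        delta[crop],
        angle_deg,
        axes=(1, 2),  # rotation in the (y, z) plane = about x
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    np.maximum(rotated_crop, 0.0, out=rotated_crop)  # clamp interpolation undershoot
    rotated = np.zeros_like(delta)
    rotated[crop] = rotated_crop
    return RITomogram(
        tomogram.n0 + rotated, voxel_pitch=tomogram.voxel_pitch, n0=tomogram.n0
    )


def project_qpm(
    tomogram: RITomogram,
    angle_deg: float,
    wavelength: float = DEFAULT_WAVELENGTH_UM,
) -> QPM:
    """Phase map of the volume rotated to ``angle_deg``, integrated along z."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    rotated = rotate_volume(tomogram, angle_deg)
    pitch = tomogram.voxel_pitch
    phase = (2.0 * np.pi / wavelength) * rotated.delta_n.sum(axis=2) * pitch
    return QPM(phase, pixel_pitch=pitch, wavelength=wavelength, angle_deg=angle_deg)


def project_sequence(
    tomogram: RITomogram,
    angles: Sequence[float],
    wavelength: float = DEFAULT_WAVELENGTH_UM,
) -> list[QPM]:
    """One QPM per rolling angle, order preserved.

    Equivalent to calling :func:`project_qpm` per angle, but the
    angle-invariant support crop is computed once for the whole sequence.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("angle list must be non-empty")
    if not all(math.isfinite(a) for a in angles):
        raise ValueError("all angles must be finite")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")

    delta = tomogram.delta_n
    support = delta > 0
    if not support.any():
        return [project_qpm(tomogram, a, wavelength) for a in angles]
    nx, ny, nz = delta.shape
    coords = np.argwhere(support)
    x_lo, x_hi = int(coords[:, 0].min()), int(coords[:, 0].max()) + 1
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    radius = np.sqrt(((coords[:, 1] - cy) ** 2 + (coords[:, 2] - cz) ** 2).max())
    my = max(0, int(np.floor(cy - radius - 2.0)))
    mz = max(0, int(np.floor(cz - radius - 2.0)))
    crop = delta[x_lo:x_hi, my : ny - my, mz : nz - mz]

    scale = 2.0 * np.pi / wavelength * tomogram.voxel_pitch
    out = []
    for a in angles:
        if a % 360.0 == 0.0:
            rotated = crop
        else:
            rotated = ndimage.rotate(
                crop,
                a,
                axes=(1, 2),
                reshape=False,
                order=1,
                mode="constant",
                cval=0.0,
                prefilter=False,
            )
            np.maximum(rotated, 0.0, out=rotated)
        phase = np.zeros((nx, ny))
        phase[x_lo:x_hi, my : ny - my] = scale * rotated.sum(axis=2)
        out.append(
            QPM(phase, pixel_pitch=tomogram.voxel_pitch, wavelength=wavelength, angle_deg=a)
        )
    return out
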