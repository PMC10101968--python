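"""Tomographic inversion: rolling-angle estimation, slice-wise filtered
back projection, and support segmentation.

A cell rolling with quasi-uniform angular speed about the x-axis yields a
QPM sequence that repeats after one full turn. The rotation period is
therefore estimated as the lag of the first strong maximum of the
frame-to-frame similarity with frame 0, and angles are assigned uniformly
as θ_k = 360·k/T. (Full holographic-tracking angle recovery from the
microfluidic model is deliberately replaced by this uniform-rotation
estimator.)

Reconstruction is classical filtered back projection, slice by slice
along the rotation axis: each x-slice of the QPM stack, rescaled from
phase to the line integral of Δn, forms a sinogram over the rolling
angles, which a ramp-filtered back projection inverts to Δn(y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .core import CellSupport, QPM, RITomogram


@dataclass
class AngleTrack:
    """Per-frame rolling angles (degrees, about x)."""

    angles_deg: np.ndarray
    frame_indices: np.ndarray
    estimated_period: float | None = None

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if not np.isfinite(self.angles_deg).all():
            raise ValueError("angles must be finite")
        if len(self.angles_deg) != len(self.frame_indices):
            raise ValueError("angles and frame indices differ in length")


class PeriodNotFoundError(RuntimeError):
    """Raised when the similarity profile shows no rotation signature."""

    def __init__(self, message: str, similarity: np.ndarray):
        super().__init__(message)
        self.similarity = similarity


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 1.0


def estimate_angles(
    qpm_sequence: list[QPM],
    t_min: int = 30,
    match_threshold: float = 0.995,
    dip_threshold: float = 0.9995,
) -> AngleTrack:
    """Estimate uniform rolling angles from the self-similarity of the stack.

    The period T is the lag (≥ ``t_min``) at which the Pearson similarity
    with frame 0 first re-enters a strong maximum (> ``match_threshold``);
    within that region the best-matching lag is taken. The threshold is
    deliberately strict: the projection half a turn away is the mirror of
    frame 0 and can correlate well above 0.9 for nearly symmetric cells,
    while the true full-turn match is essentially exact. A sequence whose
    similarity never leaves the immediate vicinity of 1 (below
    ``dip_threshold``) carries no rotation signature at all — frames of a
    spherically symmetric cell are identical — and is rejected.
    """
    n = len(qpm_sequence)
    if n < t_min + 1:
        raise ValueError(f"need more than t_min={t_min} frames, got {n}")
    ref = qpm_sequence[0].phase
    sim = np.array([_pearson(ref, q.phase) for q in qpm_sequence])
    if sim[1:].min() > dip_threshold:
        raise PeriodNotFoundError(
            "no rotation signature: similarity never leaves the maximum "
            "(symmetric or static cell)",
            sim,
        )
    tail = sim[t_min:]
    best = float(tail.max())
    if best < match_threshold:
        raise PeriodNotFoundError(
            f"period not found: no similarity maximum above {match_threshold} "
            f"at lag >= {t_min} (best {best:.4f})",
            sim,
        )
    # earliest lag attaining the maximum (up to numerical ties): the
    # full-turn match is essentially exact, so weaker local maxima (the
    # half-turn mirror, slow drifts of nearly uniform cells) never reach it
    period = t_min + int(np.flatnonzero(tail >= best - 1e-6)[0])
    frames = np.arange(n)
    return AngleTrack(360.0 * frames / period, frames, estimated_period=float(period))


def reconstruct_fbp(
    qpm_sequence: list[QPM],
    angle_track: AngleTrack,
    n0: float | None = None,
    wavelength: float | None = None,
) -> RITomogram:
    """Slice-wise ramp-filtered back projection of a QPM rotation sequence.

    Each QPM is rescaled to the line integral of Δn (in voxel-length
    units), angles are wrapped to [0, 360) and duplicates averaged, and
    every x-slice sinogram is inverted with a Ram-Lak filter and linear
    back-projection interpolation. Negative excursions of the
    reconstruction are clipped: Δn ≥ 0 by construction of the phantoms.
    """
    if len(qpm_sequence) != len(angle_track.angles_deg):
        raise ValueError("angle track length does not match QPM sequence")
    shapes = {q.phase.shape for q in qpm_sequence}
    if len(shapes) != 1:
        raise ValueError(f"QPMs have mismatched shapes: {sorted(shapes)}")
    pitches = {q.pixel_pitch for q in qpm_sequence}
    if len(pitches) != 1:
        raise ValueError("QPMs have mismatched pixel pitches")
    pitch = pitches.pop()
    wavelength = wavelength if wavelength is not None else qpm_sequence[0].wavelength
    if n0 is None:
        n0 = 1.334

    angles = np.mod(angle_track.angles_deg, 360.0)
    # average QPMs sharing a wrapped angle
    unique, inverse = np.unique(np.round(angles, 9), return_inverse=True)
    if unique.size < 2:
        raise ValueError("need at least 2 distinct angles for reconstruction")
    lx, ly = qpm_sequence[0].phase.shape
    stack = np.zeros((unique.size, lx, ly))
    counts = np.zeros(unique.size)
    for idx, q in zip(inverse, qpm_sequence):
        stack[idx] += q.phase
        counts[idx] += 1
    stack /= counts[:, None, None]

    # phase → line integral of Δn in pixel-length units
    stack *= wavelength / (2.0 * np.pi * pitch)

    recon = np.empty((lx, ly, ly))
    for x in range(lx):
        sinogram = stack[:, x, :].T  # (detector=y, angle)
        # iradon reconstructs the slice with detector along its second
        # axis; transpose back to the package's (y, z) slice layout
        recon[x] = iradon(
            sinogram,
            theta=unique,
            filter_name="ramp",
            interpolation="linear",
            circle=True,
            output_size=ly,
        ).T
    np.maximum(recon, 0.0, out=recon)
    return RITomogram(n0 + recon, voxel_pitch=pitch, n0=n0)


def _segment(delta: np.ndarray, alpha: float) -> np.ndarray:
    peak = delta.max()
    if peak <= 0:
        raise ValueError("volume contains no values above the medium level")
    mask = delta > alpha * peak
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("segmentation produced an empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    # morphological cleanup on the component's bounding box only
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - 2, 0)
    hi = np.minimum(coords.max(axis=0) + 3, mask.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = mask[box]
    sub = ndimage.binary_fill_holes(sub)
    sub = ndimage.binary_closing(sub)
    sub = ndimage.binary_fill_holes(sub)
    mask = np.zeros_like(mask)
    mask[box] = sub
    if not mask.any():
        raise ValueError("segmentation produced an empty mask")
    return mask


def segment_support(tomogram: RITomogram, alpha: float = 0.1) -> CellSupport:
    """Threshold Δn > α·max(Δn), keep the largest connected component,
    fill holes and apply one closing pass."""
    mask = _segment(tomogram.delta_n, alpha)
    return CellSupport(mask, pitch=tomogram.voxel_pitch)
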