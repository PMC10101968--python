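"""Core data containers for tomographic phase imaging flow cytometry.

The pipeline is built around three objects:

* :class:`RITomogram` — a 3D refractive-index (RI) map of a single cell
  suspended in a homogeneous medium of RI ``n0`` (default 1.334). The cell
  occupies the *support* Γ, the set of voxels where the RI contrast
  ``Δn = n − n0`` is positive; outside Γ the volume equals ``n0`` exactly.
* :class:`QPM` — a quantitative phase map: the 2D optical phase delay (in
  radians) accumulated along the optical axis at one viewing (rolling)
  angle. Under the straight-ray model, ``φ(x, y) = (2π/λ) ∫ Δn dz``.
* :class:`CellSupport` — a boolean mask of the voxels (or pixels) occupied
  by the cell.

Axis convention, fixed throughout the package: array axes are (x, y, z)
with ``z`` the optical axis (projection direction), ``y`` the flow axis and
``x`` the rotation axis of the rolling cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: refractive index of the suspension medium
DEFAULT_N0 = 1.334
#: illumination wavelength, µm (532 nm laser)
DEFAULT_WAVELENGTH_UM = 0.532
#: object-space sampling: 4.5 µm camera pitch / 40x magnification, µm/voxel
DEFAULT_PITCH_UM = 0.1125
#: side length of the reconstruction cube, voxels
DEFAULT_GRID = 201


@dataclass
class RITomogram:
    """Volumetric refractive-index map of a single cell.

    Parameters
    ----------
    values : ndarray, shape (Lx, Ly, Lz)
        Refractive index per voxel; ``values >= n0`` everywhere and
        ``values == n0`` outside the cell support.
    voxel_pitch : float
        Isotropic voxel size in µm.
    n0 : float
        Refractive index of the surrounding medium.
    """

    values: np.ndarray
    voxel_pitch: float = DEFAULT_PITCH_UM
    n0: float = DEFAULT_N0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"tomogram must be 3D, got shape {self.values.shape}")
        if self.voxel_pitch <= 0:
            raise ValueError(f"voxel_pitch must be positive, got {self.voxel_pitch}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def delta_n(self) -> np.ndarray:
        """RI contrast Δn = n − n0 (zero off the support)."""
        return self.values - self.n0

    def support_mask(self) -> np.ndarray:
        """Boolean mask of voxels with strictly positive RI contrast."""
        return self.delta_n > 0

    def copy(self) -> "RITomogram":
        return RITomogram(self.values.copy(), self.voxel_pitch, self.n0)


@dataclass
class QPM:
    """Quantitative phase map at a single rolling angle.

    ``phase`` is in radians, shape (Lx, Ly); zero where no cell material is
    traversed by the ray.
    """

    phase: np.ndarray
    pixel_pitch: float = DEFAULT_PITCH_UM
    wavelength: float = DEFAULT_WAVELENGTH_UM
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise ValueError(f"QPM must be 2D, got shape {self.phase.shape}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not np.isfinite(self.phase).all():
            raise ValueError("QPM phase contains non-finite values")


@dataclass
class CellSupport:
    """Boolean occupancy mask Γ of a cell, 3D (voxels) or 2D (pixels)."""

    mask: np.ndarray
    pitch: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError(f"support must be 2D or 3D, got shape {self.mask.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Occupied volume in µm³ (or area in µm² for a 2D mask)."""
        return self.n_voxels * self.pitch ** self.mask.ndim


# ---------------------------------------------------------------------------
# TIFF / JSON round-trip helpers
# ---------------------------------------------------------------------------

def save_tomogram(path: str | Path, tomo: RITomogram) -> None:
    """Write a tomogram as a 32-bit multi-page TIFF (pages along z)."""
    path = Path(path)
    # pages along z: move the optical axis first
    pages = np.moveaxis(tomo.values.astype(np.float32), 2, 0)
    tifffile.imwrite(
        path,
        pages,
        metadata={"voxel_pitch_um": tomo.voxel_pitch, "n0": tomo.n0},
    )


def load_tomogram(path: str | Path) -> RITomogram:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    values = np.moveaxis(pages, 0, 2).astype(np.float64)
    return RITomogram(
        values,
        voxel_pitch=float(meta.get("voxel_pitch_um", DEFAULT_PITCH_UM)),
        n0=float(meta.get("n0", DEFAULT_N0)),
    )


def save_qpm_stack(path: str | Path, qpms: list[QPM]) -> None:
    """Write a QPM sequence as multi-page TIFF + JSON angle sidecar."""
    if not qpms:
        raise ValueError("empty QPM sequence")
    path = Path(path)
    stack = np.stack([q.phase for q in qpms]).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {
        "angles_deg": [q.angle_deg for q in qpms],
        "pixel_pitch_um": qpms[0].pixel_pitch,
        "wavelength_um": qpms[0].wavelength,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def load_qpm_stack(path: str | Path) -> list[QPM]:
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    angles = sidecar["angles_deg"]
    if len(angles) != len(stack):
        raise ValueError(
            f"sidecar lists {len(angles)} angles but TIFF has {len(stack)} pages"
        )
    return [
        QPM(
            page,
            pixel_pitch=sidecar["pixel_pitch_um"],
            wavelength=sidecar["wavelength_um"],
            angle_deg=a,
        )
        for page, a in zip(stack, angles)
    ]
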