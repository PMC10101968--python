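"""Class-conditional 3D refractive-index cell phantoms.

Generates seeded digital cells for three populations — monocyte-like
cells (MC), neuroblastoma-like cells (NB) and ovarian-cancer-like cells
(OC) — as ellipsoidal bodies with a concentric nucleus, small spherical
inclusions and band-limited random intracellular texture. The default
class distributions encode the qualitative separations expected between
a white-blood-cell background and tumor cells:

* MC are nearly spherical (axis ratios close to 1), tumor classes are
  elongated, so the sphericity distribution of NB/OC sits left of MC;
* OC carry a higher mean RI contrast than NB;
* the three classes differ in texture amplitude and correlation length,
  which separates their co-occurrence (GLCM) statistics.

Every phantom satisfies Δn > 0 on its support Γ and Δn = 0 elsewhere,
the regime required by the intensity-shift augmentation bound.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_GRID,
    DEFAULT_N0,
    DEFAULT_PITCH_UM,
    CellSupport,
    RITomogram,
    save_tomogram,
)

CLASS_LABELS = ("MC", "NB", "OC")

#: physiological ceiling on RI contrast
MAX_DELTA_N = 0.12

#: minimum clearance between cell and volume boundary, voxels
BOX_MARGIN_VOX = 5

#: benchmark split sizes: 700 training + 229 test cells
DEFAULT_COUNTS = {
    "train": {"MC": 200, "NB": 250, "OC": 250},
    "test": {"MC": 47, "NB": 122, "OC": 60},
}


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one phantom; a pure function of its seed."""

    class_label: str
    equiv_radius: float          # µm, radius of the equal-volume sphere
    axis_ratios: tuple[float, float, float]  # unit geometric mean
    mean_delta_n: float          # RIU, cytoplasm RI contrast
    nucleus_fraction: float      # nuclear volume / cell volume
    nucleus_delta_n_offset: float  # RIU added inside the nucleus
    n_inclusions: int
    inclusion_radius: float      # µm
    inclusion_delta_n_offset: float  # RIU added inside inclusions
    texture_amplitude: float     # RIU, std of the random field
    texture_correlation_length: float  # µm
    seed: int
    shape: tuple[int, int, int] = (DEFAULT_GRID,) * 3
    voxel_pitch: float = DEFAULT_PITCH_UM
    n0: float = DEFAULT_N0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.mean_delta_n <= 0:
            raise ValueError("mean_delta_n must be positive")
        peak = (
            self.mean_delta_n
            + max(self.nucleus_delta_n_offset, 0.0)
            + max(self.inclusion_delta_n_offset, 0.0)
            + 5.0 * self.texture_amplitude
        )
        if peak > MAX_DELTA_N:
            raise ValueError(
                f"parameters imply peak Δn ≈ {peak:.3f} above the {MAX_DELTA_N} cap"
            )
        if not 0.0 < self.nucleus_fraction < 1.0:
            raise ValueError("nucleus_fraction must lie in (0, 1)")

    @property
    def semi_axes_um(self) -> tuple[float, float, float]:
        return tuple(self.equiv_radius * r for r in self.axis_ratios)  # type: ignore


@dataclass(frozen=True)
class ClassDistributions:
    """Documented sampling ranges for the three populations.

    ``radius_scale`` shrinks all linear dimensions (cell radius, inclusion
    radius, texture correlation length) together, preserving the relative
    class separations while allowing smaller benchmark grids.
    """

    radius_scale: float = 1.0
    # (low, high) of U or (mean, sd) of clipped normals, per class
    equiv_radius: dict = field(
        default_factory=lambda: {"MC": (4.2, 5.0), "NB": (4.6, 5.6), "OC": (4.6, 5.8)}
    )
    ratio_spread: dict = field(
        default_factory=lambda: {
            # (major range, middle range, minor range) before normalization
            "MC": ((0.94, 1.06), (0.94, 1.06), (0.94, 1.06)),
            "NB": ((1.25, 1.55), (0.85, 1.00), (0.70, 0.88)),
            "OC": ((1.25, 1.55), (0.80, 1.00), (0.70, 0.88)),
        }
    )
    mean_delta_n: dict = field(
        default_factory=lambda: {
            "MC": (0.022, 0.0015),
            "NB": (0.019, 0.0015),
            "OC": (0.026, 0.0015),
        }
    )
    nucleus_fraction: dict = field(
        default_factory=lambda: {"MC": (0.45, 0.60), "NB": (0.50, 0.65), "OC": (0.50, 0.65)}
    )
    nucleus_offset: dict = field(
        default_factory=lambda: {"MC": (0.006, 0.010), "NB": (0.008, 0.012), "OC": (0.008, 0.012)}
    )
    n_inclusions: dict = field(
        default_factory=lambda: {"MC": (3, 6), "NB": (6, 10), "OC": (10, 14)}
    )
    inclusion_radius: dict = field(
        default_factory=lambda: {"MC": (0.40, 0.70), "NB": (0.30, 0.50), "OC": (0.35, 0.55)}
    )
    inclusion_offset: dict = field(
        default_factory=lambda: {"MC": (0.008, 0.012), "NB": (0.010, 0.014), "OC": (0.010, 0.014)}
    )
    texture_amplitude: dict = field(
        default_factory=lambda: {"MC": (0.003, 0.005), "NB": (0.006, 0.009), "OC": (0.009, 0.013)}
    )
    texture_corr_length: dict = field(
        default_factory=lambda: {"MC": (0.70, 0.90), "NB": (0.40, 0.60), "OC": (0.90, 1.20)}
    )


DEFAULT_DISTRIBUTIONS = ClassDistributions()


def sample_class_params(
    class_label: str,
    rng_seed: int,
    distributions: ClassDistributions = DEFAULT_DISTRIBUTIONS,
    shape: tuple[int, int, int] = (DEFAULT_GRID,) * 3,
    voxel_pitch: float = DEFAULT_PITCH_UM,
) -> PhantomParams:
    """Draw one phantom parameterization from the class-conditional defaults."""
    if class_label not in CLASS_LABELS:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    d = distributions
    s = d.radius_scale
    rng = np.random.default_rng(rng_seed)
    raw = np.array([rng.uniform(*rr) for rr in d.ratio_spread[class_label]])
    rng.shuffle(raw)  # random orientation of the anisotropy among axes
    ratios = raw / np.prod(raw) ** (1.0 / 3.0)
    mu, sd = d.mean_delta_n[class_label]
    mean_dn = float(np.clip(rng.normal(mu, sd), 0.010, 0.035))
    lo, hi = d.n_inclusions[class_label]
    return PhantomParams(
        class_label=class_label,
        equiv_radius=s * rng.uniform(*d.equiv_radius[class_label]),
        axis_ratios=tuple(ratios),
        mean_delta_n=mean_dn,
        nucleus_fraction=rng.uniform(*d.nucleus_fraction[class_label]),
        nucleus_delta_n_offset=rng.uniform(*d.nucleus_offset[class_label]),
        n_inclusions=int(rng.integers(lo, hi + 1)),
        inclusion_radius=s * rng.uniform(*d.inclusion_radius[class_label]),
        inclusion_delta_n_offset=rng.uniform(*d.inclusion_offset[class_label]),
        texture_amplitude=rng.uniform(*d.texture_amplitude[class_label]),
        texture_correlation_length=s * rng.uniform(*d.texture_corr_length[class_label]),
        seed=int(rng.integers(2**31)),
        shape=tuple(shape),
        voxel_pitch=voxel_pitch,
    )


def _ellipsoid_metric(
    shape: tuple[int, ...],
    center: np.ndarray,
    semi_axes_um: np.ndarray,
    pitch: float,
) -> np.ndarray:
    """Normalized squared ellipsoid radius at every voxel of a grid."""
    grids = np.ix_(*(np.arange(n, dtype=np.float64) for n in shape))
    q = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes_um):
        q = q + ((g - c) * pitch / a) ** 2
    return q


def generate_phantom(params: PhantomParams) -> tuple[RITomogram, CellSupport]:
    """Render one phantom onto its voxel grid.

    The support Γ is the exact voxel-center ellipsoid; the RI inside it is
    cytoplasm + nucleus offset + inclusion offsets + clipped Gaussian
    texture, so Δn > 0 holds on every support voxel by construction.
    """
    shape = params.shape
    pitch = params.voxel_pitch
    semi = np.asarray(params.semi_axes_um)
    semi_vox = semi / pitch
    for axis, (n, sv) in enumerate(zip(shape, semi_vox)):
        if sv + BOX_MARGIN_VOX > (n - 1) / 2.0:
            raise ValueError(
                f"cell semi-axis {sv:.1f} vox on axis {axis} violates the "
                f"{BOX_MARGIN_VOX}-voxel margin in a {n}-voxel box"
            )
    rng = np.random.default_rng(params.seed)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0

    # work on a crop around the cell; the rest of the box is exactly n0
    half = np.ceil(semi_vox).astype(int) + 2
    lo = np.floor(center).astype(int) - half
    hi = np.floor(center).astype(int) + half + 1
    crop = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    crop_shape = tuple(int(b - a) for a, b in zip(lo, hi))
    crop_center = center - lo

    q = _ellipsoid_metric(crop_shape, crop_center, semi, pitch)
    mask = q <= 1.0
    delta = np.zeros(crop_shape)
    delta[mask] = params.mean_delta_n

    # concentric nucleus occupying the stated volume fraction
    if params.nucleus_delta_n_offset != 0.0:
        f2 = params.nucleus_fraction ** (2.0 / 3.0)
        delta[q <= f2] += params.nucleus_delta_n_offset

    # small spherical inclusions at uniform positions inside 0.8 of the body
    for _ in range(params.n_inclusions):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = 0.8 * rng.uniform() ** (1.0 / 3.0)
        pos_um = r * u * semi
        pos_vox = crop_center + pos_um / pitch
        qi = _ellipsoid_metric(
            crop_shape, pos_vox, np.full(3, params.inclusion_radius), pitch
        )
        delta[(qi <= 1.0) & mask] += params.inclusion_delta_n_offset

    # band-limited Gaussian random field, unit variance on the support
    if params.texture_amplitude > 0.0:
        noise = rng.normal(size=crop_shape)
        sigma_vox = params.texture_correlation_length / pitch
        smooth = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
        sd = smooth[mask].std()
        if sd > 0:
            delta[mask] += params.texture_amplitude * (
                smooth[mask] - smooth[mask].mean()
            ) / sd

    # keep Δn strictly positive on Γ, exactly zero off Γ, below the cap
    floor = 0.1 * params.mean_delta_n
    delta[mask] = np.clip(delta[mask], floor, MAX_DELTA_N)
    delta[~mask] = 0.0

    values = np.full(shape, params.n0)
    values[crop] += delta
    full_mask = np.zeros(shape, dtype=bool)
    full_mask[crop] = mask
    return (
        RITomogram(values, voxel_pitch=pitch, n0=params.n0),
        CellSupport(full_mask, pitch=pitch),
    )


# ---------------------------------------------------------------------------
# benchmark dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Bookkeeping for a generated (or augmented) dataset on disk."""

    records: list[dict]

    def __post_init__(self) -> None:
        ids = [r["id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in manifest")

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for r in self.records:
            split = out.setdefault(r["split"], {c: 0 for c in CLASS_LABELS})
            split[r["class_label"]] += 1
        return out

    def subset(self, split: str) -> list[dict]:
        return [r for r in self.records if r["split"] == split]

    def to_json(self) -> str:
        return json.dumps(
            {"records": self.records, "counts": self.counts()},
            sort_keys=True,
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        return cls(json.loads(Path(path).read_text())["records"])


def cell_seed(master_seed: int, index: int) -> int:
    """Per-cell seed stream, independent across cells and reproducible."""
    ss = np.random.SeedSequence(entropy=[int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def make_benchmark(
    counts_per_class_per_split: dict[str, dict[str, int]] | None,
    master_seed: int,
    out_dir: str | Path,
    distributions: ClassDistributions = DEFAULT_DISTRIBUTIONS,
    shape: tuple[int, int, int] = (DEFAULT_GRID,) * 3,
    voxel_pitch: float = DEFAULT_PITCH_UM,
) -> DatasetManifest:
    """Generate a benchmark dataset of tomogram TIFFs plus a JSON manifest.

    With the default counts this mirrors the reference split: 700 training
    cells (200 MC / 250 NB / 250 OC) and 229 test cells (47 / 122 / 60).
    """
    counts = counts_per_class_per_split or DEFAULT_COUNTS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    index = 0
    for split in sorted(counts):
        for label in CLASS_LABELS:
            n = counts[split].get(label, 0)
            if n < 0:
                raise ValueError(f"negative count for {split}/{label}")
            for k in range(n):
                seed = cell_seed(master_seed, index)
                params = sample_class_params(
                    label, seed, distributions, shape=shape, voxel_pitch=voxel_pitch
                )
                tomo, _ = generate_phantom(params)
                rel = f"{split}_{label}_{k:04d}.tif"
                save_tomogram(out_dir / rel, tomo)
                records.append(
                    {
                        "id": f"{split}-{label}-{k:04d}",
                        "class_label": label,
                        "seed": seed,
                        "path": rel,
                        "split": split,
                    }
                )
                index += 1
    manifest = DatasetManifest(records)
    manifest.save(out_dir / "manifest.json")
    return manifest
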