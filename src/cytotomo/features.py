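"""44-feature extraction from RI tomograms (3D) and phase maps (2D).

Each cell is summarized by an ordered vector of 44 named values in three
blocks:

* 11 intensity statistics of the RI (or phase) distribution over the
  cell support — mean, median, mode, maximum, standard deviation,
  skewness, entropy, excess kurtosis, the 0.25/0.75 quantiles, and the
  dry mass. Dry mass is the water-free cell mass obtained from the
  integral of the RI contrast (or phase) divided by the specific
  refraction increment α (default 0.19 mL/g):

      m_3D = (1/α) Σ_Γ Δn · pitch³        [picograms]
      m_2D = λ/(2πα) Σ φ · pitch²          [picograms]

* 9 morphology descriptors of the support — 3D: volume, convex volume,
  sphericity, extent, solidity, three principal-axis lengths,
  normalized centroid-to-weighted-centroid distance; 2D: area, extent,
  solidity, circularity (4πA/P²), eccentricity, max/min Feret
  diameters, major-axis length, normalized centroids' distance.

* 24 texture features: the 12 Haralick statistics of the gray-level
  co-occurrence matrix (GLCM), averaged over 13 directions in 3D (4 in
  2D), at offsets of 0.5 µm and 1 µm. Gray levels come from min–max
  quantization over the support into 32 bins. "Contrast" and "inertia"
  are listed separately but share the standard Σ(i−j)²p formula, so the
  vector carries the duplicated column under both names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from skimage import measure

from .core import CellSupport, QPM, RITomogram
from .tomography import _segment, segment_support

#: specific refraction increment, mL/g
DEFAULT_ALPHA_RI = 0.19

#: gray levels used for histograms (mode, entropy) and GLCM quantization
N_GRAY_LEVELS = 32

#: GLCM offset distances, µm
GLCM_DISTANCES_UM = (0.5, 1.0)

#: the 13 unique 3D co-occurrence directions (unit voxel steps)
DIRECTIONS_3D = (
    (0, 1, 0),
    (-1, 1, 0),
    (-1, 0, 0),
    (-1, -1, 0),
    (0, 1, -1),
    (0, 0, -1),
    (0, -1, -1),
    (-1, 0, -1),
    (1, 0, -1),
    (-1, 1, -1),
    (1, -1, -1),
    (-1, -1, -1),
    (1, 1, -1),
)

#: the 4 unique in-plane directions
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

STAT_NAMES = (
    "mean",
    "median",
    "mode",
    "maximum",
    "std",
    "skewness",
    "entropy",
    "kurtosis",
    "quantile_25",
    "quantile_75",
    "dry_mass_pg",
)

MORPH_NAMES_3D = (
    "volume_um3",
    "convex_volume_um3",
    "sphericity",
    "extent",
    "solidity",
    "axis_length_1_um",
    "axis_length_2_um",
    "axis_length_3_um",
    "centroid_distance",
)

MORPH_NAMES_2D = (
    "area_um2",
    "extent",
    "solidity",
    "circularity",
    "eccentricity",
    "feret_max_um",
    "feret_min_um",
    "major_axis_um",
    "centroid_distance",
)

HARALICK_NAMES = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "variance",
    "sum_average",
    "inertia",
    "cluster_shade",
    "cluster_tendency",
    "homogeneity",
    "max_probability",
    "inverse_variance",
)


@dataclass
class FeatureVector:
    """Ordered, named 44-value descriptor of one cell."""

    names: tuple[str, ...]
    values: np.ndarray
    flavor: str  # "3D" or "2D"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ValueError("names and values differ in length")
        if len(self.values) != 44:
            raise ValueError(f"expected 44 features, got {len(self.values)}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def feature_names(flavor: str) -> tuple[str, ...]:
    morph = MORPH_NAMES_3D if flavor == "3D" else MORPH_NAMES_2D
    glcm_names = tuple(
        f"glcm_{name}_d{str(d).replace('.', 'p')}"
        for d in GLCM_DISTANCES_UM
        for name in HARALICK_NAMES
    )
    return tuple(f"stat_{n}" for n in STAT_NAMES) + tuple(
        f"morph_{n}" for n in morph
    ) + glcm_names


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------

def _histogram_stats(values: np.ndarray) -> tuple[float, float]:
    """(mode, entropy in bits) of the 32-bin histogram of ``values``."""
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return float(vmin), 0.0
    counts, edges = np.histogram(values, bins=N_GRAY_LEVELS, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode = float(centers[np.argmax(counts)])
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return mode, entropy


def _intensity_stats(
    values: np.ndarray, dry_mass_pg: float
) -> np.ndarray:
    """The 11 statistics of a support-restricted intensity sample."""
    if values.size == 0:
        raise ValueError("empty support: no values to summarize")
    mode, entropy = _histogram_stats(values)
    constant = values.max() == values.min()
    return np.array(
        [
            values.mean(),
            np.quantile(values, 0.5),
            mode,
            values.max(),
            values.std(),
            0.0 if constant else stats.skew(values),
            entropy,
            0.0 if constant else stats.kurtosis(values),  # excess kurtosis
            np.quantile(values, 0.25),
            np.quantile(values, 0.75),
            dry_mass_pg,
        ]
    )


def ri_statistics(
    tomogram: RITomogram,
    support: CellSupport,
    alpha_ri: float = DEFAULT_ALPHA_RI,
) -> np.ndarray:
    """11 statistics of the RI distribution over the support voxels.

    Dry mass: Δn · voxel volume sums to µm³ of contrast; with α in mL/g
    and 1 µm³ = 10⁻¹² mL the quotient lands directly in picograms.
    """
    mask = support.mask
    if not mask.any():
        raise ValueError("empty support")
    values = tomogram.values[mask]
    dn_sum = float(tomogram.delta_n[mask].sum())
    dry_mass = dn_sum * tomogram.voxel_pitch**3 / alpha_ri
    return _intensity_stats(values, dry_mass)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _convex_image_volume(
    coords: np.ndarray, shape: tuple[int, ...], boundary_coords: np.ndarray | None = None
) -> int:
    """Number of grid points inside the convex hull of ``coords``.

    Grid points are tested against the hull's facet half-spaces in one
    matrix product; ``boundary_coords`` (e.g. the support's surface
    voxels) may be passed to build the hull from fewer points.
    """
    hull = ConvexHull(boundary_coords if boundary_coords is not None else coords)
    eq = hull.equations  # a point p is inside iff n·p + o <= 0 for all facets
    d = len(shape)
    n_xy = eq[:, : d - 1]
    n_z = eq[:, d - 1]
    off = eq[:, d]
    eps = 1e-9
    zpos = n_z > eps
    zneg = n_z < -eps
    zflat = ~zpos & ~zneg
    length = shape[-1]
    # convexity makes every grid column along the last axis a contiguous
    # interval: intersect the half-space z-bounds per column and count
    columns = np.indices(shape[:-1]).reshape(d - 1, -1).T.astype(np.float64)
    total = 0
    for start in range(0, len(columns), 4096):
        block = columns[start : start + 4096]
        base = block @ n_xy.T + off  # (cols, facets)
        upper = np.full(len(block), float(length - 1))
        lower = np.zeros(len(block))
        if zpos.any():
            upper = np.minimum(upper, (-base[:, zpos] / n_z[zpos]).min(axis=1))
        if zneg.any():
            lower = np.maximum(lower, (-base[:, zneg] / n_z[zneg]).max(axis=1))
        feasible = (
            base[:, zflat].max(axis=1, initial=-np.inf) <= eps
            if zflat.any()
            else np.ones(len(block), dtype=bool)
        )
        counts = np.floor(upper + eps) - np.ceil(lower - eps) + 1
        counts = np.where(feasible, np.maximum(counts, 0), 0)
        total += int(counts.sum())
    return total


def _principal_axis_lengths(coords: np.ndarray, pitch: float, factor: float) -> np.ndarray:
    """Axis lengths of the moment-equivalent solid ellipsoid/ellipse.

    ``factor`` is 2√5 in 3D and 4 in 2D: a solid ellipsoid's second
    central moment along a semi-axis a is a²/5, an ellipse's is a²/4.
    """
    centered = (coords - coords.mean(axis=0)) * pitch
    cov = centered.T @ centered / len(coords)
    eig = np.linalg.eigvalsh(cov)[::-1]
    return factor * np.sqrt(np.maximum(eig, 0.0))


def morphology_3d(support: CellSupport, tomogram: RITomogram) -> np.ndarray:
    """9 shape descriptors of a connected 3D support."""
    mask = support.mask
    if not mask.any():
        raise ValueError("empty support")
    _, n_cc = ndimage.label(mask)
    if n_cc != 1:
        raise ValueError(f"support must be a single connected component, got {n_cc}")
    pitch = support.pitch
    n_vox = int(mask.sum())
    volume = n_vox * pitch**3

    # all shape work happens on the support's bounding box
    full_coords = np.argwhere(mask)
    lo = np.maximum(full_coords.min(axis=0) - 1, 0)
    hi = np.minimum(full_coords.max(axis=0) + 2, mask.shape)
    sub = mask[tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))]
    coords = np.argwhere(sub)

    # convex volume in the regionprops sense: voxels whose centers fall
    # inside the convex hull of the support (hull of voxel centers alone
    # underestimates the digitized volume and pushes solidity above 1)
    surface = np.argwhere(sub & ~ndimage.binary_erosion(sub))
    convex_volume = _convex_image_volume(coords, sub.shape, surface) * pitch**3

    # mesh-based surface area: marching cubes on a lightly smoothed mask,
    # which suppresses the staircase area inflation of a raw binary surface
    padded = ndimage.gaussian_filter(np.pad(sub, 2).astype(np.float64), 1.2)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(pitch,) * 3)
    area = measure.mesh_surface_area(verts, faces)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area

    bbox = (coords.max(axis=0) - coords.min(axis=0) + 1) * pitch
    extent = volume / np.prod(bbox)
    solidity = volume / convex_volume

    axes = _principal_axis_lengths(coords, pitch, 2.0 * np.sqrt(5.0))

    centroid = coords.mean(axis=0)
    weights = tomogram.values[mask]
    weighted = (coords * weights[:, None]).sum(axis=0) / weights.sum()
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    centroid_dist = np.linalg.norm(centroid - weighted) * pitch / r_eq

    return np.array(
        [volume, convex_volume, sphericity, extent, solidity, *axes, centroid_dist]
    )


def _min_feret(hull_points: np.ndarray) -> float:
    """Minimum caliper width of a 2D convex hull (rotating calipers)."""
    pts = hull_points
    n = len(pts)
    best = np.inf
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths = (pts - pts[i]) @ normal
        best = min(best, widths.max() - widths.min())
    return float(best)


def morphology_2d(support: CellSupport, qpm: QPM) -> np.ndarray:
    """9 shape descriptors of a connected 2D support."""
    mask = support.mask
    if not mask.any():
        raise ValueError("empty support")
    _, n_cc = ndimage.label(mask)
    if n_cc != 1:
        raise ValueError(f"support must be a single connected component, got {n_cc}")
    pitch = support.pitch
    area = int(mask.sum()) * pitch**2

    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    convex_area = (
        _convex_image_volume(coords - lo, tuple(hi - lo)) * pitch**2
    )
    hull = ConvexHull(coords * pitch)
    hull_pts = (coords * pitch)[hull.vertices]

    bbox = (coords.max(axis=0) - coords.min(axis=0) + 1) * pitch
    extent = area / np.prod(bbox)
    solidity = area / convex_area

    # contour length of the lightly smoothed mask (the 2D analogue of the
    # smoothed marching-cubes surface area): accurate for both smooth and
    # polygonal outlines, unlike pixel-count perimeter estimators
    smoothed = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 3), 1.0)
    contour = max(measure.find_contours(smoothed, 0.5), key=len)
    steps = np.diff(contour, axis=0)
    perimeter = np.sqrt((steps**2).sum(axis=1)).sum() * pitch
    circularity = 4.0 * np.pi * area / perimeter**2

    axes = _principal_axis_lengths(coords, pitch, 4.0)
    major, minor = axes[0], axes[1]
    eccentricity = np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)) if major > 0 else 0.0

    dists = np.linalg.norm(hull_pts[:, None, :] - hull_pts[None, :, :], axis=2)
    feret_max = float(dists.max())
    feret_min = _min_feret(hull_pts)

    centroid = coords.mean(axis=0)
    weights = qpm.phase[mask]
    weighted = (coords * weights[:, None]).sum(axis=0) / weights.sum()
    r_eq = np.sqrt(area / np.pi)
    centroid_dist = np.linalg.norm(centroid - weighted) * pitch / r_eq

    return np.array(
        [
            area,
            extent,
            solidity,
            circularity,
            eccentricity,
            feret_max,
            feret_min,
            major,
            centroid_dist,
        ]
    )


# ---------------------------------------------------------------------------
# GLCM + Haralick
# ---------------------------------------------------------------------------

@dataclass
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix."""

    probabilities: np.ndarray
    n_levels: int
    direction: tuple[int, ...]
    distance_um: float
    distance_vox: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if (p < 0).any():
            raise ValueError("GLCM entries must be non-negative")
        self.probabilities = p


def quantize(
    values: np.ndarray, support: np.ndarray, n_levels: int = N_GRAY_LEVELS
) -> np.ndarray:
    """Min–max quantization of support values into levels 1..n_levels.

    Off-support voxels are flagged 0 (ignored by the GLCM accumulator).
    Invariant under affine intensity maps a·x + b with a > 0; a constant
    input degenerates to a single occupied level.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    if not support.any():
        raise ValueError("empty support")
    out = np.zeros(values.shape, dtype=np.int32)
    sample = values[support]
    vmin, vmax = sample.min(), sample.max()
    if vmax == vmin:
        out[support] = 1
        return out
    scaled = (values[support] - vmin) / (vmax - vmin)
    out[support] = np.minimum((scaled * n_levels).astype(np.int32), n_levels - 1) + 1
    return out


def glcm(
    volume_levels: np.ndarray,
    direction: tuple[int, ...],
    distance_um: float,
    pitch: float,
    n_levels: int = N_GRAY_LEVELS,
) -> GLCM:
    """Symmetric co-occurrence matrix at a voxel offset of
    round(d/pitch) steps along ``direction``.

    Pairs are counted only when both endpoints lie on the support
    (level > 0), accumulated in both orders, and normalized to sum 1.
    """
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    ndim = volume_levels.ndim
    if len(direction) != ndim:
        raise ValueError(f"direction {direction} does not match a {ndim}D volume")
    allowed = DIRECTIONS_3D if ndim == 3 else DIRECTIONS_2D
    if tuple(direction) not in allowed:
        raise ValueError(f"direction {direction} not one of the {len(allowed)} canonical steps")
    step = int(round(distance_um / pitch))
    if step < 1:
        step = 1
    offset = tuple(step * d for d in direction)
    if any(abs(o) >= s for o, s in zip(offset, volume_levels.shape)):
        raise ValueError(f"offset {offset} exceeds the volume extent {volume_levels.shape}")

    src = tuple(
        slice(max(0, -o), min(s, s - o)) for o, s in zip(offset, volume_levels.shape)
    )
    dst = tuple(
        slice(max(0, o), min(s, s + o)) for o, s in zip(offset, volume_levels.shape)
    )
    a = volume_levels[src]
    b = volume_levels[dst]
    valid = (a > 0) & (b > 0)
    av, bv = a[valid] - 1, b[valid] - 1
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (av, bv), 1.0)
    counts += counts.T  # symmetric accumulation
    total = counts.sum()
    if total > 0:
        counts /= total
    return GLCM(counts, n_levels, tuple(direction), distance_um, step)


def haralick(matrix: GLCM) -> np.ndarray:
    """The 12 Haralick statistics of a normalized GLCM.

    Levels are indexed 1..P. With marginal means/stds µ_i, σ_i (identical
    for a symmetric matrix):

        energy          Σ p²
        entropy         −Σ p log₂ p            (0·log 0 = 0)
        correlation     Σ (i−µ_i)(j−µ_j) p / (σ_i σ_j)
        contrast        Σ (i−j)² p
        variance        Σ (i−µ)² p              (µ over the i margin)
        sum average     Σ_k k · p_{x+y}(k)
        inertia         Σ (i−j)² p              (alias of contrast)
        cluster shade   Σ (i+j−µ_i−µ_j)³ p
        cluster tend.   Σ (i+j−µ_i−µ_j)² p
        homogeneity     Σ p / (1+(i−j)²)
        max probability max p
        inverse var.    Σ_{i≠j} p / (i−j)²
    """
    p = matrix.probabilities
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"GLCM must be normalized (sum={total:.6g})")
    n = p.shape[0]
    idx = np.arange(1, n + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float(px @ idx)
    mu_j = float(py @ idx)
    sd_i = float(np.sqrt(px @ (idx - mu_i) ** 2))
    sd_j = float(np.sqrt(py @ (idx - mu_j) ** 2))

    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = float((((i - mu_i) * (j - mu_j)) * p).sum() / (sd_i * sd_j))
    else:
        correlation = 1.0  # degenerate single-level matrix: perfect agreement
    contrast = float((((i - j) ** 2) * p).sum())
    variance = float((((i - mu_i) ** 2) * p).sum())

    # distribution of i+j, supported on 2..2n
    k = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.array([p[(i + j) == kk].sum() for kk in k])
    sum_average = float(k @ p_sum)

    shade_base = i + j - mu_i - mu_j
    cluster_shade = float(((shade_base**3) * p).sum())
    cluster_tendency = float(((shade_base**2) * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    max_probability = float(p.max())
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(off, p / np.where(off, (i - j) ** 2, 1.0), 0.0)
    inverse_variance = float(inv.sum())

    return np.array(
        [
            energy,
            entropy,
            correlation,
            contrast,
            variance,
            sum_average,
            contrast,  # inertia duplicates the contrast formula
            cluster_shade,
            cluster_tendency,
            homogeneity,
            max_probability,
            inverse_variance,
        ]
    )


def glcm_features(
    values: np.ndarray,
    support: np.ndarray,
    pitch: float,
    n_levels: int = N_GRAY_LEVELS,
    distances_um: tuple[float, ...] = GLCM_DISTANCES_UM,
) -> np.ndarray:
    """24 texture values: direction-averaged Haralick features per distance."""
    directions = DIRECTIONS_3D if values.ndim == 3 else DIRECTIONS_2D
    levels = quantize(values, support, n_levels)
    # crop to the support bounding box to keep the shifted-array passes small
    coords = np.argwhere(support)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    margin = int(round(max(distances_um) / pitch)) + 1
    sl = tuple(
        slice(max(0, int(a) - margin), min(s, int(b) + margin))
        for a, b, s in zip(lo, hi, values.shape)
    )
    levels = levels[sl]
    out = []
    for d in distances_um:
        per_dir = [haralick(glcm(levels, v, d, pitch, n_levels)) for v in directions]
        out.append(np.mean(per_dir, axis=0))
    return np.concatenate(out)


def glcm_features_3d(
    tomogram: RITomogram,
    support: CellSupport,
    n_levels: int = N_GRAY_LEVELS,
) -> np.ndarray:
    return glcm_features(
        tomogram.values, support.mask, tomogram.voxel_pitch, n_levels
    )


# ---------------------------------------------------------------------------
# assembled 44-feature vectors
# ---------------------------------------------------------------------------

def features_3d(
    tomogram: RITomogram,
    support: CellSupport | None = None,
    alpha_ri: float = DEFAULT_ALPHA_RI,
) -> FeatureVector:
    """Segment (if needed) and extract the full 3D descriptor."""
    if support is None:
        support = segment_support(tomogram)
    values = np.concatenate(
        [
            ri_statistics(tomogram, support, alpha_ri),
            morphology_3d(support, tomogram),
            glcm_features_3d(tomogram, support),
        ]
    )
    return FeatureVector(feature_names("3D"), values, "3D")


def segment_qpm(qpm: QPM, alpha: float = 0.1) -> CellSupport:
    """Threshold φ > α·max(φ), keep the largest component, fill holes."""
    mask = _segment(qpm.phase, alpha)
    return CellSupport(mask, pitch=qpm.pixel_pitch)


def features_2d(
    qpm: QPM,
    support: CellSupport | None = None,
    alpha_ri: float = DEFAULT_ALPHA_RI,
) -> FeatureVector:
    """Mirrored 44-feature descriptor of a single phase map."""
    if support is None:
        support = segment_qpm(qpm)
    mask = support.mask
    phase = qpm.phase[mask]
    dry_mass = (
        qpm.wavelength
        / (2.0 * np.pi * alpha_ri)
        * float(phase.sum())
        * qpm.pixel_pitch**2
    )
    values = np.concatenate(
        [
            _intensity_stats(phase, dry_mass),
            morphology_2d(support, qpm),
            glcm_features(qpm.phase, mask, qpm.pixel_pitch),
        ]
    )
    return FeatureVector(feature_names("2D"), values, "2D")
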