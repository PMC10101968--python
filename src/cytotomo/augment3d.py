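"""3D data augmentation of RI tomograms.

Three successive operations enlarge the training set without touching
class labels:

1. *intensity scaling* — Δn on the support is multiplied by
   a ~ U(0.9, 1.1);
2. *intensity shifting* — the scaled Δn is offset by
   b ~ U(−min Δn⁽¹⁾/2, +min Δn⁽¹⁾/2), whose bound (taken on the
   post-scaling minimum) guarantees Δn stays strictly positive;
3. *morphological alteration* — the Lx×Ly×Lz volume is resampled to
   (Lx+cx)×(Ly+cy)×(Lz+cz) with cx, cy, cz ~ U(−20, 20), stretching or
   compressing the cell along each axis without rescaling intensities.

Training sets are expanded with 9, 3 and 3 augmented copies per MC, NB
and OC cell respectively (each original is kept, so 200 MC originals
become 2000 records); test data are never augmented.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .core import RITomogram, load_tomogram, save_tomogram
from .phantom import DatasetManifest

#: augmented copies added per training cell of each class
DEFAULT_MULTIPLICITY = {"MC": 9, "NB": 3, "OC": 3}

#: admissible ranges of the three draws
SCALE_RANGE = (0.9, 1.1)
MORPH_RANGE = (-20, 20)
MIN_EXTENT = 32


@dataclass(frozen=True)
class AugmentationParams:
    a: float                       # intensity scale factor
    b: float                       # intensity shift, RIU
    c: tuple[int, int, int]        # voxel-extent changes (cx, cy, cz)
    seed: int


def intensity_scale(tomogram: RITomogram, a: float) -> RITomogram:
    """Rescale Δn by ``a`` on the support; the background stays at n0."""
    if a <= 0:
        raise ValueError(f"scale factor must be positive, got {a}")
    return RITomogram(
        tomogram.n0 + a * tomogram.delta_n,
        voxel_pitch=tomogram.voxel_pitch,
        n0=tomogram.n0,
    )


def shift_bound(tomogram: RITomogram) -> float:
    """Half the minimum support Δn — the admissible |b| for this tomogram."""
    support = tomogram.support_mask()
    if not support.any():
        raise ValueError("tomogram has an empty support")
    return float(tomogram.delta_n[support].min()) / 2.0


def intensity_shift(tomogram: RITomogram, b: float) -> RITomogram:
    """Offset Δn by ``b`` on the support only.

    ``|b|`` may not exceed half the minimum support Δn, which keeps the
    shifted contrast strictly positive everywhere on Γ.
    """
    bound = shift_bound(tomogram)
    if abs(b) > bound + 1e-15:
        raise ValueError(
            f"shift {b} outside the admissible interval [-{bound:.3g}, {bound:.3g}]"
        )
    values = tomogram.values.copy()
    support = tomogram.support_mask()
    values[support] += b
    return RITomogram(values, voxel_pitch=tomogram.voxel_pitch, n0=tomogram.n0)


def morph_alter(tomogram: RITomogram, cx: int, cy: int, cz: int) -> RITomogram:
    """Resample the full volume to (Lx+cx, Ly+cy, Lz+cz) voxels.

    Cubic interpolation over the whole grid; RI values are not rescaled.
    Interpolation ringing below the medium level is clamped back to n0,
    and the new support follows from Δn > 0 on the resized grid.
    """
    lx, ly, lz = tomogram.shape
    new_shape = (lx + int(cx), ly + int(cy), lz + int(cz))
    if min(new_shape) < MIN_EXTENT:
        raise ValueError(
            f"target extents {new_shape} degenerate (minimum {MIN_EXTENT} voxels)"
        )
    delta = tomogram.delta_n
    support = delta > 0
    resized = np.zeros(new_shape)
    if support.any():
        # resample only the support's neighborhood: the field is exactly
        # zero elsewhere, so stretching the crop by the per-axis factors
        # and re-embedding it reproduces the full-grid resize on Γ
        coords = np.argwhere(support)
        lo = np.maximum(coords.min(axis=0) - 4, 0)
        hi = np.minimum(coords.max(axis=0) + 5, delta.shape)
        crop = delta[tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))]
        factors = np.asarray(new_shape) / np.asarray(delta.shape)
        out_crop_shape = np.maximum(
            np.round(crop.shape * factors).astype(int), 1
        )
        sub = resize(
            crop,
            tuple(out_crop_shape),
            order=3,
            mode="constant",
            cval=0.0,
            anti_aliasing=False,
            preserve_range=True,
        )
        np.maximum(sub, 0.0, out=sub)
        off = np.round(lo * factors).astype(int)
        end = np.minimum(off + out_crop_shape, new_shape)
        resized[tuple(slice(int(a), int(b)) for a, b in zip(off, end))] = sub[
            tuple(slice(0, int(b - a)) for a, b in zip(off, end))
        ]
    return RITomogram(
        tomogram.n0 + resized, voxel_pitch=tomogram.voxel_pitch, n0=tomogram.n0
    )


def draw_params(tomogram: RITomogram, rng_seed: int) -> AugmentationParams:
    """Draw (a, b, c) from the stated uniform distributions.

    The shift bound depends on the scaled tomogram, so ``b`` is drawn
    against min Δn⁽¹⁾ = a · min Δn.
    """
    rng = np.random.default_rng(rng_seed)
    a = float(rng.uniform(*SCALE_RANGE))
    bound = a * shift_bound(tomogram)
    b = float(rng.uniform(-bound, bound))
    c = tuple(int(v) for v in rng.integers(MORPH_RANGE[0], MORPH_RANGE[1] + 1, 3))
    return AugmentationParams(a=a, b=b, c=c, seed=int(rng_seed))


def augment(
    tomogram: RITomogram, rng_seed: int
) -> tuple[RITomogram, AugmentationParams]:
    """Apply scale → shift → morph with freshly drawn parameters."""
    params = draw_params(tomogram, rng_seed)
    out = intensity_scale(tomogram, params.a)
    out = intensity_shift(out, params.b)
    out = morph_alter(out, *params.c)
    return out, params


def augment_dataset(
    manifest: DatasetManifest,
    multiplicity_per_class: dict[str, int] | None,
    rng_seed: int,
    data_dir: str | Path,
) -> DatasetManifest:
    """Expand the training split of a dataset on disk.

    Each training record keeps its original tomogram and gains
    ``multiplicity`` augmented copies with provenance (source id and the
    drawn parameters); the test split passes through untouched.
    """
    mult = multiplicity_per_class or DEFAULT_MULTIPLICITY
    if any(m < 0 for m in mult.values()):
        raise ValueError("multiplicities must be non-negative")
    data_dir = Path(data_dir)
    train = manifest.subset("train")
    if not train:
        raise ValueError("manifest has no training split to augment")
    records = list(manifest.records)
    for rec in train:
        m = mult.get(rec["class_label"], 0)
        if m == 0:
            continue
        tomo = load_tomogram(data_dir / rec["path"])
        for k in range(m):
            seed = int(
                np.random.SeedSequence(
                    entropy=[int(rng_seed), zlib.crc32(rec["id"].encode()), k]
                ).generate_state(1)[0]
                % 2**31
            )
            aug, params = augment(tomo, seed)
            rel = rec["path"].replace(".tif", f"_aug{k:02d}.tif")
            save_tomogram(data_dir / rel, aug)
            records.append(
                {
                    "id": f"{rec['id']}-aug{k:02d}",
                    "class_label": rec["class_label"],
                    "seed": seed,
                    "path": rel,
                    "split": "train",
                    "augmentation": {
                        "source": rec["id"],
                        "a": params.a,
                        "b": params.b,
                        "c": list(params.c),
                    },
                }
            )
    out = DatasetManifest(records)
    out.save(data_dir / "manifest.json")
    return out
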