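"""Synthetic multimodal brain-slice phantoms with ground-truth tumor masks.

A phantom emulates the features of a co-registered multimodal MRI slice that
the segmentation pipeline actually consumes: a bright elliptical "brain" on a
dark background, one elliptical tumor placed uniformly at random inside the
brain, per-modality tumor/background contrast (tumor bright on T1C/FLAIR/T2,
dim on T1, as in glioma imaging), smooth low-frequency background texture,
additive Gaussian noise, and an exact binary tumor mask.  It is *not* an MR
physics simulation — no bias field, no partial-volume effect, no anatomy —
but it provides controllable, reproducible data with pixel-exact ground
truth for every downstream stage.

Real data can be substituted through :func:`load_slice_image` /
:func:`load_real_case`, which read MetaImage (.mha) and NIfTI slices and
min–max normalize them to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MODALITIES",
    "PhantomParams",
    "MultimodalSlice",
    "PhantomDataset",
    "make_phantom",
    "make_dataset",
    "write_case_pngs",
    "save_dataset_npz",
    "load_dataset_npz",
    "load_slice_image",
    "load_real_case",
]

#: Canonical modality order used for channel stacking (acquisition-name order).
MODALITIES = ("T1", "T2", "T1C", "FLAIR")

#: Per-modality (tumor_mean, background_mean) defaults, in [0, 1].  Tumor is
#: hyperintense on T2/T1C/FLAIR and hypointense on T1, so multimodal fusion
#: carries complementary signal.
DEFAULT_CONTRASTS: Mapping[str, tuple[float, float]] = {
    "T1": (0.30, 0.62),
    "T2": (0.80, 0.45),
    "T1C": (0.92, 0.40),
    "FLAIR": (0.85, 0.48),
}


class PhantomParameterError(ValueError):
    """Raised for invalid phantom parameters."""


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom slice.

    Parameters
    ----------
    side : int
        Image side in pixels; must be divisible by 16 so four dyadic
        decomposition levels exist.  Default 240 (→ subband sides
        120/60/30/15).
    tumor_radius_range : (float, float), optional
        Min/max tumor semi-axis in pixels.  Defaults to
        ``(0.05*side, 0.125*side)``.
    brain_axes_fraction : (float, float)
        Brain-ellipse semi-axes as fractions of ``side/2``.
    modality_contrasts : mapping
        Per-modality ``(tumor_mean, background_mean)`` intensities in [0, 1].
    noise_sd : float
        Standard deviation of additive Gaussian noise (intensity units).
    texture_scale : float, optional
        Gaussian smoothing length (pixels) of the low-frequency background
        texture.  Defaults to ``side / 8``.
    texture_amplitude : float
        Peak absolute amplitude of the texture field.  Kept below half the
        smallest tumor/background contrast gap so the noiseless T1C phantom
        is exactly threshold-separable.
    outside_level : float
        Intensity of the dark region outside the brain ellipse.
    seed : int
        Seed of the per-slice random generator.
    """

    side: int = 240
    tumor_radius_range: tuple[float, float] | None = None
    brain_axes_fraction: tuple[float, float] = (0.82, 0.70)
    modality_contrasts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS))
    noise_sd: float = 0.03
    texture_scale: float | None = None
    texture_amplitude: float = 0.06
    outside_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side % 16:
            raise PhantomParameterError(
                f"side must be divisible by 16, got {self.side}")
        if self.tumor_radius_range is None:
            object.__setattr__(self, "tumor_radius_range",
                               (0.05 * self.side, 0.125 * self.side))
        rmin, rmax = self.tumor_radius_range
        if not (0 < rmin <= rmax):
            raise PhantomParameterError(
                f"invalid tumor_radius_range {self.tumor_radius_range}")
        semi_minor = min(self.brain_axes_fraction) * self.side / 2
        if rmax >= semi_minor:
            raise PhantomParameterError(
                f"max tumor radius {rmax} must be smaller than the brain "
                f"semi-minor axis {semi_minor}")
        for mod, (tm, bm) in self.modality_contrasts.items():
            if not (0 <= tm <= 1 and 0 <= bm <= 1):
                raise PhantomParameterError(
                    f"contrast for {mod} outside [0, 1]: {(tm, bm)}")
        if self.texture_scale is None:
            object.__setattr__(self, "texture_scale", self.side / 8)

    def with_seed(self, seed: int) -> "PhantomParams":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class MultimodalSlice:
    """Four co-registered modality grids plus the binary ground-truth mask.

    ``mask`` may be ``None`` for inference-only slices without ground truth;
    training and evaluation reject such cases.
    """

    modalities: dict[str, np.ndarray]
    mask: np.ndarray | None
    case_id: str

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.modalities.values()}
        if self.mask is not None:
            shapes |= {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"modality/mask shapes differ: {sorted(shapes)}")
        if self.mask is not None:
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask must be binary (0/1)")

    @property
    def side(self) -> int:
        return next(iter(self.modalities.values())).shape[0]

    def stack(self, order: Sequence[str] = MODALITIES) -> np.ndarray:
        """Channel-stacked image, shape ``(len(order), H, W)``."""
        return np.stack([self.modalities[m] for m in order], axis=0)


@dataclass
class PhantomDataset:
    """A list of slices plus a reproducible 80/20 train/validation split."""

    slices: list[MultimodalSlice]
    train_indices: list[int]
    val_indices: list[int]
    master_seed: int

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i: int) -> MultimodalSlice:
        return self.slices[i]

    def __iter__(self):
        return iter(self.slices)

    @property
    def train_slices(self) -> list[MultimodalSlice]:
        return [self.slices[i] for i in self.train_indices]

    @property
    def val_slices(self) -> list[MultimodalSlice]:
        return [self.slices[i] for i in self.val_indices]


def _ellipse_mask(side: int, center: tuple[float, float],
                  semi_axes: tuple[float, float], angle: float) -> np.ndarray:
    rows, cols = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_phantom(params: PhantomParams) -> MultimodalSlice:
    """Generate one multimodal phantom slice.

    The tumor center is drawn uniformly over the locus where the whole tumor
    ellipse fits inside the brain; the same anatomy (brain, tumor, texture)
    is shared across modalities while the additive noise is independent per
    modality, as for separately acquired co-registered sequences.
    """
    rng = np.random.default_rng(params.seed)
    side = params.side
    center = (side / 2, side / 2)
    brain_axes = (params.brain_axes_fraction[0] * side / 2,
                  params.brain_axes_fraction[1] * side / 2)
    # brain ellipse: semi-axes along x (cols) and y (rows)
    brain = _ellipse_mask(side, center, (brain_axes[0], brain_axes[1]), 0.0)

    rmin, rmax = params.tumor_radius_range
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    angle = rng.uniform(0, np.pi)
    margin = max(a, b)
    # sample the center uniformly inside the margin-shrunk brain ellipse
    ax_in = brain_axes[0] - margin
    ay_in = brain_axes[1] - margin
    while True:
        px = rng.uniform(-1, 1)
        py = rng.uniform(-1, 1)
        if px * px + py * py <= 1.0:
            break
    t_center = (center[0] + py * ay_in, center[1] + px * ax_in)
    tumor = _ellipse_mask(side, t_center, (a, b), angle)

    texture = rng.normal(size=(side, side))
    texture = gaussian_filter(texture, params.texture_scale, mode="reflect")
    peak = np.abs(texture).max()
    if peak > 0:
        texture *= params.texture_amplitude / peak

    modalities: dict[str, np.ndarray] = {}
    for mod, (tumor_mean, bg_mean) in params.modality_contrasts.items():
        img = np.full((side, side), params.outside_level)
        img[brain] = bg_mean + texture[brain]
        img[tumor] = tumor_mean + texture[tumor]
        if params.noise_sd > 0:
            img = img + rng.normal(0, params.noise_sd, size=(side, side))
        modalities[mod] = np.clip(img, 0.0, 1.0)

    return MultimodalSlice(modalities=modalities,
                           mask=tumor.astype(np.uint8),
                           case_id=f"phantom-{params.seed:08d}")


def make_dataset(n: int, params: PhantomParams,
                 val_fraction: float = 0.2) -> PhantomDataset:
    """Generate ``n`` slices with per-case seeds spawned deterministically
    from ``params.seed``, plus a seeded train/validation index split."""
    if n < 1:
        raise PhantomParameterError(f"dataset size must be >= 1, got {n}")
    seed_rng = np.random.default_rng(params.seed)
    case_seeds = seed_rng.integers(0, 2**31 - 1, size=n)
    slices = [make_phantom(params.with_seed(s)) for s in case_seeds]
    perm = np.random.default_rng(params.seed + 1).permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    val_idx = sorted(int(i) for i in perm[:n_val])
    train_idx = sorted(int(i) for i in perm[n_val:])
    return PhantomDataset(slices=slices, train_indices=train_idx,
                          val_indices=val_idx, master_seed=params.seed)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255), 0, 255).astype(np.uint8)


def write_case_pngs(case: MultimodalSlice, out_dir: str | Path) -> list[Path]:
    """Write one PNG per modality plus the mask; returns the paths."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mod, img in case.modalities.items():
        p = out_dir / f"{case.case_id}_{mod}.png"
        Image.fromarray(_to_uint8(img)).save(p)
        paths.append(p)
    p = out_dir / f"{case.case_id}_mask.png"
    Image.fromarray(case.mask * np.uint8(255)).save(p)
    paths.append(p)
    return paths


def save_dataset_npz(dataset: PhantomDataset, path: str | Path) -> None:
    """Save the whole dataset to one compressed numeric archive."""
    arrays: dict[str, np.ndarray] = {
        "images": np.stack([s.stack() for s in dataset.slices]).astype(np.float32),
        "masks": np.stack([s.mask for s in dataset.slices]),
        "train_indices": np.asarray(dataset.train_indices, dtype=np.int64),
        "val_indices": np.asarray(dataset.val_indices, dtype=np.int64),
        "master_seed": np.asarray(dataset.master_seed),
        "case_ids": np.asarray([s.case_id for s in dataset.slices]),
        "modality_order": np.asarray(MODALITIES),
    }
    np.savez_compressed(path, **arrays)


def load_dataset_npz(path: str | Path) -> PhantomDataset:
    with np.load(path, allow_pickle=False) as z:
        order = [str(m) for m in z["modality_order"]]
        slices = []
        for img, mask, cid in zip(z["images"], z["masks"], z["case_ids"]):
            slices.append(MultimodalSlice(
                modalities={m: img[i].astype(np.float64)
                            for i, m in enumerate(order)},
                mask=mask.astype(np.uint8),
                case_id=str(cid)))
        return PhantomDataset(
            slices=slices,
            train_indices=[int(i) for i in z["train_indices"]],
            val_indices=[int(i) for i in z["val_indices"]],
            master_seed=int(z["master_seed"]))


def _minmax_norm(img: np.ndarray) -> np.ndarray:
    img = img.astype(np.float64)
    lo, hi = img.min(), img.max()
    return np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)


def load_slice_image(path: str | Path, axial_index: int | None = None,
                     normalize: bool = True) -> np.ndarray:
    """Read a 2D axial slice from a MetaImage (.mha/.mhd) or NIfTI file.

    3D volumes are sliced along their last (axial) axis at ``axial_index``
    (defaults to the middle slice).  Intensities are min–max normalized to
    [0, 1] unless ``normalize=False`` (masks).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
        # SimpleITK array axis order is (z, y, x): axial axis first
        if vol.ndim == 3:
            idx = vol.shape[0] // 2 if axial_index is None else axial_index
            img = vol[idx]
        else:
            img = vol
    else:
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            idx = vol.shape[-1] // 2 if axial_index is None else axial_index
            img = vol[..., idx]
        else:
            img = vol
    img = np.asarray(img, dtype=np.float64)
    return _minmax_norm(img) if normalize else img


def load_real_case(modality_paths: Mapping[str, str | Path],
                   mask_path: str | Path, case_id: str = "real-case",
                   axial_index: int | None = None) -> MultimodalSlice:
    """Assemble a :class:`MultimodalSlice` from per-modality image files and
    a ground-truth mask file (any nonzero label counts as tumor)."""
    modalities = {m: load_slice_image(p, axial_index)
                  for m, p in modality_paths.items()}
    mask = load_slice_image(mask_path, axial_index, normalize=False)
    return MultimodalSlice(modalities=modalities,
                           mask=(mask > 0).astype(np.uint8),
                           case_id=case_id)
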