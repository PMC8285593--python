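"""Desk-scale stand-ins for the standard MRI preprocessing steps.

Covers multiplicative bias-field estimation and correction, exclusion
masking, brain volumetry from partial-volume maps, half-way resampling of a
registered image pair, and the correlation-ratio image-similarity cost used
to judge whether two scans of the same head became more alike after
correction.

These are deliberately simple, fully-specified algorithms: a smooth
polynomial model for the bias field rather than an EM tissue/field
decomposition, and analytically known affines rather than a registration
optimiser.  They recover the generator's ground truth, which is the contract
the rest of the pipeline depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product as _iproduct

import numpy as np
from scipy import ndimage
from scipy.linalg import sqrtm

from .volume import Volume

__all__ = [
    "BiasField",
    "SimilarityCost",
    "estimate_bias_field",
    "correct_bias",
    "correlation_ratio",
    "halfway_resample",
    "apply_exclusion_and_brain",
    "total_brain_volume",
]


def _data(x) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    return np.asarray(x, dtype=float)


def _mask(x) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    return np.asarray(x).astype(bool)


@dataclass
class BiasField:
    """Strictly positive multiplicative field, mean one over its fit mask."""

    field: np.ndarray
    order: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.field[self.mask] <= 0):
            raise ValueError("bias field must be strictly positive inside the mask")


@dataclass
class SimilarityCost:
    """Correlation-ratio cost: 0 = functionally dependent, 1 = unrelated."""

    value: float
    n_voxels: int
    flags: list = dc_field(default_factory=list)


def _poly_design(shape, order: int) -> np.ndarray:
    """All 3-D monomials of total degree <= order on [-1, 1] coordinates."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i, j, k in _iproduct(range(order + 1), repeat=3):
        if i + j + k <= order:
            cols.append((grids[0] ** i * grids[1] ** j * grids[2] ** k).ravel())
    return np.column_stack(cols)


def estimate_bias_field(
    image,
    brain_mask,
    order: int = 3,
    *,
    median_radius: int = 1,
    erode_voxels: int | None = None,
    trim_schedule: tuple = (3.0, 2.0, 1.5, 1.5),
) -> BiasField:
    """Estimate the smooth multiplicative inhomogeneity of ``image``.

    Log-intensities are median-filtered (radius ``median_radius`` voxels) to
    suppress fine structure, and a 3-D polynomial of total degree ``order``
    is fit by least squares on an eroded interior of the brain mask (the
    cortical shell's systematic intensity offset would otherwise masquerade
    as field).  The fit is re-run over a shrinking robust-trimming schedule
    so that tissue with a large log-offset from the dominant compartment
    (CSF, lesions) is excluded.  The field is ``exp`` of the fitted surface,
    renormalised to mean one over the brain mask.

    The polynomial model resolves fields whose spatial scale is no finer
    than roughly a quarter of the grid extent; steeper inhomogeneities need
    a higher ``order``.
    """
    img = _data(image)
    mask = _mask(brain_mask)
    if order < 0:
        raise ValueError("order must be >= 0")
    if not mask.any():
        raise ValueError("brain mask is empty")
    bad = int(np.sum(img[mask] <= 0))
    if bad:
        raise ValueError(f"{bad} non-positive voxel(s) inside the brain mask")

    filled = img.copy()
    filled[~mask] = np.median(img[mask])
    log_img = ndimage.median_filter(np.log(filled), size=2 * median_radius + 1)

    if erode_voxels is None:
        erode_voxels = max(2, round(min(img.shape) / 8))
    interior = ndimage.binary_erosion(mask, iterations=erode_voxels)
    if interior.sum() < 500:
        interior = mask

    X = _poly_design(img.shape, order)
    sel = interior.copy()
    fit = np.zeros(img.shape)
    for t in trim_schedule:
        beta, *_ = np.linalg.lstsq(X[sel.ravel()], log_img.ravel()[sel.ravel()], rcond=None)
        fit = (X @ beta).reshape(img.shape)
        resid = log_img - fit
        med = np.median(resid[sel])
        s = 1.4826 * np.median(np.abs(resid[sel] - med))
        if s <= 0:
            break
        new = interior & (np.abs(resid - med) < t * s)
        if new.sum() < max(300, 3 * X.shape[1]):
            break
        sel = new

    field = np.exp(fit - fit[mask].mean())
    field = field / field[mask].mean()
    return BiasField(field=field, order=order, mask=mask)


def correct_bias(image, field: BiasField):
    """Divide by the field inside its mask; leave the outside untouched."""
    img = _data(image)
    f = field.field if isinstance(field, BiasField) else _data(field)
    m = field.mask if isinstance(field, BiasField) else np.ones(img.shape, bool)
    if img.shape != f.shape:
        raise ValueError("image and field shapes differ")
    if np.any(f[m] == 0):
        raise ValueError("bias field contains zeros inside the mask")
    out = img.copy()
    out[m] = img[m] / f[m]
    if hasattr(image, "affine"):
        return Volume(out, image.affine)
    return out


def _cr_one_direction(cond: np.ndarray, dep: np.ndarray, bins: int):
    """1 - (between-bin variance of ``dep`` given binned ``cond``)/Var(dep)."""
    total_var = dep.var()
    if total_var == 0:
        return 1.0, True
    lo, hi = cond.min(), cond.max()
    if hi == lo:
        return 1.0, True
    idx = np.minimum((bins * (cond - lo) / (hi - lo)).astype(int), bins - 1)
    counts = np.bincount(idx, minlength=bins)
    sums = np.bincount(idx, weights=dep, minlength=bins)
    nz = counts > 0
    means = sums[nz] / counts[nz]
    between = np.sum(counts[nz] * (means - dep.mean()) ** 2) / dep.size
    return float(np.clip(1.0 - between / total_var, 0.0, 1.0)), False


def correlation_ratio(image_a, image_b, mask, bins: int = 64) -> SimilarityCost:
    """Symmetric correlation-ratio cost between two images over a mask.

    Lower values mean the images are more alike (up to any per-bin intensity
    mapping); the symmetric variant averages the two conditioning directions.
    """
    a, b, m = _data(image_a), _data(image_b), _mask(mask)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("image/mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    av, bv = a[m], b[m]
    c_ab, flag_ab = _cr_one_direction(av, bv, bins)
    c_ba, flag_ba = _cr_one_direction(bv, av, bins)
    flags = []
    if flag_ab or flag_ba:
        flags.append("constant_image")
    return SimilarityCost(value=float((c_ab + c_ba) / 2.0), n_voxels=int(m.sum()), flags=flags)


def _half_matrix(affine_ab: np.ndarray) -> np.ndarray:
    A = np.asarray(affine_ab, dtype=float)
    if A.shape != (4, 4):
        raise ValueError("affine_ab must be 4x4")
    if np.linalg.det(A[:3, :3]) <= 0:
        raise ValueError("affine with non-positive determinant has no real half-transform")
    H = sqrtm(A)
    if np.iscomplexobj(H):
        if np.abs(H.imag).max() > 1e-8:
            raise ValueError("affine has no real principal square root")
        H = H.real
    return H


def _resample(data: np.ndarray, T: np.ndarray, order: int) -> np.ndarray:
    """out[o] = in[T[:3,:3] @ o + T[:3,3]] with trilinear/nearest interpolation."""
    return ndimage.affine_transform(
        np.asarray(data, dtype=float), T[:3, :3], offset=T[:3, 3],
        order=order, mode="constant", cval=0.0,
    )


def halfway_resample(image_a, image_b, affine_ab, *, order: int = 1):
    """Resample both images into the space half-way between their grids.

    ``affine_ab`` maps voxel coordinates of ``image_a``'s grid onto
    ``image_b``'s.  With ``H = sqrt(affine_ab)`` (principal matrix square
    root), the half-way grid point ``o`` samples ``image_a`` at ``H^{-1} o``
    and ``image_b`` at ``H o``, so each image is interpolated exactly once.
    """
    a, b = _data(image_a), _data(image_b)
    H = _half_matrix(affine_ab)
    a_half = _resample(a, np.linalg.inv(H), order)
    b_half = _resample(b, H, order)
    if hasattr(image_a, "affine"):
        return Volume(a_half, image_a.affine), Volume(b_half, image_a.affine)
    return a_half, b_half


def apply_exclusion_and_brain(image_or_mask, brain_mask, exclusion_mask):
    """Zero voxels outside the brain or inside the exclusion mask."""
    img = _data(image_or_mask)
    brain = _mask(brain_mask)
    excl = _mask(exclusion_mask)
    if img.shape != brain.shape or img.shape != excl.shape:
        raise ValueError("shapes differ")
    out = img * (brain & ~excl)
    if hasattr(image_or_mask, "affine"):
        return Volume(out, image_or_mask.affine)
    return out


def total_brain_volume(tissue_pv, voxel_volume: float | None = None) -> float:
    """Total brain volume (mm^3) as the sum of the three tissue-class volumes.

    ``tissue_pv`` is a mapping of partial-volume maps (GM/WM/CSF) as used to
    normalise lesion loads into percentages.
    """
    maps = list(tissue_pv.values()) if hasattr(tissue_pv, "values") else list(tissue_pv)
    if len(maps) != 3:
        raise ValueError("expected three partial-volume maps (GM, WM, CSF)")
    arrays = [_data(m) for m in maps]
    if voxel_volume is None:
        vol_obj = maps[0]
        voxel_volume = vol_obj.voxel_volume if hasattr(vol_obj, "voxel_volume") else 1.0
    for arr in arrays:
        if arr.min() < 0 or arr.max() > 1 + 1e-6:
            raise ValueError("partial-volume values must lie in [0, 1]")
    total = sum(arrays)
    if total.max() > 1 + 1e-6:
        raise ValueError("partial volumes sum to more than 1 somewhere")
    return float(total.sum() * voxel_volume)
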