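"""Agreement measures between an automatic and a reference lesion mask.

Five measures are reported: the Dice similarity index, voxel-level false
positive/negative ratios, and cluster-level false positive/negative ratios
(a cluster is a connected component; a detected cluster counts as a false
positive when it shares no voxel with the reference, and a reference
cluster as a false negative when no detected cluster touches it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["OverlapMetrics", "dice", "voxel_rates", "cluster_rates", "evaluate_masks"]


def _binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x.data if isinstance(x, Volume) else x)
    out = arr.astype(bool)
    return out


def _check_shapes(a: np.ndarray, r: np.ndarray) -> None:
    if a.shape != r.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {r.shape}")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class OverlapMetrics:
    dice: float
    fpr_voxel: float
    fnr_voxel: float
    fpr_cluster: float
    fnr_cluster: float
    n_auto_clusters: int
    n_ref_clusters: int
    flags: list = field(default_factory=list)


def dice(auto, ref) -> float:
    """2|A∩R| / (|A|+|R|); defined as 1 when both masks are empty."""
    a, r = _binary(auto, "auto"), _binary(ref, "ref")
    _check_shapes(a, r)
    denom = a.sum() + r.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, r).sum() / denom)


def voxel_rates(auto, ref) -> tuple[float, float]:
    """(FPR, FNR): fraction of detected voxels that are spurious, and of
    reference voxels that are missed.  Empty denominators yield 0."""
    a, r = _binary(auto, "auto"), _binary(ref, "ref")
    _check_shapes(a, r)
    na, nr = int(a.sum()), int(r.sum())
    fpr = float(np.logical_and(a, ~r).sum() / na) if na else 0.0
    fnr = float(np.logical_and(r, ~a).sum() / nr) if nr else 0.0
    return fpr, fnr


def cluster_rates(auto, ref, connectivity: int = 26):
    """Cluster-level (FPR, FNR, n_auto_clusters, n_ref_clusters).

    Overlap criterion: at least one shared voxel.  Empty denominators yield
    a rate of 0.
    """
    a, r = _binary(auto, "auto"), _binary(ref, "ref")
    _check_shapes(a, r)
    s = _structure(connectivity)
    lab_a, n_a = ndimage.label(a, structure=s)
    lab_r, n_r = ndimage.label(r, structure=s)
    if n_a:
        touched_a = np.unique(lab_a[r & a])
        hit_a = len(touched_a[touched_a > 0])
        fpr_c = (n_a - hit_a) / n_a
    else:
        fpr_c = 0.0
    if n_r:
        touched_r = np.unique(lab_r[a & r])
        hit_r = len(touched_r[touched_r > 0])
        fnr_c = (n_r - hit_r) / n_r
    else:
        fnr_c = 0.0
    return float(fpr_c), float(fnr_c), int(n_a), int(n_r)


def evaluate_masks(auto, ref, connectivity: int = 26) -> OverlapMetrics:
    """All five agreement measures in one record, with edge-case flags."""
    a, r = _binary(auto, "auto"), _binary(ref, "ref")
    _check_shapes(a, r)
    flags = []
    if not a.any() and not r.any():
        flags.append("both_masks_empty")
    elif not a.any():
        flags.append("auto_mask_empty")
    elif not r.any():
        flags.append("ref_mask_empty")
    fpr_v, fnr_v = voxel_rates(a, r)
    fpr_c, fnr_c, n_a, n_r = cluster_rates(a, r, connectivity)
    return OverlapMetrics(
        dice=dice(a, r),
        fpr_voxel=fpr_v,
        fnr_voxel=fnr_v,
        fpr_cluster=fpr_c,
        fnr_cluster=fnr_c,
        n_auto_clusters=n_a,
        n_ref_clusters=n_r,
        flags=flags,
    )
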