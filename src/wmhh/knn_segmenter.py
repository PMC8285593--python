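"""Supervised k-nearest-neighbour voxel classifier for WMH segmentation.

The classifier follows the BIANCA design: every candidate voxel (inside the
brain, outside the exclusion mask) is described by intensity features from
one or more modalities (the voxel value and the mean over a small cubic
patch, both z-scored per subject inside the brain mask) plus its spatial
coordinates scaled by a weighting coefficient.  The lesion probability of a
voxel is the fraction of lesion-labelled points among its ``k`` nearest
training points in feature space; thresholding the probability map yields
the binary lesion mask.

Fixed defaults follow the published parameterisation: 2000 lesion and 10000
non-lesion training points, patch size 3, spatial weight 2, ``k`` = 40.

The neighbour search is exact.  Ties at the k-th distance are broken by
training-point index order, and this contract is honoured bit-for-bit (it is
what makes the classifier reproducible and testable against a brute-force
oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .synthetic_cohort import SubjectRecord
from .volume import Volume

__all__ = [
    "FeatureConfig",
    "TrainingSet",
    "ProbabilityMap",
    "ProvenanceSummary",
    "extract_features",
    "build_training_set",
    "classify",
    "threshold_map",
    "wmh_percent",
    "neighbour_provenance",
]


@dataclass(frozen=True)
class FeatureConfig:
    modalities: tuple[str, ...] = ("FLAIR", "T1", "FA")
    patch_size: int = 3
    spatial_weight: float = 2.0
    normalisation: bool = True  # per-subject z-scoring inside the brain mask

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 1")
        if self.spatial_weight < 0:
            raise ValueError("spatial_weight must be >= 0")
        if "FLAIR" not in self.modalities:
            raise ValueError("FLAIR is the reference modality and must be present")


@dataclass
class TrainingSet:
    features: np.ndarray  # (n_points, n_features)
    labels: np.ndarray  # 1 = lesion, 0 = non-lesion
    source_site: np.ndarray  # per-point site label
    source_subject: np.ndarray  # per-point subject id
    strategy: str
    config: FeatureConfig
    seed: int | None = None

    @property
    def n_lesion(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonlesion(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ProbabilityMap:
    volume: Volume  # values in [0, 1], multiples of 1/k
    k: int
    candidate_mask: np.ndarray


@dataclass
class ProvenanceSummary:
    site_fractions: dict  # site -> mean fraction of neighbours over voxels
    per_subject: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------


def _zscore(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu = data[mask].mean()
    sd = data[mask].std()
    if sd == 0:
        sd = 1.0
    return (data - mu) / sd


def extract_features(subject: SubjectRecord, cfg: FeatureConfig):
    """Per-voxel feature matrix for candidate voxels (brain minus exclusion).

    Returns ``(features, flat_indices, candidate_mask)`` where ``features``
    has, per modality, the z-scored voxel intensity and patch mean, followed
    by the three spatially-weighted normalised world coordinates.
    """
    missing = [m for m in cfg.modalities if m not in subject.volumes]
    if missing:
        raise ValueError(f"missing modalit{'y' if len(missing)==1 else 'ies'}: {missing}")
    brain = subject.brain_mask.data.astype(bool)
    excl = subject.exclusion_mask.data.astype(bool)
    candidate = brain & ~excl
    flat_idx = np.flatnonzero(candidate)

    cols = []
    for m in cfg.modalities:
        data = np.asarray(subject.volumes[m].data, dtype=float)
        z = _zscore(data, brain) if cfg.normalisation else data
        cols.append(z.ravel()[flat_idx])
        if cfg.patch_size == 1:
            cols.append(cols[-1])
        else:
            patch = ndimage.uniform_filter(z, size=cfg.patch_size, mode="nearest")
            cols.append(patch.ravel()[flat_idx])

    shape = brain.shape
    ii, jj, kk = np.unravel_index(flat_idx, shape)
    vox = np.column_stack([ii, jj, kk]).astype(float)
    affine = subject.brain_mask.affine
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    bi, bj, bk = np.nonzero(brain)
    brain_world = np.column_stack([bi, bj, bk]).astype(float) @ affine[:3, :3].T + affine[:3, 3]
    mu = brain_world.mean(axis=0)
    sd = brain_world.std(axis=0)
    sd[sd == 0] = 1.0
    spatial = (world - mu) / sd * cfg.spatial_weight
    cols.extend(spatial.T)
    return np.column_stack(cols), flat_idx, candidate


# --------------------------------------------------------------------------
# training-set composition
# --------------------------------------------------------------------------


def _allocate(counts_total: int, n_groups: int) -> list[int]:
    """Equal allocation with remainder distributed round-robin."""
    base, rem = divmod(counts_total, n_groups)
    return [base + (1 if g < rem else 0) for g in range(n_groups)]


def _sample_subject_points(subject, mask, cfg, n_les, n_non, rng):
    feats, flat_idx, candidate = extract_features(subject, cfg)
    lesion_flat = np.flatnonzero(np.asarray(mask).astype(bool).ravel())
    pos = {v: i for i, v in enumerate(flat_idx)}
    les_rows = np.array([pos[v] for v in lesion_flat if v in pos], dtype=int)
    non_rows = np.setdiff1d(np.arange(len(flat_idx)), les_rows)
    if n_les > len(les_rows):
        raise ValueError(
            f"subject {subject.subject_id}: requested {n_les} lesion points "
            f"but only {len(les_rows)} lesion voxels are available"
        )
    if n_non > len(non_rows):
        raise ValueError(
            f"subject {subject.subject_id}: requested {n_non} non-lesion points "
            f"but only {len(non_rows)} are available"
        )
    sel_les = rng.choice(les_rows, size=n_les, replace=False) if n_les else np.array([], int)
    sel_non = rng.choice(non_rows, size=n_non, replace=False) if n_non else np.array([], int)
    rows = np.concatenate([sel_les, sel_non])
    labels = np.concatenate([np.ones(n_les, int), np.zeros(n_non, int)])
    return feats[rows], labels


def build_training_set(
    subjects: Sequence[SubjectRecord],
    masks: Sequence,
    strategy: str,
    *,
    n_lesion: int = 2000,
    n_nonlesion: int = 10000,
    cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    site: str | None = None,
) -> TrainingSet:
    """Sample a labelled training set under one of the three compositions.

    ``single_site`` and ``site_specific`` draw the full point budget from one
    site's labelled subjects (for ``site_specific`` the target ``site`` must
    be named); ``mixed`` draws one pooled set with the budget stratified
    equally across the contributing sites.  Within each site the budget is
    split equally across subjects, remainder round-robin; sampling is
    without replacement.
    """
    if strategy not in ("single_site", "site_specific", "mixed"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(subjects) != len(masks):
        raise ValueError("subjects and masks must be parallel sequences")
    subjects = list(subjects)
    masks = [np.asarray(m.data if isinstance(m, Volume) else m) for m in masks]

    if strategy in ("single_site", "site_specific"):
        sites_present = sorted({s.site_id for s in subjects})
        if strategy == "site_specific":
            if site is None:
                raise ValueError("site_specific strategy requires a target site")
            if site not in sites_present:
                raise ValueError(f"unknown site {site!r}; have {sites_present}")
            keep = [i for i, s in enumerate(subjects) if s.site_id == site]
        else:
            if site is not None and site not in sites_present:
                raise ValueError(f"unknown site {site!r}; have {sites_present}")
            src = site or sites_present[0]
            keep = [i for i, s in enumerate(subjects) if s.site_id == src]
        groups = {subjects[keep[0]].site_id: keep}
        quotas = {subjects[keep[0]].site_id: (n_lesion, n_nonlesion)}
    else:
        groups = {}
        for i, s in enumerate(subjects):
            groups.setdefault(s.site_id, []).append(i)
        site_names = sorted(groups)
        les_alloc = _allocate(n_lesion, len(site_names))
        non_alloc = _allocate(n_nonlesion, len(site_names))
        quotas = {s: (les_alloc[j], non_alloc[j]) for j, s in enumerate(site_names)}

    rng = np.random.default_rng(seed)
    feats_all, labels_all, site_all, subj_all = [], [], [], []
    for site_name in sorted(groups):
        idxs = groups[site_name]
        q_les, q_non = quotas[site_name]
        les_per = _allocate(q_les, len(idxs))
        non_per = _allocate(q_non, len(idxs))
        for j, i in enumerate(idxs):
            f, lab = _sample_subject_points(
                subjects[i], masks[i], cfg, les_per[j], non_per[j], rng
            )
            feats_all.append(f)
            labels_all.append(lab)
            site_all.append(np.full(len(lab), site_name, dtype=object))
            subj_all.append(np.full(len(lab), subjects[i].subject_id, dtype=object))

    return TrainingSet(
        features=np.vstack(feats_all),
        labels=np.concatenate(labels_all),
        source_site=np.concatenate(site_all),
        source_subject=np.concatenate(subj_all),
        strategy=strategy,
        config=cfg,
        seed=seed,
    )


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def _kneighbors(query: np.ndarray, train: np.ndarray, k: int, chunk: int = 2048) -> np.ndarray:
    """Exact k nearest training rows per query row, Euclidean distance.

    Ties at the k-th distance are broken by training-point index order.
    Squared distances are computed in float64 via the inner-product
    expansion, which is exact for the tie-constructed integer instances the
    contract is verified on.
    """
    train = np.asarray(train, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64)
    n_train = len(train)
    if k > n_train:
        raise ValueError(f"k={k} exceeds {n_train} available training points")
    tt = np.einsum("ij,ij->i", train, train)
    out = np.empty((len(query), k), dtype=np.int64)
    for start in range(0, len(query), chunk):
        q = query[start:start + chunk]
        d2 = np.einsum("ij,ij->i", q, q)[:, None] - 2.0 * (q @ train.T) + tt[None, :]
        if k == n_train:
            sel = np.broadcast_to(np.arange(n_train), d2.shape).copy()
        else:
            part = np.argpartition(d2, k - 1, axis=1)[:, :k]
            kth = np.take_along_axis(d2, part, axis=1).max(axis=1)
            n_within = (d2 <= kth[:, None]).sum(axis=1)
            sel = np.sort(part, axis=1)
            tied = np.nonzero(n_within > k)[0]
            for r in tied:
                cand = np.flatnonzero(d2[r] <= kth[r])
                order = np.lexsort((cand, d2[r, cand]))
                sel[r] = cand[order[:k]]
        out[start:start + chunk] = sel
    return out


def classify(
    subject: SubjectRecord,
    training: TrainingSet,
    k: int = 40,
    cfg: FeatureConfig | None = None,
    *,
    loo: bool = False,
) -> ProbabilityMap:
    """Lesion-probability map: fraction of lesion labels among k neighbours.

    With ``loo`` set, training points contributed by the test subject are
    removed before the search (leave-one-out evaluation).
    """
    cfg = cfg or training.config
    feats, flat_idx, candidate = extract_features(subject, cfg)
    train_feats = training.features
    labels = training.labels
    if loo:
        keep = training.source_subject != subject.subject_id
        train_feats = train_feats[keep]
        labels = labels[keep]
    if train_feats.shape[1] != feats.shape[1]:
        raise ValueError("feature dimensionality mismatch between training set and subject")
    if k > len(train_feats):
        raise ValueError(f"k={k} exceeds {len(train_feats)} training points after exclusions")
    neigh = _kneighbors(feats, train_feats, k)
    prob = labels[neigh].sum(axis=1) / float(k)
    vol = np.zeros(candidate.shape)
    vol.ravel()[flat_idx] = prob
    return ProbabilityMap(
        volume=Volume(vol, subject.brain_mask.affine), k=k, candidate_mask=candidate
    )


def threshold_map(prob: ProbabilityMap, thr: float = 0.9) -> np.ndarray:
    """Binary lesion mask: probability >= thr, inside the candidate region."""
    if not 0 <= thr <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return (prob.volume.data >= thr) & prob.candidate_mask


def wmh_percent(lesion_mask, brain_volume_mm3: float, voxel_volume: float) -> float:
    """Lesion load as a percentage of total brain volume."""
    if brain_volume_mm3 <= 0:
        raise ValueError("brain volume must be positive")
    mask = np.asarray(lesion_mask.data if isinstance(lesion_mask, Volume) else lesion_mask)
    lesion_mm3 = float(mask.astype(bool).sum() * voxel_volume)
    if lesion_mm3 > brain_volume_mm3:
        raise ValueError("lesion volume exceeds brain volume")
    return 100.0 * lesion_mm3 / brain_volume_mm3


def neighbour_provenance(
    subject: SubjectRecord,
    training: TrainingSet,
    k: int = 40,
    cfg: FeatureConfig | None = None,
    *,
    loo: bool = False,
) -> ProvenanceSummary:
    """Mean per-site fraction of the k neighbours over classified voxels."""
    cfg = cfg or training.config
    feats, _, _ = extract_features(subject, cfg)
    train_feats = training.features
    source_site = training.source_site
    if loo:
        keep = training.source_subject != subject.subject_id
        train_feats = train_feats[keep]
        source_site = source_site[keep]
    if k > len(train_feats):
        raise ValueError(f"k={k} exceeds {len(train_feats)} training points after exclusions")
    neigh = _kneighbors(feats, train_feats, k)
    sites = sorted(set(source_site))
    fractions = {}
    neigh_sites = source_site[neigh]
    for s in sites:
        fractions[s] = float((neigh_sites == s).mean())
    return ProvenanceSummary(site_fractions=fractions,
                             per_subject={subject.subject_id: dict(fractions)})
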