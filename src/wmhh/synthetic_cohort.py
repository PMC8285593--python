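"""Seeded synthetic multi-site cohort generator.

Builds multi-modal brain phantoms (FLAIR, T1, optional FA) with known ground
truth so that every downstream stage — bias-field correction, supervised
lesion segmentation, overlap metrics and the harmonisation statistics — can
be exercised and tested without access to any real imaging study.

The generator separates, by construction, the two sources of variability the
harmonisation pipeline is meant to disentangle:

* **biology** (identical across sites): an age-dependent white-matter
  hyperintensity (WMH) load following a log-linear model
  ``log(WMH%) = intercept + slope * (age - age_ref) + noise``, split into
  periventricular and deep lesion clusters;
* **site/scanner effects**: per-modality multiplicative gain and additive
  offset, a smooth multiplicative bias field of configurable amplitude and
  smoothness, and additive Gaussian noise.

Because biology is shared, any between-site difference in *measured* WMH load
is, by design, a harmonisation failure — which is exactly what the
statistical battery downstream quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume

__all__ = [
    "SiteSpec",
    "BiologySpec",
    "RaterProfile",
    "SubjectRecord",
    "TravelingPair",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "simulate_rater_mask",
    "generate_traveling_heads",
    "sample_wmh_percent",
]

DEFAULT_SHAPE = (48, 48, 48)

#: tissue mean intensities per modality; FLAIR/T1 in arbitrary scanner units,
#: FA unitless in [0, 1].  Lesions are hyperintense on FLAIR, mildly
#: hypointense on T1 and carry reduced anisotropy.
DEFAULT_TISSUE_MEANS: dict[str, dict[str, float]] = {
    "WM": {"FLAIR": 100.0, "T1": 120.0, "FA": 0.45},
    "GM": {"FLAIR": 115.0, "T1": 90.0, "FA": 0.15},
    "CSF": {"FLAIR": 30.0, "T1": 40.0, "FA": 0.05},
    "LESION": {"FLAIR": 125.0, "T1": 108.0, "FA": 0.28},
}

#: modalities that receive scanner gain/offset/bias/noise.  FA is a derived
#: quantitative map, so scanner intensity effects are not applied to it; it
#: only receives a small additive noise floor.
SCANNER_MODALITIES = ("FLAIR", "T1")
FA_NOISE_SD = 0.01


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------


def _as_modality_map(value, modalities: Sequence[str], default: float) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {m: float(value.get(m, default)) for m in modalities}
    return {m: float(value) for m in modalities}


@dataclass
class SiteSpec:
    """Non-biological scanner/site effects plus the site's age distribution."""

    site_id: str
    gain: float | Mapping[str, float] = 1.0
    offset: float | Mapping[str, float] = 0.0
    bias_amplitude: float = 0.0  # peak-to-trough fractional amplitude
    bias_smoothness: float = 12.0  # voxels
    noise_sd: float = 0.0  # intensity units
    age_mean: float = 65.0
    age_sd: float = 6.0
    age_min: float = 45.0
    age_max: float = 90.0
    n_subjects: int = 10
    covariate_style: str = "wh"  # raw-unit convention: "wh" or "ukb"

    def __post_init__(self) -> None:
        gains = _as_modality_map(self.gain, SCANNER_MODALITIES, 1.0)
        if any(g <= 0 for g in gains.values()):
            raise ValueError("gain must be > 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")

    def gain_for(self, modality: str) -> float:
        if modality == "FA":
            return 1.0
        return _as_modality_map(self.gain, SCANNER_MODALITIES, 1.0)[modality]

    def offset_for(self, modality: str) -> float:
        if modality == "FA":
            return 0.0
        return _as_modality_map(self.offset, SCANNER_MODALITIES, 0.0)[modality]


@dataclass
class BiologySpec:
    """Age-dependent lesion-load model, identical across sites by design."""

    wmh_intercept: float = 0.0  # log(% of brain volume) at age_ref: 1% at 65 y
    wmh_age_slope: float = 0.06  # per-year change in log lesion load
    wmh_noise_sd: float = 0.25  # sd of the log-load residual
    age_ref: float = 65.0  # years; centre of the log-linear model
    lesion_count_rate: float = 6.0  # expected lesion clusters per subject
    periventricular_fraction: float = 0.5
    tissue_intensity_means: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_TISSUE_MEANS.items()}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.periventricular_fraction <= 1:
            raise ValueError("periventricular_fraction must lie in [0, 1]")
        if self.lesion_count_rate <= 0:
            raise ValueError("lesion_count_rate must be > 0")


@dataclass
class RaterProfile:
    """Stochastic model of a human annotator's deviations from truth."""

    rater_id: str
    boundary_jitter_sd: float = 0.0  # voxels
    miss_prob_small: float = 0.0  # probability of omitting a small lesion
    size_threshold: int = 0  # voxels; "small" means strictly below this
    dilation_bias: float = 0.0  # +: over-segmentation, -: under (voxels)

    def __post_init__(self) -> None:
        if not 0 <= self.miss_prob_small <= 1:
            raise ValueError("miss_prob_small must lie in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")


@dataclass
class SubjectRecord:
    """All volumes, masks, site label, covariates and truth for one subject."""

    subject_id: str
    site_id: str
    age: float
    covariates: dict
    volumes: dict  # modality -> Volume
    brain_mask: Volume
    exclusion_mask: Volume
    true_lesion_mask: Volume
    tissue_pv: dict  # tissue -> Volume (GM/WM/CSF partial volumes)
    manual_masks: dict = field(default_factory=dict)  # rater_id -> Volume
    bias_field: Volume | None = None  # ground-truth applied field
    clean_volumes: dict = field(default_factory=dict)  # pre-bias/noise images
    true_wmh_percent: float = 0.0
    true_brain_volume_mm3: float = 0.0
    rigid_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def voxel_volume(self) -> float:
        return self.brain_mask.voxel_volume


@dataclass
class TravelingPair:
    """One anatomy rendered under two site effects with a known rigid offset."""

    subject_id: str
    image_a: Volume
    image_b: Volume
    brain_mask_a: Volume
    brain_mask_b: Volume
    affine_ab: np.ndarray  # voxel-coordinate map: a-grid -> b-grid
    field_a: Volume
    field_b: Volume


@dataclass
class Cohort:
    subjects: list
    covariate_tables: dict  # site_id -> DataFrame in site raw units
    covariate_units: dict  # site_id -> {variable: unit}
    labelled_ids: dict  # site_id -> list of subject_ids with manual masks
    seed: int

    def by_site(self, site_id: str) -> list:
        return [s for s in self.subjects if s.site_id == site_id]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def labelled_subjects(self, site_id: str) -> list:
        wanted = set(self.labelled_ids.get(site_id, []))
        return [s for s in self.subjects if s.subject_id in wanted]


# --------------------------------------------------------------------------
# anatomy
# --------------------------------------------------------------------------


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _make_anatomy(shape: tuple[int, int, int]):
    """Ellipsoidal brain with a central ventricle proxy and a cortical shell.

    Returns hard tissue partial-volume maps (softened at boundaries by a
    small Gaussian blur and renormalised to sum to one inside the brain),
    the brain mask and the exclusion mask (cortical grey-matter proxy).
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 8:
        raise ValueError(f"degenerate grid {shape}: need >= 8 voxels per axis")
    center = [(n - 1) / 2.0 for n in shape]
    brain_ax = [0.44 * n for n in shape]
    brain = _ellipsoid(shape, center, brain_ax)
    inner = _ellipsoid(shape, center, [0.86 * a for a in brain_ax])
    ventricle = _ellipsoid(
        shape, center, [0.10 * shape[0], 0.20 * shape[1], 0.10 * shape[2]]
    )
    gm = brain & ~inner
    csf = ventricle & brain
    wm = brain & ~gm & ~csf

    pv = {}
    raw = {"GM": gm, "WM": wm, "CSF": csf}
    blurred = {t: ndimage.gaussian_filter(m.astype(float), 0.6) for t, m in raw.items()}
    total = sum(blurred.values())
    for t, b in blurred.items():
        m = np.zeros(shape)
        inside = brain & (total > 0)
        m[inside] = b[inside] / total[inside]
        pv[t] = m
    exclusion = pv["GM"] > 0.5
    return pv, brain, exclusion, ventricle


def _bias_field(shape, amplitude: float, smoothness: float, rng, brain: np.ndarray) -> np.ndarray:
    """Smooth strictly-positive multiplicative field.

    Exponential of a band-limited Gaussian random field, rescaled so that the
    max/min ratio over the brain equals ``1 + amplitude`` and renormalised to
    mean one over the brain.
    """
    noise = rng.standard_normal(shape)
    if amplitude <= 0:
        return np.ones(shape)
    g = ndimage.gaussian_filter(noise, smoothness)
    g = g - g[brain].mean()
    span = g[brain].max() - g[brain].min()
    if span <= 0:
        return np.ones(shape)
    g = g * (np.log1p(amplitude) / span)
    f = np.exp(g)
    return f / f[brain].mean()


# --------------------------------------------------------------------------
# lesions
# --------------------------------------------------------------------------


def sample_wmh_percent(age: float | np.ndarray, biology: BiologySpec, rng) -> np.ndarray:
    """Draw true WMH load (% of brain volume) from the log-linear age model."""
    age = np.asarray(age, dtype=float)
    eps = rng.normal(0.0, biology.wmh_noise_sd, size=age.shape)
    pct = np.exp(biology.wmh_intercept + biology.wmh_age_slope * (age - biology.age_ref) + eps)
    return np.clip(pct, 1e-4, 99.9)


def _grow_cluster(seed_idx, size, eligible, occupied, shape, rng) -> np.ndarray:
    """Jittered nearest-ball growth: approximately spherical, connected blobs."""
    size = int(size)
    radius = int(np.ceil((3 * size / (4 * np.pi)) ** (1 / 3))) + 3
    lo = [max(0, s - radius) for s in seed_idx]
    hi = [min(n, s + radius + 1) for s, n in zip(seed_idx, shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_ok = eligible[box] & ~occupied[box]
    coords = np.argwhere(sub_ok)
    if coords.size == 0:
        return np.zeros(0, dtype=np.int64)
    origin = np.array([s - a for s, a in zip(seed_idx, lo)], dtype=float)
    d = np.linalg.norm(coords - origin, axis=1) + 0.3 * rng.standard_normal(len(coords))
    take = coords[np.argsort(d, kind="stable")[:size]]
    flat = np.ravel_multi_index(
        tuple(take[:, i] + lo[i] for i in range(3)), shape
    )
    return flat


def _place_lesions(target_voxels, biology, wm_core, ventricle, exclusion, rng, shape):
    eligible = wm_core & ~exclusion
    n_eligible = int(eligible.sum())
    if target_voxels > 0.5 * n_eligible:
        raise ValueError(
            f"lesion volume of {target_voxels} voxels exceeds half the eligible "
            f"white matter ({n_eligible} voxels); lower the load or enlarge the grid"
        )
    mask = np.zeros(shape, dtype=bool)
    if target_voxels <= 0:
        return mask
    n_clusters = max(1, int(rng.poisson(biology.lesion_count_rate)))
    weights = rng.gamma(1.5, size=n_clusters)
    sizes = np.maximum(1, np.round(target_voxels * weights / weights.sum()).astype(int))

    rim = ndimage.binary_dilation(ventricle, iterations=2) & eligible & ~ventricle
    rim_idx = np.argwhere(rim)
    deep = eligible & ~ndimage.binary_dilation(ventricle, iterations=4)
    deep_idx = np.argwhere(deep)
    for size in sizes:
        periventricular = rng.random() < biology.periventricular_fraction
        pool = rim_idx if (periventricular and len(rim_idx)) else deep_idx
        if len(pool) == 0:
            pool = np.argwhere(eligible)
        seed_idx = pool[rng.integers(len(pool))]
        flat = _grow_cluster(tuple(seed_idx), size, eligible, mask, shape, rng)
        if flat.size:
            mask.flat[flat] = True
    return mask


# --------------------------------------------------------------------------
# subject and cohort generation
# --------------------------------------------------------------------------


def generate_subject(
    site: SiteSpec,
    biology: BiologySpec,
    age: float,
    seed,
    *,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    modalities: Sequence[str] = ("FLAIR", "T1", "FA"),
    subject_id: str | None = None,
    lesion_free: bool = False,
    covariates: dict | None = None,
) -> SubjectRecord:
    """Render one synthetic subject under the given site's scanner effects."""
    rng = np.random.default_rng(seed)
    affine = np.diag(list(spacing) + [1.0])
    pv, brain, exclusion, ventricle = _make_anatomy(shape)
    voxel_vol = float(np.prod(spacing))
    brain_vol_mm3 = float(sum(m.sum() for m in pv.values()) * voxel_vol)

    if lesion_free:
        wmh_pct = 0.0
        lesion = np.zeros(shape, dtype=bool)
    else:
        wmh_pct = float(sample_wmh_percent(np.array(age), biology, rng))
        target = int(round(wmh_pct / 100.0 * brain_vol_mm3 / voxel_vol))
        wm_core = pv["WM"] > 0.5
        lesion = _place_lesions(target, biology, wm_core, ventricle, exclusion, rng, shape)
        wmh_pct = float(100.0 * lesion.sum() * voxel_vol / brain_vol_mm3)

    field = _bias_field(shape, site.bias_amplitude, site.bias_smoothness, rng, brain)

    means = biology.tissue_intensity_means
    volumes: dict[str, Volume] = {}
    clean: dict[str, Volume] = {}
    for m in modalities:
        tissue_map = sum(pv[t] * means[t][m] for t in ("GM", "WM", "CSF"))
        tissue_map = np.where(lesion, means["LESION"][m], tissue_map)
        clean_img = tissue_map * site.gain_for(m) + site.offset_for(m)
        clean_img = clean_img * brain  # background zero
        if m == "FA":
            img = clean_img + rng.normal(0.0, FA_NOISE_SD, shape) * brain
        else:
            img = clean_img * field
            if site.noise_sd > 0:
                img = img + rng.normal(0.0, site.noise_sd, shape) * brain
        clean[m] = Volume(clean_img, affine)
        volumes[m] = Volume(img, affine)

    return SubjectRecord(
        subject_id=subject_id or f"{site.site_id}_sub",
        site_id=site.site_id,
        age=float(age),
        covariates=dict(covariates or {}),
        volumes=volumes,
        brain_mask=Volume(brain.astype(np.uint8), affine),
        exclusion_mask=Volume(exclusion.astype(np.uint8), affine),
        true_lesion_mask=Volume(lesion.astype(np.uint8), affine),
        tissue_pv={t: Volume(pv[t], affine) for t in pv},
        bias_field=Volume(field, affine),
        clean_volumes=clean,
        true_wmh_percent=wmh_pct,
        true_brain_volume_mm3=brain_vol_mm3,
    )


def _truncated_normal_ages(site: SiteSpec, n: int, rng) -> np.ndarray:
    ages = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            a = rng.normal(site.age_mean, site.age_sd)
            if site.age_min <= a <= site.age_max:
                ages[i] = a
                break
        else:  # pragma: no cover - pathological spec
            ages[i] = np.clip(site.age_mean, site.age_min, site.age_max)
    return ages


def _raw_covariates(style: str, latent: dict, rng) -> tuple[dict, dict]:
    """Express latent harmonised covariates in a site's raw-unit convention.

    ``wh`` style records activity in h/week, height in metres and binary
    smoker status; ``ukb`` style uses day/week + min/day activity fields,
    height in cm, TV time in h/day and a four-class smoker status — mirroring
    the kind of unit heterogeneity a cross-cohort merge has to resolve.
    """
    units: dict[str, str] = {}
    row: dict[str, object] = {}
    if style == "wh":
        row["height"] = round(latent["height_m"], 2)
        units["height"] = "m"
        row["moderate_activity"] = round(latent["moderate_h_week"], 2)
        units["moderate_activity"] = "h/week"
        row["vigorous_activity"] = round(latent["vigorous_h_week"], 2)
        units["vigorous_activity"] = "h/week"
        row["tv_time"] = round(latent["tv_h_week"], 2)
        units["tv_time"] = "h/week"
        row["smoker_status"] = "smoker" if latent["smoker"] else "non_smoker"
        units["smoker_status"] = "binary"
    elif style == "ukb":
        row["height"] = int(round(latent["height_m"] * 100))
        units["height"] = "cm"
        days = int(np.clip(rng.integers(1, 8), 1, 7))
        row["moderate_activity_days_week"] = days
        row["moderate_activity_min_day"] = int(
            round(latent["moderate_h_week"] * 60.0 / days)
        )
        units["moderate_activity_days_week"] = "day/week"
        units["moderate_activity_min_day"] = "min/day"
        row["vigorous_activity_min_day"] = int(round(latent["vigorous_h_week"] * 60.0 / 7.0))
        units["vigorous_activity_min_day"] = "min/day"
        row["tv_time_h_day"] = round(latent["tv_h_week"] / 7.0, 2)
        units["tv_time_h_day"] = "h/day"
        if latent["smoker"]:
            row["smoker_status"] = "current"
        else:
            row["smoker_status"] = str(rng.choice(["never", "previous", "prefer_not"], p=[0.7, 0.25, 0.05]))
        units["smoker_status"] = "4-class"
    else:
        raise ValueError(f"unknown covariate style {style!r}")
    return row, units


def _latent_covariates(rng, age: float) -> dict:
    return {
        "height_m": float(rng.normal(1.72, 0.08)),
        "moderate_h_week": float(rng.gamma(2.0, 2.5)),
        "vigorous_h_week": float(rng.gamma(1.5, 1.5)),
        "tv_h_week": float(rng.gamma(3.0, 3.0)),
        "smoker": bool(rng.random() < 0.08),
        "sex": "M" if rng.random() < 0.5 else "F",
        "sbp": float(rng.normal(130 + 0.4 * (age - 65), 15)),
    }


def generate_cohort(
    sites: Sequence[SiteSpec],
    biology: BiologySpec,
    raters: Sequence[RaterProfile] = (),
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    modalities: Sequence[str] = ("FLAIR", "T1", "FA"),
    labelled_per_site: int | Mapping[str, int] = 0,
    labelled_raters: Mapping[str, Sequence[str]] | None = None,
    labelled_selection: str = "by_load",
) -> Cohort:
    """Generate a full multi-site cohort with covariate tables in raw units.

    ``labelled_per_site`` subjects per site receive manual masks simulated
    from the raters named in ``labelled_raters[site_id]`` (default: all
    supplied raters).  ``labelled_selection`` picks which subjects are
    annotated: ``"by_load"`` takes the highest-lesion-load subjects
    (annotation sets in multi-site studies are load-matched, and training
    needs subjects with enough lesion voxels); ``"first"`` takes them in
    generation order.
    """
    if labelled_selection not in ("by_load", "first"):
        raise ValueError("labelled_selection must be 'by_load' or 'first'")
    sites = list(sites)
    if not sites:
        raise ValueError("at least one site is required")
    profiles = {r.rater_id: r for r in raters}
    if labelled_raters:
        for sid, names in labelled_raters.items():
            unknown = [n for n in names if n not in profiles]
            if unknown:
                raise ValueError(f"unknown rater profile(s) {unknown} for site {sid}")

    master = np.random.SeedSequence(seed)
    subjects: list[SubjectRecord] = []
    tables: dict[str, pd.DataFrame] = {}
    units_by_site: dict[str, dict] = {}
    labelled_ids: dict[str, list[str]] = {}

    for site, site_ss in zip(sites, master.spawn(len(sites))):
        site_rng = np.random.default_rng(site_ss)
        ages = _truncated_normal_ages(site, site.n_subjects, site_rng)
        n_lab = (
            labelled_per_site.get(site.site_id, 0)
            if isinstance(labelled_per_site, Mapping)
            else int(labelled_per_site)
        )
        n_lab = min(n_lab, site.n_subjects)
        rater_names = list(
            (labelled_raters or {}).get(site.site_id, list(profiles))
        )
        rows = []
        site_units: dict[str, str] = {"age": "years", "sex": "binary", "sbp": "mmHg"}
        labelled_ids[site.site_id] = []
        subj_seeds = site_ss.spawn(site.n_subjects)
        site_records = []
        rater_seeds = {}
        for i, (age, sub_ss) in enumerate(zip(ages, subj_seeds)):
            sid = f"{site.site_id}_{i:03d}"
            latent = _latent_covariates(site_rng, age)
            raw, raw_units = _raw_covariates(site.covariate_style, latent, site_rng)
            site_units.update(raw_units)
            child = sub_ss.spawn(1 + len(rater_names))
            rec = generate_subject(
                site,
                biology,
                age,
                child[0],
                shape=shape,
                modalities=modalities,
                subject_id=sid,
                covariates={"sex": latent["sex"], "sbp": latent["sbp"], **raw},
            )
            rater_seeds[sid] = child[1:]
            site_records.append(rec)
            rows.append({"subject_id": sid, "age": round(float(age), 1),
                         "sex": latent["sex"], "sbp": round(latent["sbp"], 1), **raw})
        if n_lab and rater_names:
            if labelled_selection == "by_load":
                chosen = sorted(site_records, key=lambda r: -r.true_wmh_percent)[:n_lab]
            else:
                chosen = site_records[:n_lab]
            for rec in sorted(chosen, key=lambda r: r.subject_id):
                for rname, r_ss in zip(rater_names, rater_seeds[rec.subject_id]):
                    rec.manual_masks[rname] = Volume(
                        simulate_rater_mask(
                            rec.true_lesion_mask.data,
                            profiles[rname],
                            r_ss,
                            brain_mask=rec.brain_mask.data.astype(bool),
                        ).astype(np.uint8),
                        rec.brain_mask.affine,
                    )
                labelled_ids[site.site_id].append(rec.subject_id)
        subjects.extend(site_records)
        tables[site.site_id] = pd.DataFrame(rows)
        units_by_site[site.site_id] = site_units

    return Cohort(
        subjects=subjects,
        covariate_tables=tables,
        covariate_units=units_by_site,
        labelled_ids=labelled_ids,
        seed=seed,
    )


# --------------------------------------------------------------------------
# rater simulation
# --------------------------------------------------------------------------


def simulate_rater_mask(true_mask, profile: RaterProfile, seed, brain_mask=None) -> np.ndarray:
    """Simulate a manual annotation of ``true_mask``.

    Small lesion clusters (connected components below ``size_threshold``)
    are independently omitted with probability ``miss_prob_small``; the
    surviving mask's boundary is then moved by ``dilation_bias`` voxels
    (signed distance offset) and jittered by a smooth random field whose
    pointwise sd is ``boundary_jitter_sd`` voxels.
    """
    rng = np.random.default_rng(seed)
    if isinstance(true_mask, Volume):
        true_mask = true_mask.data
    mask = np.asarray(true_mask).astype(bool)
    if mask.sum() == 0:
        return np.zeros_like(mask)

    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    keep = mask.copy()
    if n and profile.size_threshold > 0:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        for lab, size in zip(range(1, n + 1), sizes):
            if size < profile.size_threshold and rng.random() < profile.miss_prob_small:
                keep[labels == lab] = False
    if keep.sum() == 0:
        return np.zeros_like(mask)

    # signed distance to the mask surface (voxel-centre convention: the
    # boundary sits half a voxel from the nearest centres on either side)
    sdist = ndimage.distance_transform_edt(keep) - ndimage.distance_transform_edt(~keep)
    sdist = sdist - 0.5 * np.sign(sdist)
    perturb = sdist + profile.dilation_bias
    if profile.boundary_jitter_sd > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 1.5)
        sd = noise.std()
        if sd > 0:
            perturb = perturb + noise * (profile.boundary_jitter_sd / sd)
    out = perturb > 0
    if brain_mask is not None:
        out &= np.asarray(brain_mask).astype(bool)
    return out


# --------------------------------------------------------------------------
# traveling heads
# --------------------------------------------------------------------------


def generate_traveling_heads(
    site_a: SiteSpec,
    site_b: SiteSpec,
    n: int,
    seed,
    *,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    modality: str = "FLAIR",
    offset_voxels: Sequence[float] | None = None,
) -> list[TravelingPair]:
    """Lesion-free subjects rendered under two site effects.

    Each pair shares one anatomy; the second rendering is shifted by a known
    rigid offset (default: one integer voxel along each axis) so that
    half-way resampling has real work to do.  ``affine_ab`` maps voxel
    coordinates of the first image's grid onto the second's.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.SeedSequence(seed)
    biology = BiologySpec()
    pairs: list[TravelingPair] = []
    t = np.array([1.0, 1.0, -1.0] if offset_voxels is None else offset_voxels, dtype=float)
    for i, ss in enumerate(master.spawn(n)):
        s_a, s_b = ss.spawn(2)
        age = 30.0 + 2.0 * i
        # identical anatomy: same anatomy seed, different scanner seeds
        anat_seed = ss.spawn(1)[0]
        rec_a = generate_subject(site_a, biology, age, _combined_seed(anat_seed, s_a),
                                 shape=shape, modalities=(modality,),
                                 subject_id=f"th_{i}_a", lesion_free=True)
        rec_b = generate_subject(site_b, biology, age, _combined_seed(anat_seed, s_b),
                                 shape=shape, modalities=(modality,),
                                 subject_id=f"th_{i}_b", lesion_free=True)
        img_b = _shift(rec_b.volumes[modality].data, t, order=1)
        mask_b = _shift(rec_b.brain_mask.data.astype(float), t, order=0) > 0.5
        field_b = _shift(rec_b.bias_field.data, t, order=1)
        affine_ab = np.eye(4)
        affine_ab[:3, 3] = t
        aff = rec_a.brain_mask.affine
        pairs.append(
            TravelingPair(
                subject_id=f"th_{i}",
                image_a=rec_a.volumes[modality],
                image_b=Volume(img_b, aff),
                brain_mask_a=rec_a.brain_mask,
                brain_mask_b=Volume(mask_b.astype(np.uint8), aff),
                affine_ab=affine_ab,
                field_a=rec_a.bias_field,
                field_b=Volume(field_b, aff),
            )
        )
    return pairs


def _combined_seed(anat_ss: np.random.SeedSequence, scanner_ss: np.random.SeedSequence):
    """Same anatomy across the pair, independent scanner noise.

    ``generate_subject`` draws anatomy-determining variates (lesions) before
    scanner variates from one stream, so for lesion-free traveling heads the
    anatomy is fixed by construction and only the scanner stream matters;
    we simply use the scanner seed, keeping the anatomy seed for provenance.
    """
    del anat_ss
    return scanner_ss


def _shift(data: np.ndarray, t: np.ndarray, order: int) -> np.ndarray:
    """Translate so that out[x] = in[x - t] (content moves by +t)."""
    return ndimage.affine_transform(
        np.asarray(data, dtype=float), np.eye(3), offset=-t, order=order,
        mode="constant", cval=0.0,
    )
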