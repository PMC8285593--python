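"""End-to-end harmonisation experiments on a synthetic multi-site cohort.

Two scenarios are orchestrated, mirroring the two settings a longitudinal
imaging study meets in practice:

* **upgrade** — two sites standing in for a scanner upgrade within one
  cohort, compared across five analysis options:
  (A) no bias correction, single-site training, FA included;
  (B) bias correction, single-site training, FA included;
  (C) bias correction, site-specific training, FA included;
  (D) bias correction, mixed training, FA included;
  (E) bias correction, mixed training, FA excluded.
* **merge** — three sites standing in for a retrospective merge of two
  cohorts, compared across two options (single-site training is not carried
  forward): (A) site-specific and (B) mixed training, both bias-corrected,
  FA excluded.

For each option the pipeline is: (optional) bias-field correction ->
feature extraction -> training-set composition -> leave-one-out k-NN
classification of the labelled evaluation subset (overlap metrics) ->
full-cohort segmentation and WMH% -> the statistical battery (ANCOVA +
Johnson–Neyman, Elastic-Net variance attribution), plus a mixed ANOVA of
segmentation accuracy across site x option and the non-imaging cohort
comparison.  Everything is driven by one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import image_preproc as pp
from . import knn_segmenter as knn
from . import nonimaging
from .harmonisation_stats import (
    ancova_wmh_age,
    elastic_net_variance,
    johnson_neyman_all,
    mixed_anova,
    paired_ttest,
)
from .overlap_metrics import dice as dice_index, evaluate_masks
from .synthetic_cohort import (
    BiologySpec,
    Cohort,
    RaterProfile,
    SiteSpec,
    generate_cohort,
)
from .volume import Volume

__all__ = [
    "OptionConfig",
    "ScenarioConfig",
    "UPGRADE_OPTIONS",
    "MERGE_OPTIONS",
    "default_upgrade_config",
    "default_merge_config",
    "prepare_cohort",
    "run_option",
    "rater_experiment",
    "run_scenario",
    "save_report",
]


@dataclass(frozen=True)
class OptionConfig:
    option_id: str
    bias_correction: bool
    training_strategy: str  # single_site | site_specific | mixed
    with_fa: bool


UPGRADE_OPTIONS = (
    OptionConfig("A", False, "single_site", True),
    OptionConfig("B", True, "single_site", True),
    OptionConfig("C", True, "site_specific", True),
    OptionConfig("D", True, "mixed", True),
    OptionConfig("E", True, "mixed", False),
)

MERGE_OPTIONS = (
    OptionConfig("A", True, "site_specific", False),
    OptionConfig("B", True, "mixed", False),
)


@dataclass
class ScenarioConfig:
    scenario: str  # "upgrade" | "merge"
    sites: tuple
    biology: BiologySpec
    raters: tuple
    training_rater: dict  # site_id -> rater_id for designated training masks
    labelled_per_site: int = 12
    shape: tuple = (32, 32, 32)
    n_lesion: int = 300
    n_nonlesion: int = 1500
    k: int = 40
    threshold: float = 0.9
    bias_order: int = 3
    age_filter: tuple | None = None  # optional (lo, hi) age-matched subset
    seed: int = 0

    @property
    def options(self) -> tuple:
        return UPGRADE_OPTIONS if self.scenario == "upgrade" else MERGE_OPTIONS

    @property
    def modalities(self) -> tuple:
        return ("FLAIR", "T1", "FA")


# Scaled-down default study conditions.  Site effects (gain, offset, bias
# amplitude, noise) differ between sites; biology is shared.  Each site's
# designated training masks come from its own rater, whose annotation habits
# differ — as they do when cohorts are labelled by different people.
_RATERS = (
    RaterProfile("R1", boundary_jitter_sd=0.6, miss_prob_small=0.3,
                 size_threshold=6, dilation_bias=0.6),
    RaterProfile("R2a", boundary_jitter_sd=0.5, miss_prob_small=0.2,
                 size_threshold=6, dilation_bias=-0.6),
    RaterProfile("R2b", boundary_jitter_sd=0.5, miss_prob_small=0.2,
                 size_threshold=6, dilation_bias=-0.4),
    RaterProfile("RU", boundary_jitter_sd=0.6, miss_prob_small=0.25,
                 size_threshold=6, dilation_bias=0.3),
)


def _upgrade_sites():
    return (
        SiteSpec("SC1", gain=1.0, offset=0.0, bias_amplitude=0.1,
                 bias_smoothness=8.0, noise_sd=2.0, age_mean=69.0, age_sd=5.0,
                 age_min=60.0, age_max=85.0, n_subjects=30, covariate_style="wh"),
        SiteSpec("SC2", gain=1.15, offset=8.0, bias_amplitude=0.6,
                 bias_smoothness=8.0, noise_sd=3.0, age_mean=70.0, age_sd=5.0,
                 age_min=60.0, age_max=85.0, n_subjects=20, covariate_style="wh"),
    )


def _merge_sites():
    s1, s2 = _upgrade_sites()
    s1 = SiteSpec(**{**asdict(s1), "n_subjects": 20})
    s2 = SiteSpec(**{**asdict(s2), "n_subjects": 14})
    ukb = SiteSpec("UKB", gain=0.9, offset=-5.0, bias_amplitude=0.35,
                   bias_smoothness=8.0, noise_sd=2.5, age_mean=61.0, age_sd=7.0,
                   age_min=46.0, age_max=80.0, n_subjects=30, covariate_style="ukb")
    return s1, s2, ukb


def default_upgrade_config(seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        scenario="upgrade", sites=_upgrade_sites(), biology=BiologySpec(),
        raters=_RATERS[:3], training_rater={"SC1": "R1", "SC2": "R2a"}, seed=seed,
    )


def default_merge_config(seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        scenario="merge", sites=_merge_sites(), biology=BiologySpec(),
        raters=_RATERS, training_rater={"SC1": "R1", "SC2": "R2a", "UKB": "RU"},
        seed=seed,
    )


# --------------------------------------------------------------------------
# cohort preparation
# --------------------------------------------------------------------------


def prepare_cohort(cfg: ScenarioConfig) -> Cohort:
    """Generate the cohort and precompute bias-corrected volumes.

    Corrected FLAIR/T1 volumes (estimated field, not the generator's truth)
    are cached per subject under ``corrected_volumes`` so that every
    bias-corrected option reuses them.
    """
    labelled_raters = {s.site_id: _site_raters(cfg, s.site_id) for s in cfg.sites}
    cohort = generate_cohort(
        cfg.sites, cfg.biology, cfg.raters, cfg.seed,
        shape=cfg.shape, modalities=cfg.modalities,
        labelled_per_site=cfg.labelled_per_site,
        labelled_raters=labelled_raters,
    )
    for rec in cohort.subjects:
        brain = rec.brain_mask.data.astype(bool)
        corrected = {}
        for m in ("FLAIR", "T1"):
            fld = pp.estimate_bias_field(rec.volumes[m].data, brain, cfg.bias_order)
            corrected[m] = Volume(pp.correct_bias(rec.volumes[m].data, fld),
                                  rec.volumes[m].affine)
        if "FA" in rec.volumes:
            corrected["FA"] = rec.volumes["FA"]
        rec.corrected_volumes = corrected  # type: ignore[attr-defined]
    return cohort


def _site_raters(cfg: ScenarioConfig, site_id: str) -> list[str]:
    """Raters that annotate a site: its designated trainer first.

    The first upgrade-scenario site also gets the full rater panel, which
    the rater experiment needs (multiple annotations of the same scans).
    """
    names = [cfg.training_rater[site_id]]
    if cfg.scenario == "upgrade" and site_id == cfg.sites[0].site_id:
        names = ["R1", "R2a", "R2b"]
        if cfg.training_rater[site_id] not in names:
            names.insert(0, cfg.training_rater[site_id])
    return names


def _subject_for_option(rec, option: OptionConfig):
    """View of a subject with the option's image set (BC on/off, FA or not)."""
    vols = rec.corrected_volumes if option.bias_correction else rec.volumes
    mods = ("FLAIR", "T1", "FA") if option.with_fa else ("FLAIR", "T1")
    from dataclasses import replace
    view = replace(rec, volumes={m: vols[m] for m in mods})
    return view


# --------------------------------------------------------------------------
# option execution
# --------------------------------------------------------------------------


@dataclass
class OptionResult:
    option: OptionConfig
    metrics: pd.DataFrame  # per labelled subject: five overlap measures
    wmh: pd.DataFrame  # per subject: site, age, wmh_percent
    ancova: dict
    jn: dict
    enet: dict


def _training_sets(cohort: Cohort, cfg: ScenarioConfig, option: OptionConfig,
                   feat_cfg: knn.FeatureConfig, seed: int) -> dict:
    """site_id -> TrainingSet used for that site under this option."""
    site_ids = [s.site_id for s in cfg.sites]
    labelled = {
        sid: [( _subject_for_option(rec, option),
                rec.manual_masks[cfg.training_rater[sid]].data)
              for rec in cohort.labelled_subjects(sid)]
        for sid in site_ids
    }
    out = {}
    if option.training_strategy == "single_site":
        subs, masks = zip(*labelled[site_ids[0]])
        ts = knn.build_training_set(subs, masks, "single_site",
                                    n_lesion=cfg.n_lesion, n_nonlesion=cfg.n_nonlesion,
                                    cfg=feat_cfg, seed=seed)
        out = {sid: ts for sid in site_ids}
    elif option.training_strategy == "site_specific":
        for sid in site_ids:
            subs, masks = zip(*labelled[sid])
            out[sid] = knn.build_training_set(subs, masks, "site_specific",
                                              n_lesion=cfg.n_lesion,
                                              n_nonlesion=cfg.n_nonlesion,
                                              cfg=feat_cfg, seed=seed, site=sid)
    else:
        subs, masks = [], []
        for sid in site_ids:
            s, m = zip(*labelled[sid])
            subs.extend(s)
            masks.extend(m)
        ts = knn.build_training_set(subs, masks, "mixed",
                                    n_lesion=cfg.n_lesion, n_nonlesion=cfg.n_nonlesion,
                                    cfg=feat_cfg, seed=seed)
        out = {sid: ts for sid in site_ids}
    return out


def run_option(cohort: Cohort, option: OptionConfig, cfg: ScenarioConfig,
               seed: int) -> OptionResult:
    """Run one analysis option end-to-end over the cohort."""
    mods = ("FLAIR", "T1", "FA") if option.with_fa else ("FLAIR", "T1")
    feat_cfg = knn.FeatureConfig(modalities=mods)
    training = _training_sets(cohort, cfg, option, feat_cfg, seed)

    metric_rows = []
    wmh_rows = []
    labelled_all = {sid for ids in cohort.labelled_ids.values() for sid in ids}
    for rec in cohort.subjects:
        view = _subject_for_option(rec, option)
        ts = training[rec.site_id]
        brain_vol = pp.total_brain_volume(rec.tissue_pv)
        # full-cohort segmentation (model applied as trained)
        prob = knn.classify(view, ts, k=cfg.k, cfg=feat_cfg, loo=False)
        mask = knn.threshold_map(prob, cfg.threshold)
        wmh_rows.append({
            "subject_id": rec.subject_id, "site": rec.site_id, "age": rec.age,
            "wmh_percent": knn.wmh_percent(mask, brain_vol, rec.voxel_volume),
        })
        if rec.subject_id in labelled_all:
            # honest evaluation: leave the test subject's points out
            prob_loo = knn.classify(view, ts, k=cfg.k, cfg=feat_cfg, loo=True)
            auto = knn.threshold_map(prob_loo, cfg.threshold)
            ref = rec.manual_masks[cfg.training_rater[rec.site_id]].data
            m = evaluate_masks(auto, ref)
            metric_rows.append({
                "subject_id": rec.subject_id, "site": rec.site_id,
                "option": option.option_id, "dice": m.dice,
                "fpr_voxel": m.fpr_voxel, "fnr_voxel": m.fnr_voxel,
                "fpr_cluster": m.fpr_cluster, "fnr_cluster": m.fnr_cluster,
            })

    wmh = pd.DataFrame(wmh_rows)
    if cfg.age_filter:
        lo, hi = cfg.age_filter
        wmh = wmh[(wmh.age >= lo) & (wmh.age <= hi)].reset_index(drop=True)

    anc = ancova_wmh_age(wmh.wmh_percent, wmh.age, wmh.site)
    age_rng = (float(wmh.age.min()), float(wmh.age.max()))
    jn = johnson_neyman_all(anc, 0.05, age_rng)
    cov = _enet_covariates(cohort, wmh)
    enet = elastic_net_variance(cov, wmh.wmh_percent.to_numpy(), seed=seed)

    return OptionResult(
        option=option,
        metrics=pd.DataFrame(metric_rows),
        wmh=wmh,
        ancova={
            "slope_F": anc.slope_F, "slope_df": list(anc.slope_df), "slope_p": anc.slope_p,
            "intercept_F": anc.intercept_F, "intercept_df": list(anc.intercept_df),
            "intercept_p": anc.intercept_p, "age_mean": anc.age_mean,
        },
        jn={
            "pairs": {f"{a}|{b}": reg.intervals for (a, b), reg in jn["pairs"].items()},
            "intersection": jn["intersection"],
        },
        enet={
            "fractions": enet.fractions, "model_r2": enet.model_r2,
            "site_fraction": enet.site_feature_fraction, "alpha": enet.alpha,
        },
    )


def _enet_covariates(cohort: Cohort, wmh: pd.DataFrame) -> pd.DataFrame:
    """Harmonised non-imaging covariates + site, aligned to the WMH table."""
    frames = []
    for sid, table in cohort.covariate_tables.items():
        style = next(s.covariate_style for s in _cohort_site_specs(cohort, sid))
        rules = nonimaging.default_ruleset(style)
        harm, _ = nonimaging.apply_rules(table, rules, cohort.covariate_units[sid])
        harm = harm.copy()
        harm["site"] = sid
        frames.append(harm)
    full = pd.concat(frames, ignore_index=True)
    full = full.set_index("subject_id").loc[wmh.subject_id].reset_index()
    keep = ["age", "sex", "sbp", "height", "moderate_activity",
            "vigorous_activity", "tv_time", "smoker_status", "site"]
    return full[[c for c in keep if c in full.columns]]


def _cohort_site_specs(cohort: Cohort, sid: str):
    # covariate style is recoverable from the table's columns
    table = cohort.covariate_tables[sid]
    style = "ukb" if "moderate_activity_min_day" in table.columns else "wh"
    yield SiteSpec(site_id=sid, covariate_style=style)


# --------------------------------------------------------------------------
# rater experiment
# --------------------------------------------------------------------------


def rater_experiment(cohort: Cohort, cfg: ScenarioConfig,
                     raters: Sequence[str] = ("R1", "R2a", "R2b"),
                     seed: int = 0) -> dict:
    """Manual-vs-automated annotation-consistency comparison.

    On the first site's labelled subjects (annotated by all three rater
    profiles), computes the Dice agreement between manual masks
    (M1/M2a/M2b) and between the corresponding leave-one-out k-NN outputs
    (B1/B2a/B2b), pairing within subjects.  ``low_load`` flags the subjects
    in the lower half of true lesion load.
    """
    site0 = cfg.sites[0].site_id
    subjects = cohort.labelled_subjects(site0)
    missing = [s.subject_id for s in subjects
               if any(r not in s.manual_masks for r in raters)]
    if missing:
        raise ValueError(f"subjects missing ratings: {missing}")
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects with all ratings")

    feat_cfg = knn.FeatureConfig(modalities=("FLAIR", "T1", "FA"))
    bc_option = OptionConfig("rater", True, "single_site", True)
    views = [_subject_for_option(s, bc_option) for s in subjects]

    auto_masks: dict[str, dict[str, np.ndarray]] = {r: {} for r in raters}
    for rater in raters:
        masks = [s.manual_masks[rater].data for s in subjects]
        # same sampling seed for every rater: output differences are then
        # attributable to the training masks alone
        ts = knn.build_training_set(views, masks, "single_site",
                                    n_lesion=cfg.n_lesion, n_nonlesion=cfg.n_nonlesion,
                                    cfg=feat_cfg, seed=seed)
        for view in views:
            prob = knn.classify(view, ts, k=cfg.k, cfg=feat_cfg, loo=True)
            auto_masks[rater][view.subject_id] = knn.threshold_map(prob, cfg.threshold)

    loads = {s.subject_id: s.true_wmh_percent for s in subjects}
    median_load = float(np.median(list(loads.values())))
    comparisons = {}
    for pair, kind in ((("R1", "R2a"), "between"), (("R1", "R2b"), "between"),
                       (("R2a", "R2b"), "within")):
        if not all(p in raters for p in pair):
            continue
        man, auto, low = [], [], []
        for s in subjects:
            man.append(dice_index(s.manual_masks[pair[0]].data,
                                  s.manual_masks[pair[1]].data))
            auto.append(dice_index(auto_masks[pair[0]][s.subject_id],
                                   auto_masks[pair[1]][s.subject_id]))
            low.append(loads[s.subject_id] < median_load)
        try:
            t = paired_ttest(np.array(auto), np.array(man))
            test = {"t": t.statistic, "df": t.df, "p": t.p}
            if np.array_equal(auto, man):
                test["flag"] = "degenerate"
        except ValueError:
            test = {"t": 0.0, "df": len(man) - 1, "p": 1.0, "flag": "degenerate"}
        comparisons[f"{pair[0]}_vs_{pair[1]}"] = {
            "kind": kind,
            "manual_dice": [float(v) for v in man],
            "auto_dice": [float(v) for v in auto],
            "manual_mean": float(np.mean(man)),
            "auto_mean": float(np.mean(auto)),
            "paired_t_auto_minus_manual": test,
            "low_load": [bool(b) for b in low],
        }
    return comparisons


# --------------------------------------------------------------------------
# scenario
# --------------------------------------------------------------------------


def run_scenario(cfg: ScenarioConfig, *, with_rater_experiment: bool | None = None) -> dict:
    """Run the full option matrix and assemble a machine-readable report."""
    if cfg.scenario not in ("upgrade", "merge"):
        raise ValueError("scenario must be 'upgrade' or 'merge'")
    if with_rater_experiment is None:
        with_rater_experiment = cfg.scenario == "upgrade"
    master = np.random.SeedSequence(cfg.seed)
    opt_seeds = master.generate_state(len(cfg.options) + 1)

    cohort = prepare_cohort(cfg)
    results = {}
    metrics_frames = []
    for option, s in zip(cfg.options, opt_seeds):
        res = run_option(cohort, option, cfg, int(s % (2 ** 31)))
        results[option.option_id] = res
        metrics_frames.append(res.metrics)

    metrics = pd.concat(metrics_frames, ignore_index=True)
    anova = mixed_anova(metrics.rename(columns={"dice": "value"}),
                        dv="value", subject="subject_id",
                        between="site", within="option")
    report = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "options": {
            oid: {
                "config": asdict(res.option),
                "ancova": res.ancova,
                "johnson_neyman": res.jn,
                "elastic_net": res.enet,
                "mean_dice_by_site": res.metrics.groupby("site")["dice"].mean().round(6).to_dict(),
                "mean_wmh_by_site": res.wmh.groupby("site")["wmh_percent"].mean().round(6).to_dict(),
            }
            for oid, res in results.items()
        },
        "mixed_anova_dice": {
            "between_F": anova.between_F, "between_p": anova.between_p,
            "within_F": anova.within_F, "within_p": anova.within_p,
            "interaction_F": anova.interaction_F, "interaction_p": anova.interaction_p,
            "flags": anova.flags,
        },
        "nonimaging": _nonimaging_report(cohort),
    }
    if with_rater_experiment:
        report["rater_experiment"] = rater_experiment(
            cohort, cfg, seed=int(opt_seeds[-1] % (2 ** 31)))
    report["_tables"] = {
        "overlap_metrics": metrics,
        "wmh": {oid: res.wmh for oid, res in results.items()},
    }
    return report


def _nonimaging_report(cohort: Cohort) -> dict:
    site_ids = list(cohort.covariate_tables)
    harmonised = {}
    for sid in site_ids:
        style = "ukb" if "moderate_activity_min_day" in cohort.covariate_tables[sid].columns else "wh"
        rules = nonimaging.default_ruleset(style)
        harmonised[sid], _ = nonimaging.apply_rules(
            cohort.covariate_tables[sid], rules, cohort.covariate_units[sid])
    out = {}
    for i in range(len(site_ids)):
        for j in range(i + 1, len(site_ids)):
            a, b = site_ids[i], site_ids[j]
            comp = nonimaging.compare_cohorts(harmonised[a], harmonised[b])
            out[f"{a}|{b}"] = {
                "excluded": [comp.n_excluded_a, comp.n_excluded_b],
                "skipped": comp.skipped,
                "tests": comp.table.round(6).to_dict(orient="records"),
            }
    return out


def save_report(report: dict, out_dir) -> None:
    """Write the report deterministically (sorted keys, fixed float format)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = report.get("_tables", {})
    summary = {k: v for k, v in report.items() if k != "_tables"}
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if "overlap_metrics" in tables:
        tables["overlap_metrics"].to_csv(out / "overlap_metrics.csv",
                                         index=False, float_format="%.10g")
    for oid, df in tables.get("wmh", {}).items():
        df.to_csv(out / f"wmh_option_{oid}.csv", index=False, float_format="%.10g")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
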