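"""End-to-end study orchestration.

``analyze_study`` runs the full in-memory analysis on a synthetic (or loaded)
study: motion QC -> per-run preprocessing -> seed connectivity -> per-seed
group GLM (simultaneous trait covariates) -> cluster correction -> valence
sorting -> conjunction -> split-half / permutation confirmation -> Kendall-W
concordance between simultaneous and separate models.

``run_study`` wraps it with file I/O, provenance capture and a JSON manifest.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .characterize import ConjunctionMap, ValenceLabelMap, classify_valence, conjunction, local_peaks
from .config import StudyConfig, validate_config
from .confirm import kendalls_w, permutation_test, split_half_verify
from .connectivity import SeedCorrelationMapper
from .datatypes import DOMAIN_NAMES, SubjectRecord
from .group import TraitConnectivityGLM
from .preprocess import RunPreprocessor, qc_motion
from .synth import SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["analyze_study", "analyze_from_stacks", "run_study", "write_results",
           "StudyResults", "validate_config_file"]


@dataclass
class StudyResults:
    config: StudyConfig
    qc: pd.DataFrame
    subjects: list[SubjectRecord]
    z_stacks: dict[str, np.ndarray]  # seed -> (n_subjects, x, y, z)
    glms: dict[str, TraitConnectivityGLM]  # simultaneous model per seed
    separate_glms: dict[tuple[str, str], TraitConnectivityGLM]
    group_masks: dict[str, tuple[np.ndarray, np.ndarray]]  # seed -> (pos, neg)
    domain_masks: dict[tuple[str, str], np.ndarray]
    cluster_tables: dict[tuple[str, str, str], pd.DataFrame]
    valence: dict[tuple[str, str], ValenceLabelMap]
    conjunction: ConjunctionMap
    confirmations: pd.DataFrame
    kendall_w: pd.DataFrame
    peaks: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)


def _collect_subject_maps(study: SyntheticStudy):
    """QC, preprocess and map every subject; returns (qc table, subjects,
    per-seed z stacks)."""
    cfg = study.config
    pre = RunPreprocessor.from_params(cfg.preproc)
    mapper = SeedCorrelationMapper(cfg.seeds)
    qc_rows = []
    subjects: list[SubjectRecord] = []
    maps_by_seed: dict[str, list[np.ndarray]] = {s.name: [] for s in cfg.seeds}
    for profile in study.profiles:
        retained = []
        for run in study.runs_for(profile):
            dec = qc_motion(run, cfg.preproc.qc_threshold_mm)
            qc_rows.append({"run_id": dec.run_id,
                            "max_displacement_mm": dec.max_displacement_mm,
                            "retained": dec.retained})
            if dec.retained:
                retained.append(run)
        if not retained:
            logger.warning("subject %s: no runs pass motion QC; dropped", profile.subject_id)
            continue
        processed = [pre.transform(run) for run in retained]
        smaps = mapper.subject_maps(processed)
        for name, cmap in smaps.items():
            maps_by_seed[name].append(cmap.z)
        subjects.append(SubjectRecord(profile=profile, n_scans=len(retained)))
    qc = pd.DataFrame(qc_rows, columns=["run_id", "max_displacement_mm", "retained"])
    stacks = {name: np.stack(maps) for name, maps in maps_by_seed.items()}
    return qc, subjects, stacks


def _cluster_connections(thresholded: np.ndarray) -> list[np.ndarray]:
    """Split a thresholded map into per-cluster boolean masks (26-connectivity)."""
    labels, n = ndimage.label(thresholded != 0, structure=np.ones((3, 3, 3), bool))
    return [labels == k for k in range(1, n + 1)]


def analyze_study(study: SyntheticStudy, n_perm: int | None = None,
                  confirm_seed: int | None = None,
                  compute_separate: bool = True) -> StudyResults:
    """Run the complete analysis on an instantiated study."""
    t0 = time.time()
    qc, subjects, stacks = _collect_subject_maps(study)
    results = analyze_from_stacks(study.config, subjects, stacks,
                                  study.masks["brain"], n_perm=n_perm,
                                  confirm_seed=confirm_seed,
                                  compute_separate=compute_separate, qc=qc)
    results.timings["subject_maps"] = time.time() - t0
    return results


def analyze_from_stacks(cfg: StudyConfig, subjects: list[SubjectRecord],
                        stacks: dict[str, np.ndarray], brain: np.ndarray,
                        n_perm: int | None = None, confirm_seed: int | None = None,
                        compute_separate: bool = True,
                        qc: pd.DataFrame | None = None) -> StudyResults:
    """Group inference and everything downstream, given per-seed z stacks."""
    timings: dict[str, float] = {}
    if qc is None:
        qc = pd.DataFrame(columns=["run_id", "max_displacement_mm", "retained"])
    affine = cfg.affine
    inf = cfg.inference
    n_perm = cfg.confirm.n_permutations if n_perm is None else n_perm
    confirm_seed = cfg.rng_seed if confirm_seed is None else confirm_seed

    t0 = time.time()
    glms: dict[str, TraitConnectivityGLM] = {}
    group_masks = {}
    domain_masks = {}
    cluster_tables = {}
    valence = {}
    for seed in cfg.seeds:
        glm = TraitConnectivityGLM(mode="simultaneous", cluster_z=inf.cluster_z,
                                   alpha=inf.alpha).fit(stacks[seed.name], subjects,
                                                        brain, affine)
        glms[seed.name] = glm
        pos, neg = glm.group_mean_masks()
        group_masks[seed.name] = (pos, neg)
        for domain in DOMAIN_NAMES:
            sig, tables = glm.domain_significance_mask(domain)
            domain_masks[(seed.name, domain)] = sig
            cluster_tables[(seed.name, domain, "positive")] = tables["positive"]
            cluster_tables[(seed.name, domain, "negative")] = tables["negative"]
            valence[(seed.name, domain)] = classify_valence(sig, pos, neg)
    timings["group_inference"] = time.time() - t0

    # conjunction over domains: per-domain union of significance across seeds
    per_domain_union = []
    for domain in DOMAIN_NAMES:
        u = np.zeros(brain.shape, dtype=bool)
        for seed in cfg.seeds:
            u |= domain_masks[(seed.name, domain)]
        per_domain_union.append(u)
    conj = conjunction(per_domain_union)

    # local peaks of each significant trait effect, in MNI mm
    peak_rows = []
    for seed in cfg.seeds:
        glm = glms[seed.name]
        for domain in DOMAIN_NAMES:
            for sign in ("positive", "negative"):
                table = cluster_tables[(seed.name, domain, sign)]
                if not len(table):
                    continue
                _, thresh = glm.cluster_correct(domain, sign)
                labels, _ = ndimage.label(thresh != 0, structure=np.ones((3, 3, 3), bool))
                pk = local_peaks(np.nan_to_num(glm.z_[domain], nan=0.0), labels, affine)
                pk.insert(0, "seed", seed.name)
                pk.insert(1, "domain", domain)
                pk.insert(2, "sign", sign)
                peak_rows.append(pk)
    peaks = (pd.concat(peak_rows, ignore_index=True) if peak_rows
             else pd.DataFrame(columns=["seed", "domain", "sign", "cluster_id",
                                        "x_mm", "y_mm", "z_mm", "peak_z"]))

    # confirmatory analyses per significant connection
    t0 = time.time()
    conf_rows = []
    conn_index = 0
    for seed in cfg.seeds:
        glm = glms[seed.name]
        for domain in DOMAIN_NAMES:
            scores = np.array([s.profile.scores[domain] for s in subjects])
            for sign in ("positive", "negative"):
                _, thresh = glm.cluster_correct(domain, sign)
                for k, cl_mask in enumerate(_cluster_connections(thresh)):
                    strengths = np.array([
                        np.nanmean(stacks[seed.name][i][cl_mask])
                        for i in range(len(subjects))
                    ])
                    rseed = (confirm_seed + 1000003 * conn_index) % (2 ** 31)
                    conn_index += 1
                    sh = split_half_verify(strengths, scores, rng_seed=rseed)
                    pt = permutation_test(strengths, scores, n_perm=n_perm,
                                          rng_seed=rseed, direction=sign)
                    conf_rows.append({
                        "connection": f"{seed.name}:{domain}:{sign}:cluster{k + 1}",
                        "seed": seed.name, "domain": domain, "sign": sign,
                        "extent_vox": int(cl_mask.sum()),
                        "r_full": sh.r_full, "r_half1": sh.r_half1,
                        "r_half2": sh.r_half2, "split_half_confirmed": sh.confirmed,
                        "permutation_p": pt.p_value,
                    })
    confirmations = pd.DataFrame(
        conf_rows, columns=["connection", "seed", "domain", "sign", "extent_vox",
                            "r_full", "r_half1", "r_half2", "split_half_confirmed",
                            "permutation_p"])
    timings["confirmation"] = time.time() - t0

    # concordance between simultaneous and separate models
    t0 = time.time()
    separate_glms: dict[tuple[str, str], TraitConnectivityGLM] = {}
    kw_rows = []
    if compute_separate:
        for seed in cfg.seeds:
            glm_sim = glms[seed.name]
            for domain in DOMAIN_NAMES:
                glm_sep = TraitConnectivityGLM(mode="separate", domain=domain,
                                               cluster_z=inf.cluster_z,
                                               alpha=inf.alpha).fit(
                    stacks[seed.name], subjects, brain, affine)
                separate_glms[(seed.name, domain)] = glm_sep
                a = glm_sim.z_[domain]
                b = glm_sep.z_[domain]
                ok = brain & np.isfinite(a) & np.isfinite(b)
                w = kendalls_w(np.vstack([a[ok], b[ok]]))
                kw_rows.append({"seed": seed.name, "domain": domain, "kendalls_w": w})
    kendall_w = pd.DataFrame(kw_rows, columns=["seed", "domain", "kendalls_w"])
    timings["concordance"] = time.time() - t0

    return StudyResults(
        config=cfg, qc=qc, subjects=subjects, z_stacks=stacks, glms=glms,
        separate_glms=separate_glms, group_masks=group_masks,
        domain_masks=domain_masks, cluster_tables=cluster_tables, valence=valence,
        conjunction=conj, confirmations=confirmations, kendall_w=kendall_w,
        peaks=peaks, timings=timings,
    )


def validate_config_file(path) -> list[str]:
    """Validate a YAML config file; returns the full list of errors ([] if ok)."""
    try:
        cfg = StudyConfig.from_yaml(str(path))
    except Exception as exc:  # malformed YAML / wrong types
        return [f"could not parse config: {exc}"]
    return validate_config(cfg)


def _save_nifti(path: Path, data, affine) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def run_study(config, out_dir, n_perm: int | None = None) -> dict:
    """Run the whole study from a config (path or StudyConfig) and write the
    report bundle plus a JSON run manifest to ``out_dir``."""
    if not isinstance(config, StudyConfig):
        errs = validate_config_file(config)
        if errs:
            raise ValueError("config validation failed: " + "; ".join(errs))
        cfg = StudyConfig.from_yaml(str(config))
    else:
        cfg = config
        errs = validate_config(cfg)
        if errs:
            raise ValueError("config validation failed: " + "; ".join(errs))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    def stage(name):
        stages.append({"stage": name, "status": "completed", "time": time.time()})

    study = simulate_study(cfg)
    stage("synthesize")
    results = analyze_study(study, n_perm=n_perm)
    stage("analyze")

    outputs = write_results(results, out)
    stage("report")

    manifest = {
        "config_hash": cfg.config_hash(),
        "software_version": __version__,
        "rng_seed": cfg.rng_seed,
        "n_subjects_analyzed": len(results.subjects),
        "stages": stages,
        "outputs": outputs,
        "timings": results.timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_results(results: StudyResults, out_dir) -> dict[str, str]:
    """Write the report bundle for an analyzed study; returns output paths."""
    cfg = results.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = cfg.affine
    outputs: dict[str, str] = {}

    results.qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    outputs["qc"] = "qc.tsv"

    zdir = out / "zmaps"
    zdir.mkdir(exist_ok=True)
    for seed_name, stack in results.z_stacks.items():
        for i, subj in enumerate(results.subjects):
            p = zdir / f"{subj.subject_id}_{seed_name}_zmap.nii.gz"
            _save_nifti(p, np.nan_to_num(stack[i], nan=0.0), affine)
            with open(zdir / f"{subj.subject_id}_{seed_name}_zmap.json", "w") as fh:
                json.dump({"subject": subj.subject_id, "seed": seed_name,
                           "n_runs_averaged": subj.n_scans}, fh)
    outputs["zmaps"] = "zmaps/"

    gdir = out / "group"
    gdir.mkdir(exist_ok=True)
    for (seed_name, domain, sign), table in results.cluster_tables.items():
        table.to_csv(gdir / f"{seed_name}_{domain}_{sign}_clusters.tsv",
                     sep="\t", index=False)
    for seed_name, (pos, neg) in results.group_masks.items():
        _save_nifti(gdir / f"{seed_name}_groupmean_pos.nii.gz", pos.astype(np.int8), affine)
        _save_nifti(gdir / f"{seed_name}_groupmean_neg.nii.gz", neg.astype(np.int8), affine)
    outputs["group"] = "group/"

    vrows = []
    for (seed_name, domain), vmap in results.valence.items():
        _save_nifti(gdir / f"{seed_name}_{domain}_valence.nii.gz", vmap.labels, affine)
        row = {"seed": seed_name, "domain": domain}
        row.update(vmap.histogram)
        vrows.append(row)
    pd.DataFrame(vrows).to_csv(out / "valence_histogram.tsv", sep="\t", index=False)
    outputs["valence_histogram"] = "valence_histogram.tsv"

    _save_nifti(out / "conjunction.nii.gz", results.conjunction.sum_map, affine)
    pd.DataFrame(
        [{"level": k, "n_voxels": v} for k, v in results.conjunction.level_counts.items()]
    ).to_csv(out / "conjunction_levels.tsv", sep="\t", index=False)
    outputs["conjunction"] = "conjunction_levels.tsv"

    results.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    outputs["peaks"] = "peaks.tsv"
    results.confirmations.to_csv(out / "confirmation_report.tsv", sep="\t", index=False)
    outputs["confirmation_report"] = "confirmation_report.tsv"
    results.kendall_w.to_csv(out / "kendall_w.tsv", sep="\t", index=False)
    outputs["kendall_w"] = "kendall_w.tsv"
    return outputs
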