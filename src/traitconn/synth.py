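"""Synthetic resting-state cohort generator.

Generates a full study — five-factor trait phenotypes, geometric brain/tissue
masks, spherical seed regions, and 4D BOLD runs — whose ground truth realizes
the statistical structure the downstream analysis assumes:

* every seed owns a latent band-limited network signal shared by its voxels;
* each planted effect couples a target region to its seed's latent signal
  with per-subject coupling  c = baseline + sum_d slope_d * (score_d - mean_d),
  so the population seed-target correlation equals the coupling exactly;
* shared nuisance processes (low-frequency drift, global, WM and CSF signals,
  a motion-locked artifact) are added on top and are removable by the
  corresponding preprocessing stages;
* observation noise is AR(1)-colored but restricted to the analysis pass-band,
  so the band-pass stage is transparent to the planted couplings and they
  remain the identifiable estimands of the pipeline (out-of-band structure
  enters only through the nuisance processes).

Everything is deterministic given (config rng_seed, subject id, run index).
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import StudyConfig, validate_config
from .datatypes import DOMAIN_NAMES, BoldRun, PlantedEffect, SeedSpec, TraitProfile

__all__ = [
    "generate_trait_scores",
    "generate_bold_run",
    "simulate_study",
    "write_study",
    "read_study",
    "SyntheticStudy",
    "build_masks",
    "effect_target_mask",
]


# ---------------------------------------------------------------------------
# phenotypes


def generate_trait_scores(
    n: int,
    means,
    sds,
    corr,
    rng_seed: int,
    age_range=(19.0, 45.0),
    male_fraction: float = 0.5,
) -> list[TraitProfile]:
    """Draw ``n`` trait profiles from a multivariate normal with the given
    moments; age uniform over ``age_range``, sex Bernoulli(``male_fraction``)."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if means.shape != (5,) or sds.shape != (5,) or corr.shape != (5, 5):
        raise ValueError("means/sds must be 5-vectors and corr a 5x5 matrix")
    if np.any(sds < 0):
        raise ValueError("trait SDs must be non-negative")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    rng = np.random.default_rng(rng_seed)
    # PSD-safe transform (handles singular corr, e.g. all-zero SDs elsewhere)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    z = rng.standard_normal((n, 5)) @ root.T
    scores = means + z * sds
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sexes = (rng.random(n) < male_fraction).astype(int)
    profiles = []
    for i in range(n):
        profiles.append(
            TraitProfile(
                subject_id=f"sub-{i + 1:03d}",
                scores={d: float(scores[i, j]) for j, d in enumerate(DOMAIN_NAMES)},
                age=float(ages[i]),
                sex=int(sexes[i]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# geometry


def _voxel_centers_mm(shape, affine):
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _sphere_mask(shape, affine, center_mm, radius_mm) -> np.ndarray:
    centers = _voxel_centers_mm(shape, affine)
    d2 = ((centers - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    return (d2 <= radius_mm ** 2 + 1e-9).reshape(shape)


def build_masks(cfg: StudyConfig) -> dict[str, np.ndarray]:
    """Geometric brain/WM/CSF masks on the config grid.

    Brain is an ellipsoid filling 92% of the half-extents; "white matter" a
    mid-radius shell and "CSF" a central ventricle-like blob, both at
    probability 0.9 (above the default 0.8 tissue threshold).  These are
    geometric stand-ins, not anatomy: only their role as averaging masks for
    nuisance extraction matters.
    """
    shape = cfg.grid_shape
    affine = cfg.affine
    half_extent = np.asarray(shape, dtype=float) * cfg.voxel_size_mm / 2.0
    semi = 0.92 * half_extent
    centers = _voxel_centers_mm(shape, affine)
    rho = np.sqrt(((centers / semi) ** 2).sum(axis=1)).reshape(shape)
    brain = rho <= 1.0
    wm = np.where((rho >= 0.55) & (rho <= 0.78), 0.9, 0.0)
    csf = np.where(rho <= 0.18, 0.9, 0.0)
    return {"brain": brain, "wm": wm, "csf": csf, "rho": rho}


def effect_target_mask(
    effect: PlantedEffect, cfg: StudyConfig, brain_mask: np.ndarray, halo: bool = False
) -> np.ndarray:
    """Voxel mask of an effect's target region (optionally with the planted
    halo), intersected with the brain mask."""
    r = effect.radius_mm + (cfg.effect_halo_mm if halo else 0.0)
    return _sphere_mask(cfg.grid_shape, cfg.affine, effect.center_mm, r) & brain_mask


def _seed_mask(seed: SeedSpec, cfg: StudyConfig, brain_mask: np.ndarray) -> np.ndarray:
    m = _sphere_mask(cfg.grid_shape, cfg.affine, seed.center_mm, seed.radius_mm) & brain_mask
    if not m.any():
        raise ValueError(f"seed {seed.name!r} voxelizes to an empty set")
    return m


# ---------------------------------------------------------------------------
# temporal building blocks


def _band_indices(n_volumes: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    return (freqs >= f_lo) & (freqs <= f_hi)


def _bandlimited_series(rng, n_series: int, n_volumes: int, amp: np.ndarray) -> np.ndarray:
    """Real series synthesized from complex-Gaussian rFFT coefficients with
    per-bin amplitude ``amp`` (zero outside the band), normalized to unit
    expected variance."""
    n_bins = amp.shape[0]
    coef = (rng.standard_normal((n_series, n_bins))
            + 1j * rng.standard_normal((n_series, n_bins))) * amp
    x = np.fft.irfft(coef, n=n_volumes, axis=1)
    # Var(x_t) = (2 / T^2) * sum_k (2 amp_k^2) for interior bins
    evar = 4.0 * np.sum(amp ** 2) / n_volumes ** 2
    return x / np.sqrt(evar)


def _ar1_band_amplitude(cfg: StudyConfig) -> np.ndarray:
    """rFFT amplitude profile of AR(1) noise restricted to the analysis band."""
    T, tr = cfg.n_volumes, cfg.tr_seconds
    freqs = np.fft.rfftfreq(T, d=tr)
    phi = cfg.noise.ar_coeff
    power = 1.0 / np.abs(1.0 - phi * np.exp(-2j * np.pi * freqs * tr)) ** 2
    amp = np.sqrt(power)
    band = _band_indices(T, tr, cfg.preproc.f_lo_hz, cfg.preproc.f_hi_hz)
    amp[~band] = 0.0
    return amp


def _flat_band_amplitude(cfg: StudyConfig) -> np.ndarray:
    T, tr = cfg.n_volumes, cfg.tr_seconds
    amp = np.ones(T // 2 + 1)
    band = _band_indices(T, tr, cfg.preproc.f_lo_hz, cfg.preproc.f_hi_hz)
    amp[~band] = 0.0
    return amp


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


# ---------------------------------------------------------------------------
# run generation


def _run_rng(cfg: StudyConfig, subject_id: str, run_index: int) -> np.random.Generator:
    subj_key = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(subj_key, run_index))
    )


def generate_bold_run(
    profile: TraitProfile,
    seeds: list[SeedSpec],
    effects: list[PlantedEffect],
    cfg: StudyConfig,
    run_index: int,
    masks: dict[str, np.ndarray] | None = None,
) -> BoldRun:
    """Generate one 4D run for ``profile`` with the planted couplings.

    Deterministic per (cfg.rng_seed, subject_id, run_index).  A motion
    excursion exceeding the QC threshold is injected with probability
    ``cfg.noise.motion_spike_probability`` — only on runs after the first, so
    every subject retains at least one run.
    """
    seed_by_name = {s.name: s for s in seeds}
    for eff in effects:
        if eff.seed_name not in seed_by_name:
            raise ValueError(f"effect {eff.name!r} references unknown seed {eff.seed_name!r}")
    if masks is None:
        masks = build_masks(cfg)
    brain = masks["brain"]
    shape = cfg.grid_shape
    T = cfg.n_volumes
    nm = cfg.noise

    seed_masks = {s.name: _seed_mask(s, cfg, brain) for s in seeds}
    eff_masks = [effect_target_mask(e, cfg, brain, halo=True) for e in effects]
    seed_union = np.zeros(shape, dtype=bool)
    for m in seed_masks.values():
        seed_union |= m
    for eff, m in zip(effects, eff_masks):
        if not m.any():
            raise ValueError(f"effect {eff.name!r} target region is empty")
        if (m & seed_union).any():
            raise ValueError(f"effect {eff.name!r} target region overlaps a seed region")
    for i in range(len(effects)):
        for j in range(i + 1, len(effects)):
            if (eff_masks[i] & eff_masks[j]).any():
                raise ValueError(
                    f"effect regions {effects[i].name!r} and {effects[j].name!r} overlap"
                )

    rng = _run_rng(cfg, profile.subject_id, run_index)
    flat_amp = _flat_band_amplitude(cfg)
    noise_amp = _ar1_band_amplitude(cfg)

    # latent network signal per seed (unit variance, band-limited)
    latents = {s.name: _bandlimited_series(rng, 1, T, flat_amp)[0] for s in seeds}

    # shared nuisance processes
    tt = np.arange(T, dtype=float)
    lin = _standardize(tt)
    quad = _standardize((tt - tt.mean()) ** 2)
    slow = np.sin(2 * np.pi * 0.004 * tt * cfg.tr_seconds + rng.uniform(0, 2 * np.pi))
    drift_coefs = rng.standard_normal(3)
    drift = _standardize(drift_coefs[0] * lin + drift_coefs[1] * quad
                         + drift_coefs[2] * _standardize(slow))
    global_sig = _standardize(rng.standard_normal(T))
    wm_sig = _standardize(rng.standard_normal(T))
    csf_sig = _standardize(rng.standard_normal(T))

    # motion: slow random walk, rotations ~100x smaller (radians)
    steps = rng.normal(0.0, nm.motion_walk_mm, size=(T, 6))
    steps[:, 3:] /= 100.0
    motion = np.cumsum(steps, axis=0)
    motion -= motion[0]
    spiked = run_index > 0 and rng.random() < nm.motion_spike_probability
    spike_vol = 0
    if spiked:
        spike_vol = int(rng.integers(1, T))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        motion[spike_vol, :3] += direction * (nm.motion_spike_mm + 1.0)
    gammas = rng.standard_normal(6)
    artifact = motion @ gammas
    artifact = _standardize(artifact) if artifact.std() > 0 else artifact

    # per-voxel observation noise, AR(1)-colored within the analysis band
    brain_idx = np.flatnonzero(brain.ravel())
    n_brain = brain_idx.size
    signal = _bandlimited_series(rng, n_brain, T, noise_amp)

    flat_of_full = np.full(np.prod(shape), -1, dtype=np.int64)
    flat_of_full[brain_idx] = np.arange(n_brain)

    def rows(mask3d):
        return flat_of_full[np.flatnonzero(mask3d.ravel())]

    # seed voxels: latent + small voxel noise
    for s in seeds:
        r = rows(seed_masks[s.name])
        signal[r] = latents[s.name] + nm.seed_noise_sigma * signal[r]
    # target voxels: coupled mixture with unit variance
    trait_means = {d: m for d, m in zip(DOMAIN_NAMES, np.asarray(cfg.trait_means, float))}
    couplings = {}
    for eff, m in zip(effects, eff_masks):
        c = eff.baseline_coupling
        for d, slope in eff.trait_slope.items():
            c += slope * (profile.scores[d] - trait_means[d])
        c = float(np.clip(c, -1.0, 1.0))
        couplings[eff.name] = c
        r = rows(m)
        u = latents[eff.seed_name]
        signal[r] = c * u + np.sqrt(1.0 - c ** 2) * signal[r]

    wm_w = masks["wm"].ravel()[brain_idx]
    csf_w = masks["csf"].ravel()[brain_idx]
    fluct = (
        signal
        + nm.drift_amplitude * drift
        + nm.global_amplitude * global_sig
        + nm.motion_artifact_amplitude * artifact
        + np.outer(wm_w, nm.wm_amplitude * wm_sig)
        + np.outer(csf_w, nm.csf_amplitude * csf_sig)
    )
    if spiked:
        fluct[:, spike_vol] += 5.0  # intensity blip co-occurring with the excursion

    data = np.zeros(shape + (T,), dtype=np.float64)
    flat = data.reshape(-1, T)
    flat[brain_idx] = nm.baseline_intensity + nm.bold_sigma * fluct
    # faint out-of-brain noise so the background is not exactly zero
    out_idx = np.flatnonzero(~brain.ravel())
    flat[out_idx] = rng.normal(0.0, 1.0, size=(out_idx.size, T))

    run = BoldRun(
        data=data,
        tr_seconds=cfg.tr_seconds,
        affine=cfg.affine,
        motion=motion,
        brain_mask=brain,
        wm_prob=masks["wm"],
        csf_prob=masks["csf"],
        subject_id=profile.subject_id,
        run_index=run_index,
    )
    run.planted_couplings = couplings  # ground truth, for tests and benchmarks
    return run


# ---------------------------------------------------------------------------
# whole-study container


@dataclass
class SyntheticStudy:
    config: StudyConfig
    profiles: list[TraitProfile]
    n_runs: dict[str, int]
    masks: dict[str, np.ndarray]

    @property
    def seeds(self) -> list[SeedSpec]:
        return self.config.seeds

    @property
    def effects(self) -> list[PlantedEffect]:
        return self.config.effects

    def runs_for(self, profile: TraitProfile) -> list[BoldRun]:
        return [
            generate_bold_run(profile, self.seeds, self.effects, self.config, k, self.masks)
            for k in range(self.n_runs[profile.subject_id])
        ]


def simulate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Instantiate the cohort: phenotypes, per-subject run counts, masks.

    Runs themselves are generated lazily via :meth:`SyntheticStudy.runs_for`
    (each run is deterministic on its own, so laziness costs nothing).
    """
    errs = validate_config(cfg)
    if errs:
        raise ValueError("invalid study config: " + "; ".join(errs))
    profiles = generate_trait_scores(
        cfg.n_subjects, cfg.trait_means, cfg.trait_sds, cfg.trait_corr,
        rng_seed=cfg.rng_seed, age_range=cfg.age_range, male_fraction=cfg.male_fraction,
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(7,)))
    counts = sorted(cfg.runs_per_subject)
    probs = np.array([cfg.runs_per_subject[k] for k in counts], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(counts, size=cfg.n_subjects, p=probs)
    n_runs = {p.subject_id: int(k) for p, k in zip(profiles, draws)}
    return SyntheticStudy(config=cfg, profiles=profiles, n_runs=n_runs, masks=build_masks(cfg))


# ---------------------------------------------------------------------------
# on-disk study layout


def _save_nifti(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_study(study: SyntheticStudy, directory) -> dict:
    """Write a study to disk (NIfTI runs + motion tables + masks + TSV tables
    + JSON manifest) in a layout the pipeline readers round-trip."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    affine = cfg.affine

    _save_nifti(root / "mask_brain.nii.gz", study.masks["brain"].astype(np.float32), affine)
    _save_nifti(root / "mask_wm.nii.gz", study.masks["wm"], affine)
    _save_nifti(root / "mask_csf.nii.gz", study.masks["csf"], affine)

    pheno_rows = []
    run_entries = []
    for profile in study.profiles:
        row = {"subject_id": profile.subject_id, "age": profile.age, "sex": profile.sex,
               "n_runs": study.n_runs[profile.subject_id]}
        row.update({d: profile.scores[d] for d in DOMAIN_NAMES})
        pheno_rows.append(row)
        sub_dir = root / profile.subject_id
        sub_dir.mkdir(exist_ok=True)
        for run in study.runs_for(profile):
            stem = f"run-{run.run_index + 1:02d}"
            _save_nifti(sub_dir / f"{stem}_bold.nii.gz", run.data, affine)
            np.savetxt(sub_dir / f"{stem}_motion.par", run.motion, fmt="%.8f")
            run_entries.append(
                {"subject_id": profile.subject_id, "run_index": run.run_index,
                 "bold": f"{profile.subject_id}/{stem}_bold.nii.gz",
                 "motion": f"{profile.subject_id}/{stem}_motion.par"}
            )
    pheno = pd.DataFrame(pheno_rows)
    pheno.to_csv(root / "phenotype.tsv", sep="\t", index=False)

    seed_df = pd.DataFrame(
        [{"name": s.name, "x_mm": s.center_mm[0], "y_mm": s.center_mm[1],
          "z_mm": s.center_mm[2], "diameter_mm": s.diameter_mm,
          "hemisphere": s.hemisphere} for s in cfg.seeds]
    )
    seed_df.to_csv(root / "seeds.tsv", sep="\t", index=False)
    cfg.to_yaml(str(root / "config.yaml"))

    manifest = {
        "config_hash": cfg.config_hash(),
        "tr_seconds": cfg.tr_seconds,
        "n_subjects": cfg.n_subjects,
        "n_volumes": cfg.n_volumes,
        "runs": run_entries,
        "phenotype": "phenotype.tsv",
        "seeds": "seeds.tsv",
        "masks": {"brain": "mask_brain.nii.gz", "wm": "mask_wm.nii.gz",
                  "csf": "mask_csf.nii.gz"},
        "config": "config.yaml",
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_study(directory) -> tuple[StudyConfig, list[TraitProfile], dict[str, list[BoldRun]]]:
    """Load a written study back into memory: (config, profiles, runs-by-subject)."""
    root = Path(directory)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = StudyConfig.from_yaml(str(root / manifest["config"]))
    brain = np.asarray(nib.load(str(root / manifest["masks"]["brain"])).dataobj) > 0.5
    wm = np.asarray(nib.load(str(root / manifest["masks"]["wm"])).dataobj, dtype=float)
    csf = np.asarray(nib.load(str(root / manifest["masks"]["csf"])).dataobj, dtype=float)
    pheno = pd.read_csv(root / manifest["phenotype"], sep="\t")
    profiles = [
        TraitProfile(subject_id=str(r["subject_id"]),
                     scores={d: float(r[d]) for d in DOMAIN_NAMES},
                     age=float(r["age"]), sex=int(r["sex"]))
        for _, r in pheno.iterrows()
    ]
    runs: dict[str, list[BoldRun]] = {p.subject_id: [] for p in profiles}
    for entry in manifest["runs"]:
        img = nib.load(str(root / entry["bold"]))
        motion = np.loadtxt(root / entry["motion"])
        runs[entry["subject_id"]].append(
            BoldRun(
                data=np.asarray(img.dataobj, dtype=np.float64),
                tr_seconds=float(manifest["tr_seconds"]),
                affine=np.asarray(img.affine, dtype=float),
                motion=motion,
                brain_mask=brain, wm_prob=wm, csf_prob=csf,
                subject_id=entry["subject_id"], run_index=int(entry["run_index"]),
            )
        )
    return cfg, profiles, runs
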