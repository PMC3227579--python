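"""Declarative study configuration: cohort, seeds, planted effects, preprocessing
and inference parameters, all serializable to/from YAML.

The shipped defaults describe the canonical study design: 39 subjects with 1-5
resting-state runs of 197 volumes at TR = 2 s, 8 mm spherical seeds, band-pass
0.009-0.1 Hz, 6 mm FWHM smoothing, grand-mean intensity 10,000, a 3 mm motion
QC threshold, cluster-forming Z > 2.3 with corrected alpha 0.05, and 5000
permutations for the confirmatory tests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .datatypes import PlantedEffect, SeedSpec

# Canonical design constants of the study emulated by the default config.
CANONICAL_CONSTANTS = {
    "n_subjects": 39,
    "n_volumes": 197,
    "tr_seconds": 2.0,
    "f_lo_hz": 0.009,
    "f_hi_hz": 0.1,
    "smooth_fwhm_mm": 6.0,
    "normalize_target": 10000.0,
    "qc_threshold_mm": 3.0,
    "seed_diameter_mm": 8.0,
    "cluster_z": 2.3,
    "cluster_alpha": 0.05,
    "n_permutations": 5000,
}

# Sample moments of the five NEO domain scores used by the trait generator
# (raw-score scale, order N, E, O, A, C).
DEFAULT_TRAIT_MEANS = (78.0, 119.0, 128.0, 125.0, 122.0)
DEFAULT_TRAIT_SDS = (28.0, 20.0, 21.0, 15.0, 22.0)


@dataclass
class NoiseModel:
    """Amplitudes of the generative noise/nuisance processes.

    All fluctuation amplitudes are expressed in units of the unit-variance
    voxel noise before scaling by ``bold_sigma``.
    """

    ar_coeff: float = 0.4
    bold_sigma: float = 20.0
    baseline_intensity: float = 1000.0
    seed_noise_sigma: float = 0.1
    drift_amplitude: float = 1.5
    global_amplitude: float = 0.6
    wm_amplitude: float = 0.8
    csf_amplitude: float = 0.8
    motion_artifact_amplitude: float = 0.8
    motion_walk_mm: float = 0.05
    motion_spike_probability: float = 0.12
    motion_spike_mm: float = 4.0


@dataclass
class PreprocParams:
    despike: bool = True
    despike_c1: float = 2.5
    despike_c2: float = 4.0
    detrend_order: int = 2
    f_lo_hz: float = 0.009
    f_hi_hz: float = 0.1
    smooth_fwhm_mm: float = 6.0
    normalize_target: float = 10000.0
    wm_prob_threshold: float = 0.8
    csf_prob_threshold: float = 0.8
    qc_threshold_mm: float = 3.0


@dataclass
class InferenceParams:
    cluster_z: float = 2.3
    alpha: float = 0.05


@dataclass
class ConfirmParams:
    n_permutations: int = 5000


@dataclass
class StudyConfig:
    """Full declarative description of a synthetic trait-connectivity study."""

    n_subjects: int = 39
    runs_per_subject: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.4, 4: 0.1, 5: 0.1}
    )
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 4.0
    n_volumes: int = 197
    tr_seconds: float = 2.0
    trait_means: tuple[float, ...] = DEFAULT_TRAIT_MEANS
    trait_sds: tuple[float, ...] = DEFAULT_TRAIT_SDS
    trait_corr: tuple[tuple[float, ...], ...] = tuple(
        tuple(float(v) for v in row) for row in np.eye(5)
    )
    age_range: tuple[float, float] = (19.0, 45.0)
    male_fraction: float = 18.0 / 39.0
    seeds: list[SeedSpec] = field(default_factory=list)
    effects: list[PlantedEffect] = field(default_factory=list)
    effect_halo_mm: float = 4.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    inference: InferenceParams = field(default_factory=InferenceParams)
    confirm: ConfirmParams = field(default_factory=ConfirmParams)
    rng_seed: int = 2026

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return convert(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        d["runs_per_subject"] = {int(k): float(v) for k, v in d.get(
            "runs_per_subject", {1: 0.2, 2: 0.2, 3: 0.4, 4: 0.1, 5: 0.1}).items()}
        d["grid_shape"] = tuple(d.get("grid_shape", (24, 28, 24)))
        for key in ("trait_means", "trait_sds", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "trait_corr" in d:
            d["trait_corr"] = tuple(tuple(row) for row in d["trait_corr"])
        d["seeds"] = [
            s if isinstance(s, SeedSpec) else SeedSpec(
                name=s["name"], center_mm=tuple(s["center_mm"]),
                diameter_mm=s.get("diameter_mm", 8.0),
                hemisphere=s.get("hemisphere", "bilateral"))
            for s in d.get("seeds", [])
        ]
        d["effects"] = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(
                seed_name=e["seed_name"], name=e["name"],
                center_mm=tuple(e["center_mm"]), radius_mm=e["radius_mm"],
                baseline_coupling=e.get("baseline_coupling", 0.0),
                trait_slope=dict(e.get("trait_slope", {})),
                valence_class=e.get("valence_class", "variable"))
            for e in d.get("effects", [])
        ]
        for key, sub in (("noise", NoiseModel), ("preproc", PreprocParams),
                         ("inference", InferenceParams), ("confirm", ConfirmParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON serialization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- derived geometry ----------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine: isotropic voxels, grid centred on the origin."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        shape = np.asarray(self.grid_shape, dtype=float)
        aff[:3, 3] = -(shape - 1) / 2.0 * self.voxel_size_mm
        return aff

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def validate_config(cfg: StudyConfig) -> list[str]:
    """Check a config for consistency and return the *full* list of problems."""
    errors: list[str] = []
    if cfg.n_subjects < 10:
        errors.append(f"n_subjects must be >= 10 for group inference, got {cfg.n_subjects}")
    probs = cfg.runs_per_subject
    if not probs or abs(sum(probs.values()) - 1.0) > 1e-8:
        errors.append("runs_per_subject probabilities must sum to 1")
    if any(k < 1 or k > 5 for k in probs):
        errors.append("runs_per_subject keys must lie in 1..5")
    if len(cfg.trait_means) != 5 or len(cfg.trait_sds) != 5:
        errors.append("trait_means and trait_sds must have exactly five entries")
    if any(sd < 0 for sd in cfg.trait_sds):
        errors.append("trait SDs must be non-negative")
    corr = np.asarray(cfg.trait_corr, dtype=float)
    if corr.shape != (5, 5):
        errors.append("trait_corr must be 5x5")
    else:
        if not np.allclose(corr, corr.T, atol=1e-10):
            errors.append("trait_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            errors.append("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            errors.append("trait_corr must be positive semi-definite")
    if cfg.voxel_size_mm <= 0:
        errors.append("voxel size must be positive")
    pp = cfg.preproc
    if not (0.0 <= pp.f_lo_hz < pp.f_hi_hz):
        errors.append("band edges must satisfy 0 <= f_lo < f_hi")
    if pp.f_hi_hz > cfg.nyquist_hz + 1e-12:
        errors.append(
            f"f_hi = {pp.f_hi_hz} Hz exceeds the Nyquist frequency "
            f"{cfg.nyquist_hz} Hz for TR = {cfg.tr_seconds} s"
        )
    if pp.despike_c2 <= pp.despike_c1:
        errors.append("despike_c2 must exceed despike_c1")
    if pp.smooth_fwhm_mm < 0:
        errors.append("smoothing FWHM must be non-negative")
    if cfg.inference.cluster_z <= 0:
        errors.append("cluster-forming z must be positive")
    if not (0 < cfg.inference.alpha < 1):
        errors.append("alpha must lie in (0, 1)")
    if cfg.confirm.n_permutations < 1:
        errors.append("n_permutations must be positive")
    seed_names = {s.name for s in cfg.seeds}
    if len(seed_names) != len(cfg.seeds):
        errors.append("seed names must be unique")
    for eff in cfg.effects:
        if eff.seed_name not in seed_names:
            errors.append(f"effect {eff.name!r} references unknown seed {eff.seed_name!r}")
    effect_names = [e.name for e in cfg.effects]
    if len(set(effect_names)) != len(effect_names):
        errors.append("effect names must be unique")
    # planted regions (incl. halo) must not collide with each other or any seed
    for i, a in enumerate(cfg.effects):
        for b in cfg.effects[i + 1:]:
            d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
            if d < a.radius_mm + b.radius_mm + 2 * cfg.effect_halo_mm:
                errors.append(f"effect regions {a.name!r} and {b.name!r} overlap")
        for s in cfg.seeds:
            d = np.linalg.norm(np.subtract(a.center_mm, s.center_mm))
            if d < a.radius_mm + cfg.effect_halo_mm + s.radius_mm:
                errors.append(f"effect region {a.name!r} overlaps seed {s.name!r}")
    if not (0.0 <= cfg.noise.motion_spike_probability <= 1.0):
        errors.append("motion_spike_probability must lie in [0, 1]")
    if cfg.rng_seed < 0 or cfg.rng_seed >= 2 ** 31:
        errors.append("rng_seed must lie in [0, 2^31)")
    return errors


def shipped_config_path() -> str:
    """Path to the annotated default study YAML shipped with the package."""
    from importlib import resources

    return str(resources.files("traitconn").joinpath("data/default_study.yaml"))


def default_seeds() -> list[SeedSpec]:
    """Three seeds on the default grid: one anterior-cingulate-like midline
    seed and a left/right precuneus-like pair."""
    return [
        SeedSpec("acc", (0.0, 36.0, 8.0), 8.0, "bilateral"),
        SeedSpec("pcu_l", (-8.0, -40.0, 20.0), 8.0, "left"),
        SeedSpec("pcu_r", (8.0, -40.0, 20.0), 8.0, "right"),
    ]


def default_effects() -> list[PlantedEffect]:
    """Ground-truth couplings of the default study.

    One variable-valence trait association per domain (disjoint targets, so
    the five-way conjunction is empty by construction), two invariant-positive
    connections (one carrying a weaker secondary openness association), and
    one invariant-negative connection.  Slopes are scaled so the coupling SD
    across subjects is ~0.17 for the primary associations.
    """
    return [
        PlantedEffect("acc", "var_neuroticism", (-24.0, 16.0, -12.0), 8.0,
                      0.0, {"neuroticism": 0.006}, "variable"),
        PlantedEffect("acc", "var_extraversion", (28.0, 20.0, 4.0), 8.0,
                      0.0, {"extraversion": 0.0085}, "variable"),
        PlantedEffect("pcu_l", "var_openness", (-24.0, -32.0, 4.0), 8.0,
                      0.0, {"openness": 0.008}, "variable"),
        PlantedEffect("pcu_r", "var_agreeableness", (20.0, -24.0, 12.0), 8.0,
                      0.0, {"agreeableness": 0.011}, "variable"),
        PlantedEffect("acc", "var_conscientiousness", (0.0, -8.0, 32.0), 8.0,
                      0.0, {"conscientiousness": 0.0075}, "variable"),
        PlantedEffect("pcu_r", "pos_pcu", (-4.0, -20.0, -20.0), 8.0,
                      0.5, {}, "invariant_pos"),
        PlantedEffect("acc", "pos_acc_openness", (-6.0, 28.0, 24.0), 6.0,
                      0.45, {"openness": 0.004}, "invariant_pos"),
        PlantedEffect("pcu_l", "neg_pcu", (28.0, 4.0, -20.0), 8.0,
                      -0.45, {}, "invariant_neg"),
    ]


def default_config(rng_seed: int = 2026) -> StudyConfig:
    cfg = StudyConfig(seeds=default_seeds(), effects=default_effects(), rng_seed=rng_seed)
    errs = validate_config(cfg)
    if errs:  # pragma: no cover - defends against regressions in the defaults
        raise RuntimeError("default config invalid: " + "; ".join(errs))
    return cfg


def recovery_config(rng_seed: int = 2026) -> StudyConfig:
    """Scaled-down single-run study used for slope-recovery benchmarks.

    Spatial smoothing is disabled: with a regionally shared latent signal and
    voxel-independent noise, smoothing inflates correlation amplitudes by a
    kernel-dependent factor, so recovery against the planted slope is only
    well-posed unsmoothed.  Map-level analyses keep the default 6 mm kernel.
    """
    cfg = default_config(rng_seed)
    cfg.grid_shape = (18, 20, 18)
    cfg.runs_per_subject = {1: 1.0}
    cfg.noise.motion_spike_probability = 0.0
    cfg.preproc.smooth_fwhm_mm = 0.0
    # re-centre the planted geometry on the smaller grid
    cfg.seeds = [
        SeedSpec("acc", (0.0, 20.0, 6.0), 8.0, "bilateral"),
        SeedSpec("pcu", (0.0, -24.0, 12.0), 8.0, "bilateral"),
    ]
    cfg.effects = [
        PlantedEffect("acc", "var_neuroticism", (-18.0, 10.0, -8.0), 8.0,
                      0.0, {"neuroticism": 0.006}, "variable"),
        PlantedEffect("acc", "var_extraversion", (20.0, 12.0, 2.0), 8.0,
                      0.0, {"extraversion": 0.0085}, "variable"),
        PlantedEffect("pcu", "var_openness", (-16.0, -20.0, 2.0), 8.0,
                      0.0, {"openness": 0.008}, "variable"),
        PlantedEffect("pcu", "var_agreeableness", (18.0, -16.0, 8.0), 8.0,
                      0.0, {"agreeableness": 0.011}, "variable"),
        PlantedEffect("acc", "var_conscientiousness", (0.0, -4.0, 24.0), 8.0,
                      0.0, {"conscientiousness": 0.0075}, "variable"),
    ]
    errs = validate_config(cfg)
    if errs:  # pragma: no cover
        raise RuntimeError("recovery config invalid: " + "; ".join(errs))
    return cfg
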