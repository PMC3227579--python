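"""Self-contained validation benchmarks for the pipeline.

Each function recomputes one headline property from scratch — simulating its
own inputs from a seed — and returns plain numbers.  They are shared by the
acceptance script and the test suite.

Problem sizes are chosen to keep every benchmark desk-scale: the FWE
calibration uses 500 null fields on a 24^3 grid at 8 mm FWHM (2 voxels, the
canonical lower bound for lattice validity of random-field theory); slope
recovery uses 20 replicates of the 39-subject
single-run recovery study; the map-level benchmarks share one full default
study (39 subjects, 1-5 runs each).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .config import default_config, recovery_config
from .confirm import percentile_pvalue, permutation_test
from .datatypes import DOMAIN_NAMES, SmoothnessEstimate, SubjectRecord, TraitProfile
from .grf import grf_cluster_correct
from .group import TraitConnectivityGLM
from .pipeline import StudyResults, analyze_study
from .synth import effect_target_mask, simulate_study

__all__ = [
    "permutation_worked_example",
    "ols_oracle_max_delta",
    "fwe_calibration",
    "parameter_recovery",
    "run_default_study",
    "kendalls_w_summary",
    "valence_modal_classes",
    "conjunction_top_level",
    "null_pvalue_uniformity",
]


def permutation_worked_example(rng_seed: int = 0, n_perm: int = 5000) -> float:
    """p-value of an observed correlation ranked at the 97.5th percentile of
    its own 5000-pairing permutation null (should be exactly 0.025).

    The null is built by the real permutation machinery on a synthetic
    connection; the observed value is then placed at the 125th-largest null
    correlation, i.e. 97.5% of the null lies strictly below it.
    """
    rng = np.random.default_rng(rng_seed)
    strengths = rng.standard_normal(39)
    scores = rng.standard_normal(39)
    null = permutation_test(strengths, scores, n_perm=n_perm, rng_seed=rng_seed,
                            direction="positive").null_r
    k = int(round(0.025 * n_perm))
    observed = np.sort(null)[-k]  # k-th largest: exactly k null values >= it
    return percentile_pvalue(observed, null, direction="positive")


def _random_subjects(rng: np.random.Generator, n: int) -> list[SubjectRecord]:
    means = np.array([78.0, 119.0, 128.0, 125.0, 122.0])
    sds = np.array([28.0, 20.0, 21.0, 15.0, 22.0])
    subs = []
    for i in range(n):
        scores = {d: float(means[j] + sds[j] * rng.standard_normal())
                  for j, d in enumerate(DOMAIN_NAMES)}
        subs.append(SubjectRecord(
            profile=TraitProfile(f"sub-{i:03d}", scores, age=float(rng.uniform(19, 45)),
                                 sex=int(rng.integers(2))),
            n_scans=int(rng.integers(1, 6))))
    return subs


def ols_oracle_max_delta(rng_seed: int = 0, n_voxels: int = 20) -> float:
    """Max |beta difference| between the voxelwise group GLM and a brute-force
    normal-equations oracle on a random small fixture."""
    rng = np.random.default_rng(rng_seed)
    subjects = _random_subjects(rng, 39)
    shape = (n_voxels, 1, 1)
    Z = rng.standard_normal((39,) + shape)
    mask = np.ones(shape, dtype=bool)
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    glm = TraitConnectivityGLM().fit(Z, subjects, mask, affine)
    X = glm.design_.to_numpy()
    # independent oracle: solve the normal equations voxel by voxel
    max_delta = 0.0
    for v in range(n_voxels):
        y = Z[:, v, 0, 0]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        for j, col in enumerate(glm.design_.columns):
            max_delta = max(max_delta, abs(beta[j] - glm.beta_[col][v, 0, 0]))
    return max_delta


def fwe_calibration(rng_seed: int = 0, n_sims: int = 500, grid: int = 24,
                    voxel_mm: float = 4.0, fwhm_mm: float = 8.0,
                    cluster_z: float = 2.3, alpha: float = 0.05) -> float:
    """Family-wise false-positive rate of GRF cluster correction over null
    smooth Gaussian fields with known smoothness.

    The correction is exercised exactly as the pipeline deploys it on each
    effect map — positive and negative clusters tested separately — so a
    family-wise false positive is a significant cluster of either sign.
    Default smoothness is 8 mm FWHM = 2 voxels, the canonical lower bound for
    lattice validity of random-field theory.
    """
    rng = np.random.default_rng(rng_seed)
    shape = (grid,) * 3
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    pad = int(np.ceil(4 * sigma))
    impulse = np.zeros((2 * pad + 1,) * 3)
    impulse[pad, pad, pad] = 1.0
    kernel_norm = np.sqrt((ndimage.gaussian_filter(impulse, sigma) ** 2).sum())
    mask = np.ones(shape, dtype=bool)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    rpv = (voxel_mm / fwhm_mm) ** 3
    sm = SmoothnessEstimate(fwhm_mm=np.full(3, fwhm_mm), resels_per_voxel=rpv,
                            n_resels=mask.sum() * rpv, n_voxels=int(mask.sum()))
    hits = 0
    for _ in range(n_sims):
        white = rng.standard_normal(tuple(s + 2 * pad for s in shape))
        field = ndimage.gaussian_filter(white, sigma)[pad:-pad, pad:-pad, pad:-pad]
        field /= kernel_norm  # exact unit variance
        tab_pos, _ = grf_cluster_correct(field, mask, sm, affine,
                                         cluster_z=cluster_z, alpha=alpha,
                                         sign="positive")
        tab_neg, _ = grf_cluster_correct(field, mask, sm, affine,
                                         cluster_z=cluster_z, alpha=alpha,
                                         sign="negative")
        hits += int(len(tab_pos) > 0 or len(tab_neg) > 0)
    return hits / n_sims


def parameter_recovery(rng_seed: int = 0, n_replicates: int = 20) -> dict:
    """Recovery of the planted trait slopes in the single-run recovery study.

    Returns sign agreement, worst per-effect relative bias of the
    replicate-mean slope estimate, and the domain-specificity rate (planted
    domain's mean Z in the target region exceeds every other domain's).
    """
    from .pipeline import _collect_subject_maps

    signs_ok = 0
    signs_total = 0
    spec_ok = 0
    spec_total = 0
    ratios: dict[str, list[float]] = {}
    for rep in range(n_replicates):
        cfg = recovery_config((rng_seed + 7919 * rep) % (2 ** 31))
        study = simulate_study(cfg)
        _, subjects, stacks = _collect_subject_maps(study)
        brain = study.masks["brain"]
        for seed in cfg.seeds:
            glm = TraitConnectivityGLM().fit(stacks[seed.name], subjects,
                                             brain, cfg.affine)
            for eff in (e for e in cfg.effects if e.seed_name == seed.name):
                domain = next(iter(eff.trait_slope))
                truth = eff.trait_slope[domain]
                m = effect_target_mask(eff, cfg, brain)
                bhat = float(np.nanmean(glm.beta_[domain][m]))
                ratios.setdefault(eff.name, []).append(bhat / truth)
                signs_total += 1
                signs_ok += int(np.sign(bhat) == np.sign(truth))
                zmeans = {d: float(np.nanmean(glm.z_[d][m])) for d in DOMAIN_NAMES}
                spec_total += 1
                spec_ok += int(all(zmeans[domain] > zmeans[d]
                                   for d in DOMAIN_NAMES if d != domain))
    mean_ratios = {name: float(np.mean(r)) for name, r in ratios.items()}
    worst_bias = max(abs(r - 1.0) for r in mean_ratios.values())
    return {
        "sign_agreement": signs_ok / signs_total,
        "max_relative_bias": worst_bias,
        "specificity": spec_ok / spec_total,
        "mean_slope_ratios": mean_ratios,
        "n_replicates": n_replicates,
    }


def run_default_study(rng_seed: int = 2026, n_perm: int = 2000) -> StudyResults:
    """One full default study (shared by the map-level benchmarks)."""
    cfg = default_config(rng_seed)
    return analyze_study(simulate_study(cfg), n_perm=n_perm)


def kendalls_w_summary(results: StudyResults) -> dict:
    """Minimum Kendall's W between simultaneous- and separate-model Z maps
    over all seed-domain pairs."""
    return {
        "min_w": float(results.kendall_w.kendalls_w.min()),
        "n_pairs": int(len(results.kendall_w)),
    }


def valence_modal_classes(results: StudyResults) -> dict[str, str]:
    """Modal valence class of the significant-voxel histogram per domain
    (aggregated over seeds)."""
    out = {}
    for domain in DOMAIN_NAMES:
        totals = {"invariant_pos": 0, "invariant_neg": 0, "variable": 0}
        for (seed, dom), vmap in results.valence.items():
            if dom == domain:
                for k, v in vmap.histogram.items():
                    totals[k] += v
        out[domain] = max(totals, key=totals.get)
    return out


def conjunction_top_level(results: StudyResults) -> int:
    """Number of voxels common to all five domain-association maps."""
    return results.conjunction.level_counts[5]


def null_pvalue_uniformity(rng_seed: int = 0, n_connections: int = 500,
                           n: int = 39, n_perm: int = 500) -> dict:
    """KS test of permutation p-values against U(0,1) across simulated null
    connections (fixed a priori test direction)."""
    rng = np.random.default_rng(rng_seed)
    ps = np.empty(n_connections)
    for i in range(n_connections):
        strengths = rng.standard_normal(n)
        scores = rng.standard_normal(n)
        ps[i] = permutation_test(strengths, scores, n_perm=n_perm,
                                 rng_seed=int(rng.integers(2 ** 31)),
                                 direction="positive").p_value
    ks = stats.kstest(ps, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n_connections": n_connections}
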