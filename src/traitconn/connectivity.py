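"""Seed voxelization, seed-mean time series, voxelwise correlation and
Fisher-z maps, and per-subject averaging over retained runs.

Correlations at zero-variance voxels are undefined and propagate as NaN;
group-level fits treat them as missing (complete-case per voxel).
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import BoldRun, ConnectivityMap, SeedSpec

FISHER_EPS = 1e-7

__all__ = [
    "voxelize_seed",
    "extract_seed_ts",
    "correlation_map",
    "fisher_z",
    "average_subject_maps",
    "SeedCorrelationMapper",
]


def voxelize_seed(spec: SeedSpec, affine: np.ndarray, shape) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the seed sphere
    (inclusive boundary), in mm space via the grid affine."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    d2 = ((centers - np.asarray(spec.center_mm, dtype=float)) ** 2).sum(axis=1)
    mask = (d2 <= spec.radius_mm ** 2 + 1e-9).reshape(tuple(shape))
    if not mask.any():
        raise ValueError(f"seed {spec.name!r} voxelizes to an empty set on this grid")
    return mask


def extract_seed_ts(run: BoldRun, voxels: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the seed voxel set."""
    voxels = np.asarray(voxels, dtype=bool)
    if voxels.shape != run.shape3d:
        raise ValueError("seed voxel mask grid does not match the run grid")
    if not voxels.any():
        raise ValueError("empty seed voxel set")
    return run.data[voxels].mean(axis=0)


def correlation_map(run: BoldRun, seed_ts: np.ndarray) -> np.ndarray:
    """Pearson correlation of every in-mask voxel with the seed series.

    Returns a 3D map: NaN outside the brain mask and at zero-variance voxels.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.shape != (run.n_volumes,):
        raise ValueError("seed series length must equal the run's volume count")
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-12:
        raise ValueError("seed time series has zero variance")
    flat = run.data.reshape(-1, run.n_volumes)
    in_mask = run.brain_mask.ravel()
    Y = flat[in_mask]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ s) / (norms * s_norm)
    r[norms < 1e-12] = np.nan
    out = np.full(flat.shape[0], np.nan)
    out[in_mask] = np.clip(r, -1.0, 1.0)
    return out.reshape(run.shape3d)


def fisher_z(r_map: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform z = atanh(r), with |r| clamped at 1 - 1e-7."""
    r = np.clip(np.asarray(r_map, dtype=float), -1.0 + FISHER_EPS, 1.0 - FISHER_EPS)
    return np.arctanh(r)


def average_subject_maps(zmaps: list[np.ndarray], subject_id: str = "",
                         seed_name: str = "") -> ConnectivityMap:
    """Voxelwise mean of a subject's retained-run z-maps (NaN-aware: a voxel
    is defined if it is defined in at least one run)."""
    if len(zmaps) == 0:
        raise ValueError("need at least one retained run to average")
    shapes = {m.shape for m in zmaps}
    if len(shapes) != 1:
        raise ValueError(f"z-maps on mismatched grids: {sorted(shapes)}")
    stack = np.stack(zmaps)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN out-of-mask voxels
        mean = np.nanmean(stack, axis=0)
    return ConnectivityMap(subject_id=subject_id, seed_name=seed_name,
                           z=mean, n_runs_averaged=len(zmaps))


class SeedCorrelationMapper(TransformerMixin, BaseEstimator):
    """Transform a preprocessed run into per-seed Fisher-z maps.

    ``transform(run)`` returns {seed name: 3D z map}; ``subject_maps(runs)``
    averages over a subject's retained runs into :class:`ConnectivityMap`s.
    Seed voxels are retained in the maps by default;
    ``exclude_seed_voxels=True`` marks them missing instead, which removes
    them from downstream group fits.
    """

    def __init__(self, seeds: list[SeedSpec] | None = None,
                 exclude_seed_voxels: bool = False):
        self.seeds = seeds
        self.exclude_seed_voxels = exclude_seed_voxels

    def fit(self, X=None, y=None):
        return self

    def transform(self, run: BoldRun) -> dict[str, np.ndarray]:
        out = {}
        for spec in self.seeds or []:
            mask = voxelize_seed(spec, run.affine, run.shape3d)
            ts = extract_seed_ts(run, mask)
            z = fisher_z(correlation_map(run, ts))
            if self.exclude_seed_voxels:
                z = np.where(mask, np.nan, z)
            out[spec.name] = z
        return out

    def subject_maps(self, runs: list[BoldRun]) -> dict[str, ConnectivityMap]:
        if not runs:
            raise ValueError("no retained runs for this subject")
        per_seed: dict[str, list[np.ndarray]] = {s.name: [] for s in self.seeds or []}
        for run in runs:
            for name, z in self.transform(run).items():
                per_seed[name].append(z)
        subject_id = runs[0].subject_id
        return {
            name: average_subject_maps(maps, subject_id=subject_id, seed_name=name)
            for name, maps in per_seed.items()
        }
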