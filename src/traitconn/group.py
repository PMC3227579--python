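"""Voxelwise group-level GLM relating subject Fisher-z maps to trait scores.

The simultaneous model regresses each voxel's z values across subjects on an
intercept, the five demeaned trait scores, age, sex, and the demeaned number
of retained scans; separate models carry a single demeaned trait instead of
all five.  t statistics are converted to Z scores by exact
probability-integral mapping, and cluster-extent correction is applied at
Z > 2.3, corrected alpha 0.05, separately for positive and negative effects.

Missing voxels (undefined correlations for some subjects) are handled
complete-case per voxel; the dropped count is recorded.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import DOMAIN_NAMES, SubjectRecord
from .grf import estimate_smoothness, grf_cluster_correct

logger = logging.getLogger(__name__)

__all__ = ["build_design", "t_to_z", "fit_group_ols", "TraitConnectivityGLM"]

SIMULTANEOUS_COLUMNS = ["intercept", *DOMAIN_NAMES, "age", "sex", "n_scans"]


def build_design(subjects: list[SubjectRecord], mode: str = "simultaneous",
                 domain: str | None = None) -> pd.DataFrame:
    """Group design matrix.

    ``simultaneous``: intercept + five demeaned traits + age + sex + demeaned
    scan count (9 columns).  ``separate``: intercept + one demeaned trait +
    age + sex + demeaned scan count (5 columns).
    """
    if len(subjects) < 10:
        raise ValueError(f"need at least 10 subjects for group inference, got {len(subjects)}")
    if mode not in ("simultaneous", "separate"):
        raise ValueError(f"mode must be 'simultaneous' or 'separate', got {mode!r}")
    if mode == "separate":
        if domain not in DOMAIN_NAMES:
            raise ValueError(f"separate mode needs a valid domain, got {domain!r}")
        domains = [domain]
    else:
        domains = list(DOMAIN_NAMES)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(subjects))}
    for d in domains:
        v = np.array([s.profile.scores[d] for s in subjects], dtype=float)
        cols[d] = v - v.mean()
    cols["age"] = np.array([s.profile.age for s in subjects], dtype=float)
    cols["sex"] = np.array([s.profile.sex for s in subjects], dtype=float)
    n_scans = np.array([s.n_scans for s in subjects], dtype=float)
    if np.ptp(n_scans) > 0:
        cols["n_scans"] = n_scans - n_scans.mean()
    else:
        # single-run designs have no scan-count variance; the covariate is
        # structurally empty and is omitted rather than breaking the fit
        logger.info("scan count is constant (%g); omitting the n_scans covariate",
                    n_scans[0])

    X = pd.DataFrame(cols, index=[s.subject_id for s in subjects])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by leave-one-out rank
        offending = [c for c in X.columns
                     if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank]
        raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")
    return X


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Exact t -> Z via the distribution functions, tail-symmetric to avoid
    catastrophic cancellation for large |t|."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    with np.errstate(invalid="ignore"):
        z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
        z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    z[np.isnan(t)] = np.nan
    return z


class TraitConnectivityGLM(BaseEstimator):
    """Sklearn-style voxelwise group GLM with GRF cluster correction.

    Parameters
    ----------
    mode : 'simultaneous' or 'separate'
    domain : trait name, required for separate mode
    cluster_z, alpha : cluster-forming Z and corrected cluster alpha

    Fitted attributes (per in-mask voxel, complete-case):
    ``design_`` (DataFrame), ``beta_`` {column: 3D map}, ``t_``, ``z_``,
    ``residuals_`` (n_subjects, x, y, z with NaN where dropped), ``df_``,
    ``smoothness_``, ``n_dropped_voxels_``.
    """

    def __init__(self, mode: str = "simultaneous", domain: str | None = None,
                 cluster_z: float = 2.3, alpha: float = 0.05):
        self.mode = mode
        self.domain = domain
        self.cluster_z = cluster_z
        self.alpha = alpha

    def fit(self, Z: np.ndarray, subjects: list[SubjectRecord],
            mask: np.ndarray, affine: np.ndarray):
        """Fit the voxelwise OLS model.

        ``Z`` is the stacked subject maps (n_subjects, x, y, z); ``mask`` the
        analysis mask; ``affine`` the voxel->mm transform.
        """
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 4 or Z.shape[0] != len(subjects):
            raise ValueError("Z must be (n_subjects, x, y, z) matching the subject list")
        X = build_design(subjects, self.mode, self.domain)
        n, p = X.shape
        if n - p < 1:
            raise ValueError(f"no residual degrees of freedom: n={n}, p={p}")
        mask = np.asarray(mask, dtype=bool)
        affine = np.asarray(affine, dtype=float)
        Xv = X.to_numpy()
        df = n - p

        flatZ = Z.reshape(n, -1)
        in_mask = mask.ravel()
        Y = flatZ[:, in_mask]  # (n, v)
        complete = np.isfinite(Y).all(axis=0)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropping %d in-mask voxels with missing values", n_dropped)

        beta = np.full((p, Y.shape[1]), np.nan)
        resid = np.full(Y.shape, np.nan)
        bc, *_ = np.linalg.lstsq(Xv, Y[:, complete], rcond=None)
        beta[:, complete] = bc
        resid[:, complete] = Y[:, complete] - Xv @ bc

        sigma2 = np.full(Y.shape[1], np.nan)
        sigma2[complete] = (resid[:, complete] ** 2).sum(axis=0) / df
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        se_scale = np.sqrt(np.diag(XtX_inv))  # per column

        def unflat(vec, fill=np.nan):
            out = np.full(flatZ.shape[1], fill)
            out[in_mask] = vec
            return out.reshape(mask.shape)

        self.design_ = X
        self.df_ = df
        self.mask_ = mask
        self.affine_ = affine
        self.voxel_size_mm_ = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        self.n_dropped_voxels_ = n_dropped
        self.beta_ = {}
        self.t_ = {}
        self.z_ = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for j, col in enumerate(X.columns):
                b = beta[j]
                t = b / (np.sqrt(sigma2) * se_scale[j])
                self.beta_[col] = unflat(b)
                self.t_[col] = unflat(t)
                self.z_[col] = unflat(t_to_z(t, df))
        tmp = np.full((n, flatZ.shape[1]), np.nan)
        tmp[:, in_mask] = resid
        self.residuals_ = tmp.reshape((n,) + mask.shape)
        self._smoothness = None  # estimated lazily (needs a volumetric mask)
        return self

    @property
    def smoothness_(self):
        self._check_fitted()
        if self._smoothness is None:
            self._smoothness = estimate_smoothness(self.residuals_, self.mask_,
                                                   self.voxel_size_mm_)
        return self._smoothness

    def _check_fitted(self):
        if not hasattr(self, "z_"):
            raise RuntimeError("model is not fitted")

    def cluster_correct(self, column: str, sign: str = "positive"):
        """GRF cluster correction of one effect's Z map at the given sign."""
        self._check_fitted()
        zmap = np.nan_to_num(self.z_[column], nan=0.0)
        return grf_cluster_correct(zmap, self.mask_, self.smoothness_, self.affine_,
                                   cluster_z=self.cluster_z, alpha=self.alpha, sign=sign)

    def group_mean_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Cluster-corrected masks of significant positive / negative group-mean
        connectivity (intercept contrast, both signs)."""
        _, pos = self.cluster_correct("intercept", "positive")
        _, neg = self.cluster_correct("intercept", "negative")
        return pos != 0, neg != 0

    def domain_significance_mask(self, domain: str) -> tuple[np.ndarray, dict]:
        """Union of the positive and negative cluster-corrected maps of a trait
        effect, plus the per-sign cluster tables."""
        tab_pos, pos = self.cluster_correct(domain, "positive")
        tab_neg, neg = self.cluster_correct(domain, "negative")
        return (pos != 0) | (neg != 0), {"positive": tab_pos, "negative": tab_neg}


def fit_group_ols(maps: np.ndarray, subjects: list[SubjectRecord], mask: np.ndarray,
                  affine: np.ndarray, mode: str = "simultaneous",
                  domain: str | None = None, cluster_z: float = 2.3,
                  alpha: float = 0.05) -> TraitConnectivityGLM:
    """Thin functional wrapper over :class:`TraitConnectivityGLM`."""
    return TraitConnectivityGLM(mode=mode, domain=domain, cluster_z=cluster_z,
                                alpha=alpha).fit(maps, subjects, mask, affine)
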