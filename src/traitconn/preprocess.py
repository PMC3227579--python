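"""Temporal and spatial conditioning of individual BOLD runs.

Stage order (fixed): despike -> band-pass -> detrend -> spatial smoothing ->
grand-mean intensity normalization -> nine-regressor nuisance regression.
The three temporal stages operate on the demeaned time series; each voxel's
temporal mean is restored before the spatial stages so that the grand-mean
normalization remains meaningful (nuisance regression removes the mean again
through its intercept).

Motion QC is a separate decision (`qc_motion`): a run is retained iff its
maximum head displacement — the Euclidean norm of the translation parameters
relative to the reference (first) volume — is strictly below the threshold
(default 3 mm).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import BoldRun, NuisanceSet, QCDecision

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

__all__ = [
    "qc_motion",
    "despike",
    "detrend",
    "bandpass",
    "smooth_spatial",
    "normalize_intensity",
    "extract_nuisance",
    "nuisance_regress",
    "RunPreprocessor",
]


def qc_motion(run: BoldRun, threshold_mm: float = 3.0) -> QCDecision:
    """Retain a run iff max translation displacement < ``threshold_mm`` (strict)."""
    trans = run.motion[:, :3] - run.motion[0, :3]
    max_disp = float(np.linalg.norm(trans, axis=1).max())
    return QCDecision(
        run_id=f"{run.subject_id}_run-{run.run_index:02d}",
        max_displacement_mm=max_disp,
        retained=max_disp < threshold_mm,
    )


def _poly_basis(t: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, t)
    return np.polynomial.legendre.legvander(x, order)


def despike(series: np.ndarray, clip_c1: float = 2.5, clip_c2: float = 4.0) -> np.ndarray:
    """Compress extreme time-series outliers with a smooth saturating map.

    A quadratic running fit is subtracted; residuals within ``clip_c1`` robust
    SDs (1.4826*MAD) pass unchanged, beyond that they are compressed by
    s -> c1 + (c2 - c1) * tanh((s - c1)/(c2 - c1)), which is continuous,
    monotone, and bounded by ``clip_c2`` robust SDs.  Works on any (..., t)
    array along the last axis.
    """
    if clip_c2 <= clip_c1:
        raise ValueError(f"clip_c2 ({clip_c2}) must exceed clip_c1 ({clip_c1})")
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 3:
        raise ValueError("despike needs at least 3 timepoints")
    basis = _poly_basis(t, 2)
    coef, *_ = np.linalg.lstsq(basis, series.reshape(-1, t).T, rcond=None)
    fit = (basis @ coef).T.reshape(series.shape)
    resid = series - fit
    mad = np.median(np.abs(resid - np.median(resid, axis=-1, keepdims=True)),
                    axis=-1, keepdims=True)
    sd = 1.4826 * mad
    sd = np.where(sd <= 0, 1.0, sd)
    s = resid / sd
    a = np.abs(s)
    span = clip_c2 - clip_c1
    compressed = clip_c1 + span * np.tanh((a - clip_c1) / span)
    s_new = np.where(a > clip_c1, np.sign(s) * compressed, s)
    return fit + s_new * sd


def detrend(series: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a polynomial trend (default linear + quadratic, plus mean)."""
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t <= order + 1:
        raise ValueError(f"need more than {order + 1} timepoints for order-{order} detrend")
    basis = _poly_basis(t, order)
    coef, *_ = np.linalg.lstsq(basis, series.reshape(-1, t).T, rcond=None)
    fit = (basis @ coef).T.reshape(series.shape)
    return series - fit


def bandpass(series: np.ndarray, tr_seconds: float,
             f_lo: float = 0.009, f_hi: float = 0.1) -> np.ndarray:
    """Ideal Fourier band-pass: rFFT bins with f_lo <= f <= f_hi (inclusive)
    are retained, all others zeroed."""
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= f_lo < f_hi):
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"f_hi = {f_hi} Hz exceeds Nyquist = {nyquist} Hz")
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    coef = np.fft.rfft(series, axis=-1)
    coef[..., ~keep] = 0.0
    return np.fft.irfft(coef, n=t, axis=-1)


def smooth_spatial(volume: np.ndarray, fwhm_mm: float = 6.0,
                   voxel_mm=(4.0, 4.0, 4.0)) -> np.ndarray:
    """Separable Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis."""
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox,
                                   mode="nearest")


def normalize_intensity(run: BoldRun, target: float = 10000.0) -> BoldRun:
    """Scale the whole 4D run by one factor so the in-mask grand mean = target."""
    grand_mean = float(run.data[run.brain_mask].mean())
    if abs(grand_mean) < 1e-12:
        raise ValueError("in-mask grand mean is zero; cannot normalize")
    return run.replace_data(run.data * (target / grand_mean))


def extract_nuisance(run: BoldRun, wm_prob_threshold: float = 0.8,
                     csf_prob_threshold: float = 0.8) -> NuisanceSet:
    """Global / WM / CSF mean series plus the six motion parameters."""
    flat = run.data.reshape(-1, run.n_volumes)
    g = flat[run.brain_mask.ravel()].mean(axis=0)
    out = {"global": g}
    for name, prob, thr in (("wm", run.wm_prob, wm_prob_threshold),
                            ("csf", run.csf_prob, csf_prob_threshold)):
        m = prob >= thr
        if not m.any():
            raise ValueError(f"{name} mask empty at probability threshold {thr}")
        out[name] = flat[m.ravel()].mean(axis=0)
    return NuisanceSet(global_signal=out["global"], wm=out["wm"], csf=out["csf"],
                       motion=run.motion.copy())


def nuisance_regress(run: BoldRun, nuisance: NuisanceSet) -> BoldRun:
    """Voxelwise OLS residuals on [intercept + 9 nuisance regressors].

    Out-of-mask voxels are zeroed.  Residuals are mean-zero per voxel.
    """
    t = run.n_volumes
    X = np.column_stack([np.ones(t), nuisance.design()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which columns are collinear via QR diagonal
        labels = ["intercept", "global", "wm", "csf"] + [f"motion{i}" for i in range(6)]
        _, r = np.linalg.qr(X)
        bad = [labels[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"nuisance design is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"collinear columns: {bad}")
    flat = run.data.reshape(-1, t)
    in_mask = run.brain_mask.ravel()
    Y = flat[in_mask].T  # (t, nvox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(flat)
    out[in_mask] = resid.T
    return run.replace_data(out.reshape(run.data.shape))


class RunPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying the full per-run chain.

    Parameters mirror the pipeline stages; ``fit`` is a no-op (kept for
    sklearn composition).  ``transform`` maps a :class:`BoldRun` to its
    preprocessed residual run.
    """

    def __init__(self, despike_enabled: bool = True, despike_c1: float = 2.5,
                 despike_c2: float = 4.0, detrend_order: int = 2,
                 f_lo_hz: float = 0.009, f_hi_hz: float = 0.1,
                 smooth_fwhm_mm: float = 6.0, normalize_target: float = 10000.0,
                 wm_prob_threshold: float = 0.8, csf_prob_threshold: float = 0.8):
        self.despike_enabled = despike_enabled
        self.despike_c1 = despike_c1
        self.despike_c2 = despike_c2
        self.detrend_order = detrend_order
        self.f_lo_hz = f_lo_hz
        self.f_hi_hz = f_hi_hz
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.normalize_target = normalize_target
        self.wm_prob_threshold = wm_prob_threshold
        self.csf_prob_threshold = csf_prob_threshold

    def fit(self, X=None, y=None):
        return self

    def transform(self, run: BoldRun) -> BoldRun:
        t = run.n_volumes
        flat = run.data.reshape(-1, t)
        in_mask = run.brain_mask.ravel()
        series = flat[in_mask]
        mean = series.mean(axis=1, keepdims=True)
        fluct = series - mean
        if self.despike_enabled:
            fluct = despike(fluct, self.despike_c1, self.despike_c2)
        fluct = bandpass(fluct, run.tr_seconds, self.f_lo_hz, self.f_hi_hz)
        fluct = detrend(fluct, self.detrend_order)
        data = np.zeros_like(flat)
        data[in_mask] = fluct + mean
        data = data.reshape(run.data.shape)
        if self.smooth_fwhm_mm > 0:
            vox = run.voxel_size_mm
            sigma_vox = self.smooth_fwhm_mm * FWHM_TO_SIGMA / vox
            data = ndimage.gaussian_filter(
                data, sigma=tuple(sigma_vox) + (0.0,), mode="nearest")
        out = run.replace_data(data)
        out = normalize_intensity(out, self.normalize_target)
        nuis = extract_nuisance(out, self.wm_prob_threshold, self.csf_prob_threshold)
        return nuisance_regress(out, nuis)

    @classmethod
    def from_params(cls, pp) -> "RunPreprocessor":
        """Build from a :class:`traitconn.config.PreprocParams`."""
        return cls(despike_enabled=pp.despike, despike_c1=pp.despike_c1,
                   despike_c2=pp.despike_c2, detrend_order=pp.detrend_order,
                   f_lo_hz=pp.f_lo_hz, f_hi_hz=pp.f_hi_hz,
                   smooth_fwhm_mm=pp.smooth_fwhm_mm,
                   normalize_target=pp.normalize_target,
                   wm_prob_threshold=pp.wm_prob_threshold,
                   csf_prob_threshold=pp.csf_prob_threshold)
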