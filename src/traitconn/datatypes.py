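"""Core data containers for the trait-connectivity pipeline.

All spatial coordinates exposed to users are MNI millimetres; voxel indices
(0-based) are internal.  A 4x4 affine maps voxel indices to mm, as in NIfTI-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMAIN_NAMES = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")

VALENCE_CLASSES = ("invariant_pos", "invariant_neg", "variable")


@dataclass
class TraitProfile:
    """Five-factor personality domain scores plus demographics for one subject.

    Scores are on the raw NEO domain-score scale (each domain roughly
    0-192, population mean ~80-125 depending on domain).
    """

    subject_id: str
    scores: dict[str, float]
    age: float
    sex: int  # 0/1 coding; only its role as a nuisance covariate matters

    def __post_init__(self) -> None:
        if set(self.scores) != set(DOMAIN_NAMES):
            raise ValueError(
                f"scores must contain exactly the five domains {DOMAIN_NAMES}, "
                f"got {sorted(self.scores)}"
            )
        vals = np.array([self.scores[d] for d in DOMAIN_NAMES], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite domain score for subject {self.subject_id}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")

    def score_vector(self) -> np.ndarray:
        return np.array([self.scores[d] for d in DOMAIN_NAMES], dtype=float)


@dataclass
class SeedSpec:
    """A spherical seed region of interest defined in MNI mm."""

    name: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = 8.0
    hemisphere: str = "bilateral"

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"seed {self.name}: diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class PlantedEffect:
    """Ground-truth seed-target coupling for the synthetic cohort.

    The target region shares the seed's latent network signal with coupling

        c_subject = baseline_coupling + sum_d trait_slope[d] * (score_d - mean_d)

    ``valence_class`` records the intended group-level connectivity valence:
    ``invariant_pos``/``invariant_neg`` require a strong signed baseline,
    ``variable`` a baseline near zero.
    """

    seed_name: str
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    baseline_coupling: float = 0.0
    trait_slope: dict[str, float] = field(default_factory=dict)
    valence_class: str = "variable"

    def __post_init__(self) -> None:
        if self.valence_class not in VALENCE_CLASSES:
            raise ValueError(f"unknown valence_class {self.valence_class!r}")
        unknown = set(self.trait_slope) - set(DOMAIN_NAMES)
        if unknown:
            raise ValueError(f"trait_slope references unknown domains {sorted(unknown)}")
        b = self.baseline_coupling
        if self.valence_class == "invariant_pos" and b <= 0.2:
            raise ValueError(f"invariant_pos effect {self.name} needs a strongly positive baseline")
        if self.valence_class == "invariant_neg" and b >= -0.2:
            raise ValueError(f"invariant_neg effect {self.name} needs a strongly negative baseline")
        if self.valence_class == "variable" and abs(b) > 0.15:
            raise ValueError(f"variable effect {self.name} needs a near-zero baseline")


@dataclass
class BoldRun:
    """One 4D resting-state acquisition with its motion table and masks.

    ``data`` is (x, y, z, t) in arbitrary units; ``affine`` maps voxel index
    to MNI mm; ``motion`` is (t, 6): three translations in mm then three
    rotations in radians.  Masks share the run's grid: ``brain`` is boolean,
    ``wm``/``csf`` are tissue probabilities in [0, 1].
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    motion: np.ndarray
    brain_mask: np.ndarray
    wm_prob: np.ndarray
    csf_prob: np.ndarray
    subject_id: str = ""
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion table must have exactly 6 columns")
        if self.motion.shape[0] != self.n_volumes:
            raise ValueError(
                f"motion table length {self.motion.shape[0]} != n_volumes {self.n_volumes}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        for name, m in (("wm", self.wm_prob), ("csf", self.csf_prob)):
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} probability mask outside [0, 1]")
        for name, m in (("brain", self.brain_mask), ("wm", self.wm_prob), ("csf", self.csf_prob)):
            if m.shape != self.shape3d:
                raise ValueError(f"{name} mask grid {m.shape} != run grid {self.shape3d}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def replace_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(
            data=data,
            tr_seconds=self.tr_seconds,
            affine=self.affine,
            motion=self.motion,
            brain_mask=self.brain_mask,
            wm_prob=self.wm_prob,
            csf_prob=self.csf_prob,
            subject_id=self.subject_id,
            run_index=self.run_index,
        )


@dataclass
class SubjectRecord:
    """Phenotype plus the retained runs entering a subject's RSFC estimate."""

    profile: TraitProfile
    n_scans: int

    @property
    def subject_id(self) -> str:
        return self.profile.subject_id


@dataclass
class ConnectivityMap:
    """Per-subject, per-seed Fisher-z connectivity map on the common grid."""

    subject_id: str
    seed_name: str
    z: np.ndarray
    n_runs_averaged: int

    def __post_init__(self) -> None:
        if self.n_runs_averaged < 1:
            raise ValueError("n_runs_averaged must be >= 1")


@dataclass
class QCDecision:
    """Motion quality-control verdict for one run."""

    run_id: str
    max_displacement_mm: float
    retained: bool


@dataclass
class NuisanceSet:
    """The nine nuisance regressors: global, WM, CSF means and six motion params."""

    global_signal: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    motion: np.ndarray

    def __post_init__(self) -> None:
        t = len(self.global_signal)
        if len(self.wm) != t or len(self.csf) != t or self.motion.shape != (t, 6):
            raise ValueError("all nuisance series must share the run's number of volumes")

    def design(self) -> np.ndarray:
        """Stack the nine regressors as a (t, 9) matrix."""
        return np.column_stack([self.global_signal, self.wm, self.csf, self.motion])


@dataclass
class SmoothnessEstimate:
    """Spatial smoothness of a residual field, as per-axis FWHM and resels."""

    fwhm_mm: np.ndarray  # length 3
    resels_per_voxel: float
    n_resels: float
    n_voxels: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.fwhm_mm) <= 0):
            raise ValueError("FWHM estimates must be positive")
        if self.n_resels <= 0:
            raise ValueError("resel count must be positive")
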