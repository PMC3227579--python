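"""Characterization of trait-associated connectivity maps.

Voxels where a trait effect is significant are sorted by the valence of the
group-mean connectivity at that voxel: ``invariant_pos`` if it falls in the
significant-positive group-mean mask, ``invariant_neg`` if in the negative
mask, ``variable`` otherwise.  Conjunction maps binarize thresholded maps and
sum them voxelwise; local peaks are strict 26-neighbourhood maxima filtered
greedily by a minimum separation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

VALENCE_CODES = {"invariant_pos": 1, "invariant_neg": 2, "variable": 3}

__all__ = ["classify_valence", "conjunction", "local_peaks", "ValenceLabelMap",
           "ConjunctionMap"]


@dataclass
class ValenceLabelMap:
    labels: np.ndarray  # int-coded, 0 where not significant
    histogram: dict[str, int]


@dataclass
class ConjunctionMap:
    sum_map: np.ndarray
    level_counts: dict[int, int]


def classify_valence(domain_sig_mask: np.ndarray, group_pos_mask: np.ndarray,
                     group_neg_mask: np.ndarray) -> ValenceLabelMap:
    """Label each significant voxel by the valence of its group-mean RSFC."""
    sig = np.asarray(domain_sig_mask, dtype=bool)
    pos = np.asarray(group_pos_mask, dtype=bool)
    neg = np.asarray(group_neg_mask, dtype=bool)
    if sig.shape != pos.shape or sig.shape != neg.shape:
        raise ValueError("masks must share one grid")
    if (pos & neg).any():
        raise ValueError("positive and negative group-mean masks overlap")
    labels = np.zeros(sig.shape, dtype=np.int8)
    labels[sig & pos] = VALENCE_CODES["invariant_pos"]
    labels[sig & neg] = VALENCE_CODES["invariant_neg"]
    labels[sig & ~pos & ~neg] = VALENCE_CODES["variable"]
    hist = {name: int((labels == code).sum()) for name, code in VALENCE_CODES.items()}
    return ValenceLabelMap(labels=labels, histogram=hist)


def conjunction(maps: list[np.ndarray]) -> ConjunctionMap:
    """Binarize each thresholded map and sum voxelwise.

    ``level_counts[k]`` is the number of voxels present in exactly k maps,
    for k = 0 .. len(maps); the top level counts voxels common to all maps.
    """
    if len(maps) < 2:
        raise ValueError("conjunction needs at least two maps")
    shapes = {np.asarray(m).shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps on mismatched grids: {sorted(shapes)}")
    total = np.zeros(maps[0].shape, dtype=np.int16)
    for m in maps:
        total += (np.asarray(m) != 0).astype(np.int16)
    counts = {k: int((total == k).sum()) for k in range(len(maps) + 1)}
    return ConjunctionMap(sum_map=total, level_counts=counts)


def local_peaks(z_map: np.ndarray, cluster_labels: np.ndarray, affine: np.ndarray,
                min_separation_mm: float = 20.0) -> pd.DataFrame:
    """Local peaks per cluster: strict 26-neighbourhood maxima, greedily
    filtered by descending Z to enforce the minimum separation (in mm).

    Returns columns: cluster_id, x_mm, y_mm, z_mm, peak_z.
    """
    z = np.asarray(z_map, dtype=float)
    labels = np.asarray(cluster_labels)
    aff = np.asarray(affine, dtype=float)
    voxel = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    if min_separation_mm < voxel.max():
        raise ValueError("min_separation_mm must be at least the voxel size")

    # strict local maxima: greater than every 26-neighbour
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(np.nan_to_num(z, nan=-np.inf),
                                       footprint=footprint, mode="constant",
                                       cval=-np.inf)
    rows = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        members = labels == cid
        cand = members & np.isfinite(z) & (z > neigh_max)
        coords = np.argwhere(cand)
        if coords.size == 0:  # plateau-only cluster: fall back to its maximum
            vals = np.where(members, z, -np.inf)
            coords = np.argwhere(vals == vals.max())[:1]
        order = np.argsort([-z[tuple(c)] for c in coords], kind="stable")
        kept_mm: list[np.ndarray] = []
        for i in order:
            c = coords[i]
            mm = aff[:3, :3] @ c.astype(float) + aff[:3, 3]
            if all(np.linalg.norm(mm - prev) >= min_separation_mm for prev in kept_mm):
                kept_mm.append(mm)
                rows.append({"cluster_id": int(cid), "x_mm": float(mm[0]),
                             "y_mm": float(mm[1]), "z_mm": float(mm[2]),
                             "peak_z": float(z[tuple(c)])})
    return pd.DataFrame(rows, columns=["cluster_id", "x_mm", "y_mm", "z_mm", "peak_z"])
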