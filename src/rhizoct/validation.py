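"""Brute-force reference implementations for validating the fast pipeline paths.

Each function here recomputes a pipeline quantity by direct enumeration —
exhaustive inscribed-sphere search for local thickness, all-pairs minima for
the distance transform, direct recounting from a generator change ledger —
sharing no code with the production implementations.  They are quadratic or
worse and meant for small grids (≤ ~64³) in tests and acceptance checks.
"""

from __future__ import annotations

import numpy as np

from .volume_io import LabelVolume, SoilClass


def brute_force_edt(root_mask: np.ndarray, voxel_mm: float) -> np.ndarray:
    """All-pairs minimum Euclidean distance (mm) to the root set."""
    root_mask = np.asarray(root_mask, dtype=bool)
    sources = np.argwhere(root_mask).astype(float)
    if len(sources) == 0:
        raise ValueError("empty root mask")
    coords = np.indices(root_mask.shape).reshape(3, -1).T.astype(float)
    out = _min_dist(coords, sources)
    return out.reshape(root_mask.shape) * voxel_mm


def _min_dist(points: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Chunked all-pairs minimum Euclidean distance from points to references."""
    ref_sq = (references ** 2).sum(axis=1)
    out = np.empty(len(points))
    step = max(1, 40_000_000 // max(len(references), 1))
    for i in range(0, len(points), step):
        chunk = points[i:i + step]
        d2 = ((chunk ** 2).sum(axis=1)[:, None] + ref_sq[None, :]
              - 2.0 * chunk @ references.T)
        out[i:i + step] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return out


def brute_force_local_thickness(pore_mask: np.ndarray, voxel_mm: float) -> np.ndarray:
    """Exhaustive maximal-ball search (mm), volume faces treated as solid.

    For every candidate centre c the inscribed radius is the distance to the
    nearest solid voxel centre, computed by direct enumeration over all solid
    voxels.  Every pore voxel then takes the diameter of the largest ball
    covering it (centre within the ball radius).
    """
    pore_mask = np.asarray(pore_mask, dtype=bool)
    out = np.zeros(pore_mask.shape, dtype=float)
    if not pore_mask.any():
        return out
    padded = np.pad(pore_mask, 1, mode="constant", constant_values=False)
    solid = np.argwhere(~padded).astype(float) - 1.0  # back to unpadded coordinates
    pores = np.argwhere(pore_mask).astype(float)

    # inscribed radius at every candidate centre: exact nearest-solid query
    from scipy.spatial import cKDTree

    radii, _ = cKDTree(solid).query(pores, k=1)

    # every pore voxel takes the largest ball that covers it; each candidate
    # sphere is expanded by an exact fixed-radius neighbour query
    thickness = np.zeros(len(pores))
    tree = cKDTree(pores)
    covered = tree.query_ball_point(pores, radii + 1e-9)
    for j, members in enumerate(covered):
        d = 2.0 * radii[j]
        for m in members:
            if thickness[m] < d:
                thickness[m] = d
    idx = tuple(pores.astype(int).T)
    out[idx] = thickness
    return out * voxel_mm


def induced_profile_from_ledger(truth, dist_mm: np.ndarray,
                                labels_before: LabelVolume,
                                bin_edges_mm: np.ndarray,
                                border_mm: float) -> np.ndarray:
    """Per-bin macropore induced change recounted directly from the change ledger.

    Reconstructs the after-growth macropore state by applying the ledger's
    per-voxel (before, after) class pairs on top of the before-growth labels,
    then counts gains minus losses per distance shell over the common soil
    domain — an independent path to the same quantity the decomposition
    recovers from the paired images.
    """
    pore_codes = (int(SoilClass.MACROPORE), int(SoilClass.BIOPORE))
    root_codes = (int(SoilClass.ROOT_OLD), int(SoilClass.ROOT_NEW))
    before = labels_before.labels
    after = before.copy()
    zc, yc, xc = truth.change_coords.T
    after[zc, yc, xc] = truth.class_after

    domain = ~np.isin(before, root_codes) & ~np.isin(after, root_codes)
    pore_b = np.isin(before, pore_codes)
    pore_a = np.isin(after, pore_codes)
    edges = np.asarray(bin_edges_mm, dtype=float)
    out = np.zeros(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        shell = domain & (dist_mm > max(lo, border_mm)) & (dist_mm <= hi)
        n = int(shell.sum())
        if n:
            gained = int((shell & pore_a & ~pore_b).sum())
            lost = int((shell & pore_b & ~pore_a).sum())
            out[i] = (gained - lost) / n
    return out
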