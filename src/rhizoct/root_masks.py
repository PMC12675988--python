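"""New-root masks, biopore classification, and root growth-environment shares.

Roots present in both scans are old field roots; the newly grown root mask is the
after-growth root segmentation minus a (slightly dilated) before-growth root
segmentation.  The one-voxel dilation tolerance absorbs sub-voxel registration
error between the two scans.

Biopores — macropores of biological origin (former root channels, faunal
burrows) — are recognised by their cylindrical shape: an elongated skeleton with
a near-constant diameter along it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .pore_metrics import local_thickness
from .volume_io import LabelVolume, SoilClass


@dataclass
class ClassShares:
    """Percentages of new-root volume grown into each before-growth structure.

    Sums to 100 (up to float epsilon).  A structure absent from a core (e.g. no
    pre-existing biopores in repacked soil) simply carries 0.
    """

    matrix_pct: float
    macropore_pct: float
    biopore_pct: float
    old_root_pct: float | None = None  # populated only when old roots are tallied apart

    def as_tuple(self) -> tuple[float, ...]:
        vals = (self.matrix_pct, self.macropore_pct, self.biopore_pct)
        return vals if self.old_root_pct is None else vals + (self.old_root_pct,)


def new_root_mask(roots_before_mask: np.ndarray, roots_after_mask: np.ndarray,
                  tolerance_voxels: int = 1) -> np.ndarray:
    """After-roots minus before-roots, with a dilation tolerance on the latter."""
    before = np.asarray(roots_before_mask, dtype=bool)
    after = np.asarray(roots_after_mask, dtype=bool)
    if before.shape != after.shape:
        raise ValueError(f"mask shapes differ: {before.shape} vs {after.shape}")
    if tolerance_voxels < 0:
        raise ValueError("tolerance_voxels must be >= 0")
    if tolerance_voxels and before.any():
        structure = np.ones((3, 3, 3), dtype=bool)
        before = ndimage.binary_dilation(before, structure, iterations=tolerance_voxels)
    return after & ~before


def classify_biopores(macropore_mask: np.ndarray, voxel_mm: float,
                      min_elongation: float = 4.0,
                      max_diameter_cv: float = 0.5,
                      min_length_mm: float = 1.0,
                      min_diameter_mm: float = 0.1) -> np.ndarray:
    """Select the cylindrical connected components of the macropore phase.

    A component qualifies as a biopore when its skeleton is long relative to its
    mean local thickness (``skeleton length / mean diameter >= min_elongation``),
    the diameter varies little along the skeleton (coefficient of variation
    ``<= max_diameter_cv``), and the channel has the absolute length
    (``>= min_length_mm``) and calibre (``>= min_diameter_mm``) of a real root
    or faunal channel — chance alignments of small packing pores are elongated
    but short and thin, and channels only a few voxels across cannot be
    shape-classified reliably.  Idempotent: reclassifying the biopore output
    returns it unchanged.
    """
    macropore_mask = np.asarray(macropore_mask, dtype=bool)
    out = np.zeros(macropore_mask.shape, dtype=bool)
    if not macropore_mask.any():
        return out
    labeled, n = ndimage.label(macropore_mask, structure=np.ones((3, 3, 3)))
    thickness = local_thickness(macropore_mask, voxel_mm).thickness_mm
    skeleton = skeletonize(macropore_mask)
    for comp in range(1, n + 1):
        comp_mask = labeled == comp
        skel = skeleton & comp_mask
        n_skel = int(skel.sum())
        if n_skel == 0:
            continue
        diam = thickness[skel]
        mean_d = diam.mean()
        if mean_d <= 0:
            continue
        length_mm = n_skel * voxel_mm
        elongation = length_mm / mean_d
        cv = diam.std() / mean_d
        if (elongation >= min_elongation and cv <= max_diameter_cv
                and length_mm >= min_length_mm and mean_d >= min_diameter_mm):
            out |= comp_mask
    return out


def root_environment_shares(new_root: np.ndarray, labels_before: LabelVolume,
                            old_roots_as_biopore: bool = True) -> ClassShares:
    """Before-growth structure shares under the newly grown root.

    Old-root voxels overgrown by a new root count as biopore occupancy by
    default — biopores include channels previously created by roots — or as a
    separate category when ``old_roots_as_biopore`` is False.
    """
    new_root = np.asarray(new_root, dtype=bool)
    if new_root.shape != labels_before.shape:
        raise ValueError("new-root mask and before-labels shapes differ")
    n_total = int(new_root.sum())
    if n_total == 0:
        raise ValueError("empty new-root mask: shares are undefined")
    before = labels_before.labels[new_root]
    counts = np.bincount(before, minlength=5).astype(float)
    matrix = counts[SoilClass.MATRIX]
    macro = counts[SoilClass.MACROPORE]
    bio = counts[SoilClass.BIOPORE]
    old = counts[SoilClass.ROOT_OLD] + counts[SoilClass.ROOT_NEW]
    scale = 100.0 / n_total
    if old_roots_as_biopore:
        return ClassShares(matrix * scale, macro * scale, (bio + old) * scale)
    return ClassShares(matrix * scale, macro * scale, bio * scale, old * scale)
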