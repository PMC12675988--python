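"""Decompose rhizosphere porosity gradients into two mechanisms.

For each distance shell ``d`` around the newly grown root:

* root-induced change   ``induced(d)   = phi_after(d) − phi_before(d)``
  — what root activity did to local porosity at fixed positions;
* growth-preference effect ``preference(d) = phi_before(d) − mean_total_before``
  — how much the locations the root chose already differed from the core mean.

Both local porosities are evaluated against the SAME distance field, the one
seeded by the new roots in the after-growth image, so the before-profile reads
porosity at the positions later populated by roots.  The two terms add exactly:

    induced(d) + preference(d) = phi_after(d) − mean_total_before

and the residual of that identity is carried along for auditing.  The mean total
macroporosity reference is taken from the before-growth image by default (the
pre-growth core mean); it can be switched to the after-growth mean, which shifts
only the preference term and the identity reference, never the induced term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradients import DistanceMap, ShellProfile, distance_from_root, shell_profile
from .pore_metrics import classify_pores, local_thickness, total_macroporosity
from .volume_io import LabelVolume, SoilClass


@dataclass
class DecompositionProfile:
    bin_edges_mm: np.ndarray
    phi_before: np.ndarray
    phi_after: np.ndarray
    mean_total_before: float
    induced: np.ndarray
    preference: np.ndarray
    identity_residual: np.ndarray
    n_domain_voxels: np.ndarray | None = None

    def to_frame(self, core_id: str = "core") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_id": core_id,
                "bin_lower_mm": self.bin_edges_mm[:-1],
                "bin_upper_mm": self.bin_edges_mm[1:],
                "phi_before": self.phi_before,
                "phi_after": self.phi_after,
                "mean_total_before": self.mean_total_before,
                "induced": self.induced,
                "preference": self.preference,
                "identity_residual": self.identity_residual,
            }
        )


def decompose(profile_before: ShellProfile, profile_after: ShellProfile,
              mean_total_before: float) -> DecompositionProfile:
    """Per-bin induced and preference terms from paired before/after profiles.

    Both profiles must share bin edges and must have been computed on the same
    distance map (seeded by the after-image new roots).
    """
    if profile_before.n_bins != profile_after.n_bins or not np.allclose(
        profile_before.bin_edges_mm, profile_after.bin_edges_mm
    ):
        raise ValueError("before/after profiles have mismatching bins")
    phi_b = np.asarray(profile_before.local_value, dtype=float)
    phi_a = np.asarray(profile_after.local_value, dtype=float)
    induced = phi_a - phi_b
    preference = phi_b - mean_total_before
    residual = (induced + preference) - (phi_a - mean_total_before)
    return DecompositionProfile(
        bin_edges_mm=profile_before.bin_edges_mm,
        phi_before=phi_b,
        phi_after=phi_a,
        mean_total_before=float(mean_total_before),
        induced=induced,
        preference=preference,
        identity_residual=residual,
        n_domain_voxels=profile_after.n_domain_voxels,
    )


def _soil_domain(labels_before: LabelVolume, labels_after: LabelVolume) -> np.ndarray:
    """Common soil domain: voxels that are not root in either image."""
    return labels_before.soil_domain_mask() & labels_after.soil_domain_mask()


def macropore_decomposition(labels_before: LabelVolume, labels_after: LabelVolume,
                            bin_edges_mm=None, border_exclusion_mm: float | None = None,
                            dist: DistanceMap | None = None) -> DecompositionProfile:
    """Full macroporosity decomposition from paired, registered label volumes.

    Macropores and biopores are pooled — a biopore is just a macropore of
    cylindrical shape — so relabelling between the two classes cannot change
    the result.
    """
    if labels_before.shape != labels_after.shape:
        raise ValueError("before/after label volumes have different shapes")
    if dist is None:
        dist = distance_from_root(labels_after)
    domain = _soil_domain(labels_before, labels_after)
    prof_b = shell_profile(dist, labels_before.pore_mask(), domain,
                           bin_edges_mm, border_exclusion_mm)
    prof_a = shell_profile(dist, labels_after.pore_mask(), domain,
                           bin_edges_mm, border_exclusion_mm)
    mean_total = total_macroporosity(labels_before.pore_mask(),
                                     labels_before.soil_domain_mask())
    return decompose(prof_b, prof_a, mean_total)


def narrow_pore_decomposition(labels_before: LabelVolume, labels_after: LabelVolume,
                              bin_edges_mm=None, border_exclusion_mm: float | None = None,
                              dist: DistanceMap | None = None,
                              macropore_min_mm: float = 0.04,
                              narrow_max_mm: float = 0.15) -> DecompositionProfile:
    """Same decomposition with narrow pores (0.04–0.15 mm diameter) as the target.

    Narrow masks are derived from the local thickness of each image's pore
    phase, so root-made thin pores (the surface wall effect) and compacted thin
    pores both register.
    """
    if labels_before.shape != labels_after.shape:
        raise ValueError("before/after label volumes have different shapes")
    if dist is None:
        dist = distance_from_root(labels_after)
    domain = _soil_domain(labels_before, labels_after)
    voxel_mm = labels_before.voxel_mm
    narrow_b = classify_pores(local_thickness(labels_before.pore_mask(), voxel_mm),
                              macropore_min_mm, narrow_max_mm).narrow_mask
    narrow_a = classify_pores(local_thickness(labels_after.pore_mask(), voxel_mm),
                              macropore_min_mm, narrow_max_mm).narrow_mask
    prof_b = shell_profile(dist, narrow_b, domain, bin_edges_mm, border_exclusion_mm)
    prof_a = shell_profile(dist, narrow_a, domain, bin_edges_mm, border_exclusion_mm)
    mean_total = total_macroporosity(narrow_b, labels_before.soil_domain_mask())
    return decompose(prof_b, prof_a, mean_total)


def total_macroporosity_change(labels_before: LabelVolume, labels_after: LabelVolume,
                               core_id: str = "core",
                               bin_edges_mm=None,
                               border_exclusion_mm: float | None = None):
    """Core-level after-minus-before total macroporosity, plus the regression pair.

    Both totals are taken over the common soil domain (voxels that are root in
    neither image), so space newly occupied by the root itself does not register
    as porosity loss.  For planted cores the returned row also carries the
    volume-weighted root-induced change within 1 mm of the new root — the pair
    (rhizosphere induced change, total change) feeds the core-level association
    between local root action and whole-core macroporosity.  Unplanted controls
    (no ROOT_NEW) are flagged and carry no rhizosphere term.
    """
    if labels_before.shape != labels_after.shape:
        raise ValueError("before/after label volumes have different shapes")
    domain = _soil_domain(labels_before, labels_after)
    phi_b = total_macroporosity(labels_before.pore_mask(), domain)
    phi_a = total_macroporosity(labels_after.pore_mask(), domain)
    delta_total = phi_a - phi_b

    row = {
        "core_id": core_id,
        "total_macroporosity_before": phi_b,
        "total_macroporosity_after": phi_a,
        "delta_total": delta_total,
        "is_control": False,
        "induced_rhizosphere_lt1mm": np.nan,
    }
    if labels_after.mask(SoilClass.ROOT_NEW).any():
        dec = macropore_decomposition(labels_before, labels_after,
                                      bin_edges_mm, border_exclusion_mm)
        n = dec.n_domain_voxels.astype(float)
        ok = n > 0
        row["induced_rhizosphere_lt1mm"] = float(
            np.sum(dec.induced[ok] * n[ok]) / n[ok].sum()
        )
    else:
        row["is_control"] = True
    return delta_total, pd.DataFrame([row])
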