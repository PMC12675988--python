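"""Seeded synthetic paired before/after soil cores with exact ground truth.

The generator emulates the ingredients of a root-ingrowth µCT experiment on a
granular soil:

* a matrix phase whose sub-resolution porosity exists only as metadata (pores
  below the ~0.04 mm resolution limit are not imaged);
* carved spherical macropore bodies up to a target macroporosity;
* cylindrical biopores (old root channels) of a stated diameter running through
  the core, one of them crossing the central region where roots start;
* a new root grown as a random-walk tube whose steps target macropore space
  with a tunable probability (roots prefer paths of low penetration
  resistance) and matrix otherwise;
* a near-root perturbation with exact per-voxel bookkeeping: macropores within
  a stated distance band of the root surface are compacted to matrix (or
  matrix loosened to macropores) and, in the first band, matrix is converted
  to narrow pores — the particle-rearrangement "wall effect" at the root
  surface;
* a rhizosheath-like core table whose mass and tracer activity are stated
  monotone functions of the macropore share of the root environment.

Every change the root makes is recorded in a :class:`GroundTruth` ledger, so
every downstream quantity (environment shares, induced profiles, total
macroporosity change) has an exact oracle.  All operations are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .gradients import default_bin_edges
from .root_masks import ClassShares
from .volume_io import LabelVolume, SoilClass, Volume3D

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "InfeasibleParamsError",
    "generate_before",
    "grow_root",
    "simulate_core",
    "synthesize_rhizosheath_table",
    "RHIZOSHEATH_COEFFICIENTS",
]


class InfeasibleParamsError(ValueError):
    """Raised when the requested structures cannot fit in the grid."""


@dataclass
class SyntheticParams:
    """Study conditions for one synthetic core.

    Defaults describe a loamy repacked core at the scanner's 0.0182 mm voxels:
    12% resolvable macroporosity, two 0.4 mm biopores, a 0.1 mm-radius root,
    even odds of the root targeting macropore space at each step, strong
    (−0.5) macropore compaction within 0.04–0.4 mm of the root surface and a
    +0.1 narrow-pore wall effect in the first 0.2 mm.
    """

    shape: tuple[int, int, int] = (48, 180, 180)
    voxel_mm: float = 0.0182
    matrix_microstructure_fraction: float = 0.30  # unresolved; metadata only
    macroporosity_target: float = 0.12
    n_biopores: int = 2
    biopore_diameter_mm: float = 0.4
    pore_radius_range_mm: tuple[float, float] = (0.025, 0.09)
    pore_clustering: float = 0.9  # 0 = uniform pore placement, 1 = fully field-driven
    pore_cluster_scale_mm: float = 0.5  # correlation length of macropore-rich regions
    root_radius_mm: float = 0.10
    p_macropore_preference: float = 0.5
    compaction_amplitude: float = -0.5
    compaction_band_mm: tuple[float, float] = (0.04, 0.4)
    wall_effect_amplitude: float = 0.1
    wall_band_mm: tuple[float, float] = (0.0, 0.2)
    wall_pore_radius_mm: float = 0.033
    n_old_roots: int = 0
    grey_solid: int = 30000
    grey_pore: int = 5000
    grey_root: int = 12000
    grey_noise_sd: float = 1500.0
    persistence: float = 0.6  # direction memory of the root walk
    analysis_band_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("matrix_microstructure_fraction", "macroporosity_target",
                     "p_macropore_preference", "wall_effect_amplitude",
                     "pore_clustering"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.compaction_amplitude <= 1.0:
            raise ValueError("compaction_amplitude must be in [-1, 1]")
        if self.voxel_mm <= 0 or self.root_radius_mm <= 0:
            raise ValueError("voxel_mm and root_radius_mm must be positive")
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError(f"shape must be a 3D grid of at least 8^3, got {self.shape}")

    @property
    def root_radius_vox(self) -> float:
        return self.root_radius_mm / self.voxel_mm

    @property
    def band_margin_vox(self) -> int:
        """Voxels needed around the root axis for the full analysis band."""
        return int(np.ceil((self.analysis_band_mm + self.root_radius_mm)
                           / self.voxel_mm)) + 2


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the synthetic root did.

    ``change_coords``/``class_before``/``class_after`` list exactly the voxels
    whose class differs between the paired label volumes; per-bin induced
    changes and environment shares recomputed from them are exact oracles for
    the analysis pipeline.
    """

    core_id: str
    root_path: np.ndarray  # (n_steps, 3) voxel indices along the root axis
    change_coords: np.ndarray  # (n_changed, 3)
    class_before: np.ndarray
    class_after: np.ndarray
    imposed_class_shares: ClassShares
    imposed_induced_bin_edges_mm: np.ndarray
    imposed_induced_profile: np.ndarray  # expected macropore induced change per bin
    params: SyntheticParams = field(repr=False, default=None)  # type: ignore[assignment]

    def per_voxel_changes(self) -> dict[tuple[int, int, int], tuple[int, int]]:
        """Sparse map voxel -> (class_before, class_after)."""
        return {
            tuple(int(i) for i in c): (int(b), int(a))
            for c, b, a in zip(self.change_coords, self.class_before, self.class_after)
        }


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _carve_ball(labels: np.ndarray, center, radius_vox: float, value: int,
                only_class: int | None = None) -> int:
    """Set a digital ball to ``value``; returns the number of voxels changed."""
    cz, cy, cx = center
    n = int(np.ceil(radius_vox))
    zlo, zhi = max(cz - n, 0), min(cz + n + 1, labels.shape[0])
    ylo, yhi = max(cy - n, 0), min(cy + n + 1, labels.shape[1])
    xlo, xhi = max(cx - n, 0), min(cx + n + 1, labels.shape[2])
    zz, yy, xx = np.meshgrid(np.arange(zlo, zhi) - cz, np.arange(ylo, yhi) - cy,
                             np.arange(xlo, xhi) - cx, indexing="ij")
    ball = zz * zz + yy * yy + xx * xx <= radius_vox * radius_vox
    region = labels[zlo:zhi, ylo:yhi, xlo:xhi]
    if only_class is not None:
        ball &= region == only_class
    changed = int(ball.sum() - (region[ball] == value).sum())
    region[ball] = value
    return changed


def _carve_cylinder(labels: np.ndarray, y0: float, x0: float, radius_vox: float,
                    value: int, rng: np.random.Generator,
                    max_amp: float = 1.5) -> None:
    """Gently curved cylinder along z over the full grid depth."""
    nz, ny, nx = labels.shape
    amp = rng.uniform(0.0, max(max_amp, 0.0))
    wavelength = rng.uniform(1.5 * nz, 3.0 * nz)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for z in range(nz):
        cy = y0 + amp * np.sin(2 * np.pi * z / wavelength + phase)
        cx = x0 + amp * np.cos(2 * np.pi * z / wavelength + phase)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox * radius_vox
        labels[z][disk] = value


def _grey_from_labels(labels: np.ndarray, params: SyntheticParams,
                      rng: np.random.Generator) -> np.ndarray:
    means = np.array([params.grey_solid, params.grey_pore, params.grey_pore,
                      params.grey_root, params.grey_root], dtype=float)
    grey = means[labels] + rng.normal(0.0, params.grey_noise_sd, size=labels.shape)
    return np.clip(grey, 0, 65535).astype(np.uint16)


def generate_before(params: SyntheticParams) -> tuple[Volume3D, LabelVolume]:
    """Pre-growth core: matrix with carved macropores and cylindrical biopores.

    The realized macroporosity (macropores + biopores per soil voxel) lands
    within ±10% (relative) of ``macroporosity_target``; an impossible request
    (biopores that cannot fit, or that alone exceed the target) raises
    :class:`InfeasibleParamsError` rather than silently truncating.
    """
    rng = _rng(params.seed, 0)
    nz, ny, nx = params.shape
    labels = np.full(params.shape, int(SoilClass.MATRIX), dtype=np.uint8)

    bio_r = params.biopore_diameter_mm / 2 / params.voxel_mm
    if params.n_biopores > 0:
        if params.macroporosity_target <= 0:
            raise InfeasibleParamsError(
                "biopores requested but macroporosity_target is 0")
        margin = bio_r + 2
        if 2 * margin >= min(ny, nx):
            raise InfeasibleParamsError(
                f"biopore diameter {params.biopore_diameter_mm} mm does not fit "
                f"in a {ny}x{nx} cross-section")
        centers: list[tuple[float, float]] = [(ny / 2, nx / 2)]  # one crosses the root start region
        tries = 0
        while len(centers) < params.n_biopores:
            tries += 1
            if tries > 5000:
                raise InfeasibleParamsError(
                    f"could not place {params.n_biopores} non-touching biopores")
            y = rng.uniform(margin, ny - margin)
            x = rng.uniform(margin, nx - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= (2 * bio_r + 2) ** 2
                   for cy, cx in centers):
                centers.append((y, x))
        for y, x in centers:
            # curvature amplitude adapts to the clearance towards the nearest
            # neighbouring cylinder so biopores never merge when packed tightly
            gap = min((np.hypot(y - cy, x - cx) - 2 * bio_r
                       for cy, cx in centers if (cy, cx) != (y, x)),
                      default=np.inf)
            _carve_cylinder(labels, y, x, bio_r, int(SoilClass.BIOPORE), rng,
                            max_amp=float(min(1.5, 0.4 * gap)))

    if params.n_old_roots > 0:
        old_r = params.root_radius_vox
        for _ in range(params.n_old_roots):
            y = rng.uniform(old_r + 2, ny - old_r - 2)
            x = rng.uniform(old_r + 2, nx - old_r - 2)
            _carve_cylinder(labels, y, x, old_r, int(SoilClass.ROOT_OLD), rng)

    n_soil = int((labels != int(SoilClass.ROOT_OLD)).sum())
    target_n = params.macroporosity_target * n_soil
    pore_n = int(np.isin(labels, (int(SoilClass.MACROPORE), int(SoilClass.BIOPORE))).sum())
    if pore_n > 1.1 * target_n:
        raise InfeasibleParamsError(
            f"biopores alone give macroporosity {pore_n / n_soil:.3f}, above "
            f"the target {params.macroporosity_target} (+10%)")
    # macropores cluster in pore-rich regions: placement follows a smooth random
    # intensity field, so the core has macropore-rich zones and matrix-dominated
    # zones at the stated correlation length (soil porosity is spatially
    # structured; growth preferences only exist because of that structure)
    if params.pore_clustering > 0:
        sigma = params.pore_cluster_scale_mm / params.voxel_mm
        field = ndimage.gaussian_filter(rng.standard_normal(params.shape), sigma)
        ranks = np.empty(field.size)
        ranks[np.argsort(field, axis=None)] = np.arange(field.size)
        accept = ((1.0 - params.pore_clustering)
                  + params.pore_clustering * (ranks / (field.size - 1)) ** 3)
        accept = accept.reshape(params.shape)
    else:
        accept = None

    r_lo, r_hi = (r / params.voxel_mm for r in params.pore_radius_range_mm)
    guard = 0
    while pore_n < target_n:
        guard += 1
        if guard > 2_000_000:
            raise InfeasibleParamsError("macroporosity target unreachable by carving")
        center = tuple(int(rng.integers(0, s)) for s in params.shape)
        if accept is not None and rng.random() >= accept[center]:
            continue
        pore_n += _carve_ball(labels, center, rng.uniform(r_lo, r_hi),
                              int(SoilClass.MACROPORE),
                              only_class=int(SoilClass.MATRIX))

    grey = _grey_from_labels(labels, params, rng)
    return (Volume3D(grey, params.voxel_mm, origin_label=f"synthetic-{params.seed}"),
            LabelVolume(labels, params.voxel_mm))


_OFFSETS = np.array([(dz, dy, dx)
                     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dz, dy, dx) != (0, 0, 0)], dtype=int)
_OFFSET_UNITS = _OFFSETS / np.linalg.norm(_OFFSETS, axis=1, keepdims=True)


def _walk_root(labels: np.ndarray, params: SyntheticParams,
               rng: np.random.Generator) -> np.ndarray:
    """Random-walk root axis from the bottom to the top margin of the grid.

    Each step targets macropore space (a position whose root-radius ball fits
    inside the pore phase) with probability ``p_macropore_preference``, and
    matrix otherwise; direction persistence keeps the path tube-like.
    """
    nz, ny, nx = labels.shape
    pore = np.isin(labels, (int(SoilClass.MACROPORE), int(SoilClass.BIOPORE)))
    pore_edt = ndimage.distance_transform_edt(pore)
    solid_edt = ndimage.distance_transform_edt(~pore)
    # porosity felt at the root's own scale: matrix-targeted growth follows the
    # path of least penetration resistance, i.e. descends this field
    poro_smooth = ndimage.gaussian_filter(pore.astype(np.float32),
                                          2.0 * params.root_radius_vox)
    r = params.root_radius_vox
    margin = params.band_margin_vox
    wander = min(ny, nx) // 2 - margin
    if wander < 2:
        raise InfeasibleParamsError(
            f"grid cross-section {ny}x{nx} too small for the root plus the "
            f"{params.analysis_band_mm} mm analysis band")
    cy, cx = ny // 2, nx // 2
    z0, z1 = 2, nz - 3

    # start position: deepest point of the targeted phase in the start slice
    start = None
    if rng.random() < params.p_macropore_preference:
        window = pore_edt[z0, cy - wander: cy + wander, cx - wander: cx + wander]
        if window.size and window.max() > r:
            iy, ix = np.unravel_index(np.argmax(window), window.shape)
            start = np.array([z0, cy - wander + iy, cx - wander + ix])
    if start is None:
        # least-resistance start: the matrix column with the lowest mean
        # root-scale porosity (the path runs mostly along z from there)
        column = poro_smooth[:, cy - wander: cy + wander,
                             cx - wander: cx + wander].mean(axis=0)
        matrix_win = labels[z0, cy - wander: cy + wander,
                            cx - wander: cx + wander] == int(SoilClass.MATRIX)
        if column.size == 0 or not matrix_win.any():
            raise InfeasibleParamsError("no matrix voxel available to start the root")
        masked = np.where(matrix_win, column, np.inf)
        iy, ix = np.unravel_index(np.argmin(masked), masked.shape)
        start = np.array([z0, cy - wander + iy, cx - wander + ix])

    path = [start]
    pos = start
    direction = np.array([1.0, 0.0, 0.0])
    max_steps = 30 * nz
    stall = 0
    for _ in range(max_steps):
        if pos[0] >= z1:
            return np.array(path)
        nxt = pos + _OFFSETS
        # never step backwards along the growth axis: the root tip advances,
        # and axis-ward corrections must always stay reachable; after too many
        # lateral moves (circling a local field minimum) force an advance
        ok = ((_OFFSETS[:, 0] >= (1 if stall >= 20 else 0)) & (nxt[:, 0] < nz)
              & (np.abs(nxt[:, 1] - cy) <= wander)
              & (np.abs(nxt[:, 2] - cx) <= wander))
        if not ok.any():
            direction = np.array([1.0, 0.0, 0.0])
            continue
        cand = np.where(ok)[0]
        cand_pos = nxt[cand]
        cand_pore = pore_edt[cand_pos[:, 0], cand_pos[:, 1], cand_pos[:, 2]]
        cand_solid = solid_edt[cand_pos[:, 0], cand_pos[:, 1], cand_pos[:, 2]]
        macro_fit = cand_pore > r  # the whole root ball fits in the pore phase
        matrix_fit = cand_solid > r  # the whole root ball fits in the matrix
        want_macro = rng.random() < params.p_macropore_preference
        if want_macro:
            # stay on the pore axis; without a fitting candidate, climb the
            # pore depth field back towards the pore interior
            if macro_fit.any():
                pool, depth = cand[macro_fit], cand_pore[macro_fit]
            else:
                pool, depth = cand, cand_pore
        else:
            # never enter pore interiors; descend the smoothed-porosity field
            # so the path settles in the macropore-poor zones of the core
            sub = matrix_fit if matrix_fit.any() else (
                ~macro_fit if (~macro_fit).any() else np.ones(len(cand), bool))
            pool, depth = cand[sub], cand_solid[sub]
        units = _OFFSET_UNITS[pool]
        # persistence keeps the path tube-like; the depth weight keeps it on
        # the axis of the targeted phase so the whole tube stays inside it
        score = np.exp(3.0 * params.persistence * (units @ direction)
                       + 0.8 * units[:, 0])
        score = score * (1.0 + depth) ** 3
        if not want_macro:
            pos_pool = nxt[pool]
            score = score * np.exp(
                -60.0 * poro_smooth[pos_pool[:, 0], pos_pool[:, 1], pos_pool[:, 2]])
        choice = pool[rng.choice(len(pool), p=score / score.sum())]
        step = _OFFSETS[choice]
        stall = 0 if step[0] > 0 else stall + 1
        pos = pos + step
        path.append(pos)
        direction = (params.persistence * direction
                     + (1 - params.persistence) * _OFFSET_UNITS[choice])
        direction /= np.linalg.norm(direction)
    raise InfeasibleParamsError("root path could not traverse the grid")


def grow_root(before: LabelVolume, params: SyntheticParams,
              grey_before: Volume3D | None = None,
              core_id: str = "core") -> tuple[LabelVolume, Volume3D, GroundTruth]:
    """Grow a new root through a pre-growth core and perturb its rhizosphere.

    Returns the after-growth label volume, a matching greyscale volume (grey of
    unchanged voxels is preserved when ``grey_before`` is supplied), and the
    exact change ledger.  The input volume is not mutated.
    """
    if before.shape != tuple(params.shape):
        raise ValueError("before volume shape does not match params.shape")
    rng = _rng(params.seed, 1)
    labels_before = before.labels
    path = _walk_root(labels_before, params, rng)

    path_mask = np.zeros(before.shape, dtype=bool)
    path_mask[path[:, 0], path[:, 1], path[:, 2]] = True
    dist_to_axis = ndimage.distance_transform_edt(~path_mask)
    tube = dist_to_axis <= params.root_radius_vox

    labels_after = labels_before.copy()
    labels_after[tube] = int(SoilClass.ROOT_NEW)

    # environment shares of the new root, from the before-growth classes
    before_under_root = labels_before[tube]
    counts = np.bincount(before_under_root, minlength=5).astype(float)
    scale = 100.0 / counts.sum()
    shares = ClassShares(
        matrix_pct=counts[SoilClass.MATRIX] * scale,
        macropore_pct=counts[SoilClass.MACROPORE] * scale,
        biopore_pct=(counts[SoilClass.BIOPORE] + counts[SoilClass.ROOT_OLD]
                     + counts[SoilClass.ROOT_NEW]) * scale,
    )

    dist_mm = ndimage.distance_transform_edt(~tube) * params.voxel_mm

    amp = params.compaction_amplitude
    if amp != 0.0:
        lo, hi = params.compaction_band_mm
        band = (dist_mm > lo) & (dist_mm <= hi)
        if amp < 0:
            cand = band & np.isin(labels_after, (int(SoilClass.MACROPORE),
                                                 int(SoilClass.BIOPORE)))
            hit = cand & (rng.random(size=labels_after.shape) < -amp)
            labels_after[hit] = int(SoilClass.MATRIX)
        else:
            cand = band & (labels_after == int(SoilClass.MATRIX))
            hit = cand & (rng.random(size=labels_after.shape) < amp)
            labels_after[hit] = int(SoilClass.MACROPORE)

    if params.wall_effect_amplitude > 0.0:
        lo, hi = params.wall_band_mm
        band = (dist_mm > lo) & (dist_mm <= hi)
        band_matrix = band & (labels_after == int(SoilClass.MATRIX))
        n_target = int(round(params.wall_effect_amplitude * band_matrix.sum()))
        seeds = np.argwhere(band_matrix)
        rng.shuffle(seeds)
        blob_r = params.wall_pore_radius_mm / params.voxel_mm
        converted = 0
        masked = np.where(band_matrix, labels_after, 255)  # restrict carving to the band
        for center in seeds:
            if converted >= n_target:
                break
            converted += _carve_ball(masked, tuple(center), blob_r,
                                     int(SoilClass.MACROPORE),
                                     only_class=int(SoilClass.MATRIX))
        labels_after[masked == int(SoilClass.MACROPORE)] = int(SoilClass.MACROPORE)

    if grey_before is not None:
        grey = grey_before.data.copy()
        changed_mask = labels_after != labels_before
        means = np.array([params.grey_solid, params.grey_pore, params.grey_pore,
                          params.grey_root, params.grey_root], dtype=float)
        new_vals = (means[labels_after[changed_mask]]
                    + rng.normal(0.0, params.grey_noise_sd, size=int(changed_mask.sum())))
        grey[changed_mask] = np.clip(new_vals, 0, 65535).astype(grey.dtype)
    else:
        grey = _grey_from_labels(labels_after, params, rng)

    change_coords = np.argwhere(labels_after != labels_before)
    class_b = labels_before[change_coords[:, 0], change_coords[:, 1], change_coords[:, 2]]
    class_a = labels_after[change_coords[:, 0], change_coords[:, 1], change_coords[:, 2]]

    edges, induced = _imposed_induced_profile(
        labels_before, labels_after, dist_mm, params)

    truth = GroundTruth(
        core_id=core_id,
        root_path=path,
        change_coords=change_coords,
        class_before=class_b.copy(),
        class_after=class_a.copy(),
        imposed_class_shares=shares,
        imposed_induced_bin_edges_mm=edges,
        imposed_induced_profile=induced,
        params=params,
    )
    return (LabelVolume(labels_after, params.voxel_mm),
            Volume3D(grey, params.voxel_mm, origin_label=f"{core_id}-after"),
            truth)


def _imposed_induced_profile(labels_before, labels_after, dist_mm, params):
    """Expected per-bin macropore induced change, straight from the change set."""
    edges = default_bin_edges(params.voxel_mm, max_mm=params.analysis_band_mm)
    pore_codes = (int(SoilClass.MACROPORE), int(SoilClass.BIOPORE))
    root_codes = (int(SoilClass.ROOT_OLD), int(SoilClass.ROOT_NEW))
    domain = ~np.isin(labels_before, root_codes) & ~np.isin(labels_after, root_codes)
    pore_b = np.isin(labels_before, pore_codes)
    pore_a = np.isin(labels_after, pore_codes)
    border = params.voxel_mm
    out = np.zeros(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        shell = domain & (dist_mm > max(lo, border)) & (dist_mm <= hi)
        n = shell.sum()
        if n:
            out[i] = (int((shell & pore_a).sum()) - int((shell & pore_b).sum())) / n
    return edges, out


def simulate_core(params: SyntheticParams, core_id: str = "core"):
    """Generate a full paired core: before/after volumes, labels and ledger."""
    grey_b, labels_b = generate_before(params)
    labels_a, grey_a, truth = grow_root(labels_b, params, grey_before=grey_b,
                                        core_id=core_id)
    return {
        "grey_before": grey_b,
        "labels_before": labels_b,
        "grey_after": grey_a,
        "labels_after": labels_a,
        "truth": truth,
    }


#: Coefficients of the generating equations of the rhizosheath table:
#: mass_g = mass_intercept + mass_slope * macropore_share_fraction + N(0, sd)
#: tracer_kBq = tracer_intercept + tracer_slope * mass_g + N(0, sd * tracer_slope)
RHIZOSHEATH_COEFFICIENTS = {
    "mass_intercept": 0.5,
    "mass_slope": 2.0,
    "tracer_intercept": 5.0,
    "tracer_slope": 40.0,
}


def synthesize_rhizosheath_table(truths: list[GroundTruth], noise_sd: float = 0.05,
                                 seed: int = 0) -> pd.DataFrame:
    """Rhizosheath mass and tracer activity correlated with root-environment shares.

    Mass rises monotonically with the macropore share of the root's environment
    (pore walls shed adhering soil), and tracer activity — standing in for
    root-derived carbon — rises monotonically with mass.  The generating
    equations and their coefficients are recorded in the frame's ``attrs``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not truths:
        raise ValueError("need at least one GroundTruth")
    rng = _rng(seed, 2)
    c = RHIZOSHEATH_COEFFICIENTS
    rows = []
    for t in truths:
        share = (t.imposed_class_shares.macropore_pct
                 + t.imposed_class_shares.biopore_pct) / 100.0
        mass = c["mass_intercept"] + c["mass_slope"] * share + rng.normal(0, noise_sd)
        tracer = (c["tracer_intercept"] + c["tracer_slope"] * mass
                  + rng.normal(0, noise_sd * c["tracer_slope"]))
        rows.append({
            "core_id": t.core_id,
            "matrix_pct": t.imposed_class_shares.matrix_pct,
            "macropore_pct": t.imposed_class_shares.macropore_pct,
            "biopore_pct": t.imposed_class_shares.biopore_pct,
            "macropore_share_pct": 100.0 * share,
            "rhizosheath_mass_g": mass,
            "tracer_activity_kBq": tracer,
        })
    df = pd.DataFrame(rows)
    df.attrs["generating_equations"] = (
        "mass_g = {mass_intercept} + {mass_slope} * macropore_share_fraction + eps; "
        "tracer_kBq = {tracer_intercept} + {tracer_slope} * mass_g + eps'".format(**c)
    )
    df.attrs["coefficients"] = dict(c)
    df.attrs["noise_sd"] = noise_sd
    return df


def vary(params: SyntheticParams, **kwargs) -> SyntheticParams:
    """Copy of ``params`` with fields replaced (convenience for batch designs)."""
    return replace(params, **kwargs)
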