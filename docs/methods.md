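# Methods

`rhizoct` quantifies how a newly grown plant root and the soil structure around
it shape each other, from paired (before/after growth) segmented X-ray µCT
volumes of soil cores. This note documents the measurement model, the synthetic
data it is validated on, the numerical conventions, and the limits of both.

## The measurement model

### Inputs and classes

The pipeline consumes two co-registered volumes per core on the same isotropic
grid (default voxel edge 0.0182 mm): a greyscale reconstruction and a label map
over five classes — `MATRIX` (soil with only sub-resolution pores),
`MACROPORE` (resolvable pore, local diameter > 0.04 mm), `BIOPORE` (macropore
of biological origin, recognisable by its cylindrical shape), `ROOT_OLD`
(roots already present in the first scan) and `ROOT_NEW`. Segmentation and
registration happen upstream; the package starts from labels.

Biopores are a *subtype* of the macropore phase: every porosity quantity pools
`MACROPORE ∪ BIOPORE`, and relabelling between the two classes cannot change
any porosity result (this is asserted by a test).

### Local thickness and pore classes

The pore size distribution uses the maximal-ball (local thickness) definition:
the thickness at a pore voxel is the diameter of the largest sphere fully
inscribed in the pore phase that contains the voxel. The implementation is
EDT → redundant-ball pruning → sphere propagation, with two fixed conventions:

* a voxel belongs to a sphere of radius *r* iff its centre lies within *r* of
  the sphere centre, and the inscribed radius at a candidate centre is its EDT
  value. This is the standard digital convention; it carries the usual bias of
  up to one voxel against the continuum width (a slab of 3 voxel layers reads
  4 voxels; a digital ball of radius 5 reads 10.2 voxels everywhere).
* volume faces are treated as solid, so thickness is never inflated by the
  unknown space outside the scanned core. This is conservative: pores touching
  a face read thinner than they may be.

Pore classes by thickness *t*: macropore *t* > 0.04 mm (strictly; 0.04 mm is
the resolution limit at these voxels), narrow pore 0.04 < *t* ≤ 0.15 mm — the
small, just-resolvable end of the macropore population and the size range most
favourable to microbial activity. Edge inclusion at 0.04/0.15 is a convention;
both thresholds are arguments.

An exhaustive inscribed-sphere search (`rhizoct.validation`) recomputes the
thickness map by direct enumeration on small grids; pipeline and search agree
exactly on the test volumes, with a ±1 voxel acceptance bound.

### Distance shells around the new root

Every voxel gets its exact Euclidean distance to the nearest `ROOT_NEW` voxel
(old roots are excluded from all soil domains but are *not* distance sources).
The rhizosphere is profiled over the 0–1 mm interval in 0.2 mm half-open shells
`(lo, hi]` — about 10 voxel layers each — with a 0.1 mm variant available. The
voxel layer touching the root surface (distance ≤ one voxel edge, 0.0182 mm) is
excluded by default: partial-volume effects make the exact root boundary
unreliable. Shells with no domain voxel carry NaN and an explicit flag, never a
silent zero.

Local porosity in a shell is `target ∩ domain / domain`, where the domain is
all non-root voxels ("local soil volume"; roots are not soil). Whether the
denominator should also exclude stones or old roots is not observable from the
labels alone; excluding both root classes is our fixed choice. Two exact
identities are enforced by tests: shells partition the domain within
(border, 1 mm], and the volume-weighted mean of per-shell fractions equals the
aggregate fraction of that domain.

Grey-value profiles (µCT-derived density) use the same shells and also report
the cumulative mean from the root surface out to each shell edge.

### The two-mechanism decomposition

A porosity gradient around a root confounds two mechanisms: the root *changed*
the soil, and the root *chose* where to grow. With paired scans both are
identifiable per distance shell *d*:

* root-induced change: `induced(d) = phi_after(d) − phi_before(d)`
* growth-preference effect: `preference(d) = phi_before(d) − mean_total_before`

Both local porosities are evaluated against the *same* distance field — the one
seeded by the new roots in the after image — so `phi_before` reads porosity at
the positions later populated by roots. The terms add exactly:
`induced(d) + preference(d) = phi_after(d) − mean_total_before`; the residual
of this identity is computed and carried in every output for auditing.

`mean_total_before` is the before-growth core mean by default. The source text
for this design is ambiguous about before vs after; switching to the after
mean shifts only the preference term and the identity reference, and is
exposed as a parameter of `decompose`.

Core-level totals (`total_macroporosity_change`) are computed over the common
soil domain — voxels that are root in *neither* image — so the space the root
itself now occupies does not register as porosity loss. Unplanted control
cores pass through this operation only; rhizosphere terms are undefined
without new roots and are flagged as such.

### New-root masks, environment shares, biopore shape

The new-root mask is `after_roots AND NOT dilate(before_roots, 1 voxel)`; the
one-voxel dilation absorbs sub-voxel registration error between scans and is
configurable. Growth-environment shares are the before-growth class
percentages under the new-root voxels (matrix / non-biopore macropore /
biopore); old-root voxels overgrown by a new root count as biopore occupancy
by default, since biopores include channels made by earlier roots. Cores with
no pre-existing biopores simply report a zero share.

Biopore classification operationalises "cylindrical shape" per connected
macropore component: skeleton length / mean local thickness ≥ 4, thickness
coefficient of variation along the skeleton ≤ 0.5, plus two absolute guards —
skeleton length ≥ 1 mm and mean diameter ≥ 0.1 mm. The guards exist because
chance alignments of small packing pores are elongated but short and thin,
and a channel only 2–4 voxels across cannot be shape-classified reliably at
this resolution. All four thresholds are arguments.

## The synthetic paired-core generator

Real cores from this kind of experiment are multi-gigabyte scans; the
generator produces desk-scale paired cores in which every downstream quantity
has exact ground truth via a per-voxel change ledger.

What it emulates, and the defaults (all `SyntheticParams` fields):

* **Grid**: default shape 48×180×180 voxels at 0.0182 mm — the smallest
  cross-section that holds a centred root tube plus the full 1 mm analysis
  band with room for the walk to wander.
* **Matrix** with a stated sub-resolution microstructure fraction (0.30,
  metadata only — such pores are invisible at this voxel size, exactly as in
  a real scan).
* **Macropores**: carved spherical bodies (radii 0.025–0.09 mm) until realized
  macroporosity is within ±10 % (relative) of the 0.12 target. Placement
  follows a smooth correlated random field (correlation length 0.5 mm,
  clustering strength 0.9): real soil porosity is spatially structured, and
  growth *preference* is only a meaningful mechanism when macropore-rich and
  macropore-poor regions exist.
* **Biopores**: gently curved cylinders along the core axis, diameter 0.4 mm,
  one crossing the central region where roots start (so a pore-preferring
  root has a channel available). Curvature shrinks with clearance so packed
  biopores never merge.
* **Root growth**: a 1-voxel-step random walk with direction persistence; each
  step targets macropore space with probability `p_macropore_preference`
  (the targeted position must fit the whole 0.10 mm-radius root ball inside
  the pore phase) and matrix otherwise (descending the porosity field
  smoothed at the root scale — least penetration resistance). The tube of all
  voxels within the root radius of the path becomes `ROOT_NEW`.
* **Rhizosphere perturbation** with exact bookkeeping: macropore voxels within
  a band of the root surface (default 0.04–0.4 mm) convert to matrix with
  probability |compaction_amplitude| (−0.5 by default; positive amplitudes
  loosen instead), and matrix in the first band (0–0.2 mm) converts to small
  pore blobs (radius 0.033 mm → thickness ≈ 0.07 mm, i.e. narrow pores) at
  rate `wall_effect_amplitude` (0.1) — the particle-rearrangement wall effect
  at the root surface.
* **Greyscale**: class means 30000 (solid), 5000 (pore), 12000 (root) on the
  16-bit scale, Gaussian noise sd 1500; unchanged voxels keep their
  before-image grey values, so density gradients are comparable across scans.
* **Rhizosheath table**: mass = 0.5 + 2.0 · (macropore share of the root
  environment) + ε, tracer activity = 5 + 40 · mass + ε′ — stated monotone
  maps recorded in the table metadata, emulating the direction of the
  adhering-soil and root-derived-carbon measurements.

Everything is deterministic under a fixed seed; the ledger
(`GroundTruth.per_voxel_changes`) equals the voxel-wise diff of the two label
volumes by construction and by test.

**What the generator does not emulate** — hence what passing tests do *not*
show about real data: mechanistic soil deformation (compaction here is random
voxel conversion, not displacement), root thinning/branching, shrink–swell and
mucilage effects, image artefacts (beam hardening, ring artefacts,
partial-volume greyscale mixing beyond the excluded border voxel),
registration error (the paired volumes are perfectly aligned; the 1-voxel
differencing tolerance is exercised only synthetically), and the absolute
porosity values of any particular field soil.

## Numerical choices and degenerate inputs

* Half-open bins `(lo, hi]` everywhere; strict `>` at the 0.04 mm macropore
  threshold; documented rather than discoverable, since the underlying
  quantities are continuous and ties are measure-zero on real data.
* Empty pore mask → all-zero thickness map (not an error); empty new-root
  mask, empty domain, all-tied rank inputs, < 3 regression pairs, < 3
  replicate cores → informative `ValueError`s.
* Anisotropic voxel spacing is rejected everywhere (single scalar `voxel_mm`).
* Requests the generator cannot honour (biopores that cannot fit or alone
  exceed the porosity target, a grid too small for the root plus the 1 mm
  band) raise `InfeasibleParamsError` instead of silently truncating.
* Per-bin mechanism comparisons are paired t tests on per-core
  `preference − induced` differences, one variance per distance bin (both the
  response and its spread shrink with distance, so pooling variances across
  bins would be wrong). No multiple-testing correction by default; a Holm
  option exists. The replicate-level mixed-effects machinery of a full field
  study (random pot/core effects, variance modelling, marginal-means slicing)
  is deliberately out of scope — those are routine statistical-package fits,
  not image-pipeline substance.

## Problem sizes used by the test suite and acceptance script

Oracle comparisons run on 32³ masks (20 for thickness, 10 for distance);
shell-conservation and rhizosheath checks on 24×150×150 cores; the
parameter-recovery and preference-recovery checks on 20 seeded full-default
cores (48×180×180) each. These sizes keep the exhaustive oracles exact and
the whole validation run at desk scale while every shell still spans its
nominal ~10 voxel layers.

## Known limitations

* Local thickness reads up to one voxel above the continuum width (digital
  maximal-ball bias); all thresholds are interpreted under that convention.
* The thickness propagation is exact but quadratic in pathological cases
  (one huge pore); fine at the porosities used here.
* Biopore shape criteria are heuristics; merged pore clusters inherit the
  label of the component they touch.
* The root walk guarantees a connected, z-monotone tube, which is tidier than
  real root systems (no branching, no thinning with depth).
* `preference` compares the before-profile to a scalar core mean; cores whose
  macroporosity trends systematically with depth would need a depth-resolved
  reference.
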