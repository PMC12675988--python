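"""I/O for 3D greyscale volumes, label maps, profile tables and run configuration.

Volumes are multi-page TIFF stacks in z-major order (axis 0 = z, then y, x) or raw
binaries with a JSON sidecar carrying ``shape`` and ``dtype``.  The physical voxel
edge length (mm, isotropic) is never read from TIFF tags — tag dialects vary across
scanners and writers — and must be supplied by the caller or a YAML config.
Grey values are passed through bit-exactly; no rescaling ever happens on read.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class SoilClass(enum.IntEnum):
    """Fixed label legend shared by the whole pipeline.

    BIOPORE is conceptually a subtype of the macropore phase (a macropore of
    biological origin, hence cylindrical); the pore phase is
    ``{MACROPORE, BIOPORE}``.
    """

    MATRIX = 0
    MACROPORE = 1
    BIOPORE = 2
    ROOT_OLD = 3
    ROOT_NEW = 4


DEFAULT_LEGEND: dict[int, str] = {int(c): c.name for c in SoilClass}

#: Fixed column order for profile tables written by :func:`write_profile_table`.
PROFILE_COLUMNS = [
    "core_id",
    "bin_lower_mm",
    "bin_upper_mm",
    "n_domain_voxels",
    "n_target_voxels",
    "fraction_or_mean",
]


def _check_voxel_mm(voxel_mm) -> float:
    if np.ndim(voxel_mm) != 0:
        raise ValueError(
            "voxel_mm must be a single scalar: only isotropic grids are supported"
        )
    voxel_mm = float(voxel_mm)
    if not np.isfinite(voxel_mm) or voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be positive, got {voxel_mm}")
    return voxel_mm


@dataclass
class Volume3D:
    """A greyscale 3D image on an isotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Grey values, arbitrary units (typically uint16 from a µCT reconstruction).
    voxel_mm : float
        Edge length of the cubic voxel in mm.
    origin_label : str
        Free-text provenance tag (core id, file name, ...).
    """

    data: np.ndarray
    voxel_mm: float
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.voxel_mm = _check_voxel_mm(self.voxel_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Per-voxel class map over :class:`SoilClass`, sharing a Volume3D grid."""

    labels: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or min(labels.shape) < 1:
            raise ValueError(f"expected a 3D label grid, got shape {labels.shape}")
        valid = np.isin(labels, list(DEFAULT_LEGEND))
        if not valid.all():
            bad = np.unique(labels[~valid])
            raise ValueError(f"unknown label codes present: {bad.tolist()}")
        self.labels = labels.astype(np.uint8, copy=False)
        self.voxel_mm = _check_voxel_mm(self.voxel_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, *classes: SoilClass) -> np.ndarray:
        """Binary mask of the union of the given classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in classes:
            out |= self.labels == int(c)
        return out

    def pore_mask(self) -> np.ndarray:
        """Resolvable pore phase: macropores plus biopores."""
        return self.mask(SoilClass.MACROPORE, SoilClass.BIOPORE)

    def soil_domain_mask(self) -> np.ndarray:
        """Soil voxels: everything except roots (old and new).

        Local porosity is expressed per local *soil* volume, and roots are not
        soil, so both root classes are excluded from every porosity denominator.
        """
        return ~self.mask(SoilClass.ROOT_OLD, SoilClass.ROOT_NEW)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.voxel_mm)


def _load_grid(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValueError(
                    f"inconsistent slice shapes in {path.name}: {sorted(shapes)}"
                )
            arr = tf.asarray()
        if arr.ndim == 2:  # single-page stack
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path.name} is not a 3D stack (ndim={arr.ndim})")
        return arr
    # raw binary with sidecar metadata
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"raw volume {path} has no sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(int(s) for s in meta["shape"])
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    if arr.size != int(np.prod(shape)):
        raise ValueError(
            f"raw volume {path.name}: file size does not match sidecar shape {shape}"
        )
    return arr.reshape(shape)


def read_volume(path, voxel_mm: float) -> Volume3D:
    """Read a greyscale stack bit-exactly (no rescaling, no tag parsing)."""
    path = Path(path)
    return Volume3D(_load_grid(path), voxel_mm, origin_label=path.name)


def write_volume(volume: Volume3D, path) -> Path:
    """Write a z-major multi-page TIFF (or raw+sidecar for non-TIFF suffixes)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.data, photometric="minisblack")
    else:
        volume.data.tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"shape": volume.data.shape, "dtype": volume.data.dtype.name})
        )
    return path


def read_labels(path, legend: dict[int, str] | None = None, voxel_mm: float = 1.0,
                paired: Volume3D | None = None) -> LabelVolume:
    """Read a label stack and map file codes onto the canonical legend.

    Parameters
    ----------
    legend : dict mapping integer file codes to class names
        Every code present in the file must appear here; unknown codes are an
        error (a silent remap would corrupt every downstream porosity).
    paired : optional greyscale volume that must share the grid.
    """
    legend = DEFAULT_LEGEND if legend is None else legend
    names = {c.name for c in SoilClass}
    bad_names = set(legend.values()) - names
    if bad_names:
        raise ValueError(f"legend maps to unknown classes: {sorted(bad_names)}")
    arr = _load_grid(Path(path))
    present = np.unique(arr)
    unknown = [int(c) for c in present if int(c) not in legend]
    if unknown:
        raise ValueError(f"label codes {unknown} in {path} are absent from the legend")
    out = np.empty(arr.shape, dtype=np.uint8)
    for code in present:
        out[arr == code] = SoilClass[legend[int(code)]]
    if paired is not None:
        if paired.shape != out.shape:
            raise ValueError(
                f"label grid {out.shape} does not match paired volume {paired.shape}"
            )
        voxel_mm = paired.voxel_mm
    return LabelVolume(out, voxel_mm)


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels, photometric="minisblack")
    return path


def write_profile_table(table: pd.DataFrame, path) -> Path:
    """Write a profile table as CSV with the fixed :data:`PROFILE_COLUMNS` order.

    Extra columns are kept after the fixed block; re-reading with
    :func:`read_profile_table` reproduces the table.
    """
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"profile table is missing columns {missing}")
    if len(table):
        if (table["bin_lower_mm"] >= table["bin_upper_mm"]).any():
            raise ValueError("bin_lower_mm must be < bin_upper_mm in every row")
        if (table["n_target_voxels"] > table["n_domain_voxels"]).any():
            raise ValueError("n_target_voxels may not exceed n_domain_voxels")
    extra = [c for c in table.columns if c not in PROFILE_COLUMNS]
    path = Path(path)
    table[PROFILE_COLUMNS + extra].to_csv(path, index=False)
    return path


def read_profile_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Run configuration, normally loaded from a YAML file."""

    voxel_mm: float = 0.0182
    bin_edges_mm: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 1.0])
    border_exclusion_mm: float | None = None  # None -> one voxel edge
    macropore_min_mm: float = 0.04
    narrow_max_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_mm = _check_voxel_mm(self.voxel_mm)
        edges = list(self.bin_edges_mm)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges_mm must be strictly increasing")
        self.bin_edges_mm = edges


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.__dict__, sort_keys=False))
    return path
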