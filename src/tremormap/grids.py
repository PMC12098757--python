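"""Volume grids, scalar maps, and seed masks.

All stages of the pipeline operate on a single shared voxel grid (a
``VolumeGrid``): a shape, a voxel-to-world affine, and a boolean analysis
mask selecting in-brain voxels.  There is deliberately no resampling
anywhere — volumes that do not match the grid are rejected loudly, because
silent resampling is the dominant source of bugs in voxel-wise pipelines.

Scalar maps store one value per in-mask voxel plus a coverage mask, so a
map defined only on part of the brain (e.g. a cerebellum-only atrophy
network map) is distinct from a map that is zero there.  NaN on disk means
"not covered", never "value zero".
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarMap",
    "SeedMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_seed_mask",
    "flip_to_left",
]


class GridMismatchError(ValueError):
    """A volume's shape or affine does not match the analysis grid."""


def _as_affine(affine) -> np.ndarray:
    a = np.asarray(affine, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {a.shape}")
    if abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return a


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """A fixed 3D voxel grid with an in-brain analysis mask.

    Parameters
    ----------
    shape:
        Voxels per axis, strictly positive.
    affine:
        4x4 voxel-index-to-world (mm) transform; must be invertible.
    analysis_mask:
        Boolean array over the grid marking in-brain voxels.  At least one
        voxel must be inside.  ``None`` means the whole grid.
    midsagittal_symmetric:
        Declares that the grid (mask included) is mirror-symmetric about
        its mid-x plane, which makes the pure mirror hemisphere flip exact.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    analysis_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    midsagittal_symmetric: bool = True

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        affine = _as_affine(self.affine if self.affine is not None else np.eye(4))
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)
        mask = self.analysis_mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("analysis_mask shape does not match grid shape")
        if not mask.any():
            raise ValueError("analysis_mask selects no voxels")
        mask = mask.copy()
        mask.setflags(write=False)
        object.__setattr__(self, "analysis_mask", mask)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (the length of every ScalarMap on this grid)."""
        return int(self.analysis_mask.sum())

    @property
    def mask_ijk(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel indices of in-mask voxels, C order."""
        return np.argwhere(self.analysis_mask)

    def flat_positions(self, ijk: np.ndarray) -> np.ndarray:
        """Map (k, 3) voxel indices to positions in the in-mask vector.

        Indices outside the analysis mask map to -1.
        """
        ijk = np.atleast_2d(np.asarray(ijk, dtype=int))
        lut = np.full(self.shape, -1, dtype=np.int64)
        lut[self.analysis_mask] = np.arange(self.n_voxels)
        if (ijk < 0).any() or (ijk >= np.array(self.shape)).any():
            raise IndexError("voxel index outside grid bounds")
        return lut[ijk[:, 0], ijk[:, 1], ijk[:, 2]]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def __eq__(self, other):
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (self.matches(other)
                and np.array_equal(self.analysis_mask, other.analysis_mask)
                and self.midsagittal_symmetric == other.midsagittal_symmetric)

    def __hash__(self):
        return hash((self.shape, self.affine.tobytes()))


@dataclass(frozen=True, eq=False)
class ScalarMap:
    """One real value per in-mask voxel, with a coverage mask.

    ``values`` and ``coverage`` are 1-D arrays of length ``grid.n_voxels``.
    Values must be finite wherever covered; uncovered entries are ignored
    (stored as 0 internally, written as NaN by default).  ``provenance``
    carries short content hashes of the clinical data that informed the map,
    used to enforce hold-out firewalls downstream.
    """

    grid: VolumeGrid
    values: np.ndarray
    coverage: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = self.grid.n_voxels
        if values.shape != (n,):
            raise ValueError(f"values must have shape ({n},), got {values.shape}")
        cov = self.coverage
        if cov is None:
            cov = np.isfinite(values)
        cov = np.asarray(cov, dtype=bool)
        if cov.shape != (n,):
            raise ValueError("coverage must match the in-mask voxel count")
        if not np.isfinite(values[cov]).all():
            raise ValueError("non-finite value inside coverage")
        values = np.where(cov, values, 0.0)
        values.setflags(write=False)
        cov = cov.copy()
        cov.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "coverage", cov)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        """Render as a full 3D array; uncovered / out-of-mask voxels get ``fill``."""
        out = np.full(self.grid.shape, fill, dtype=float)
        vals = np.where(self.coverage, self.values, fill)
        out[self.grid.analysis_mask] = vals
        return out

    def with_provenance(self, *hashes: str) -> "ScalarMap":
        merged = tuple(dict.fromkeys(self.provenance + hashes))
        return replace(self, provenance=merged)

    def __eq__(self, other):
        if not isinstance(other, ScalarMap):
            return NotImplemented
        return (self.grid == other.grid
                and np.array_equal(self.values, other.values)
                and np.array_equal(self.coverage, other.coverage))

    def __hash__(self):
        return hash((self.grid, self.values.tobytes()))


@dataclass(frozen=True, eq=False)
class SeedMask:
    """A binary seed region (VTA or lesion) on the shared grid.

    ``voxels`` is a (k, 3) array of 0-based voxel indices; ``side`` tags the
    hemisphere so right-sided seeds can be mirrored onto the left before
    seeding the connectome.
    """

    grid: VolumeGrid
    voxels: np.ndarray
    side: str = "bilateral"
    name: str = ""

    def __post_init__(self):
        vox = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if vox.size == 0:
            raise ValueError(f"seed mask {self.name!r} is empty")
        if vox.shape[1] != 3:
            raise ValueError("voxels must be (k, 3) indices")
        if (vox < 0).any() or (vox >= np.array(self.grid.shape)).any():
            raise ValueError(f"seed mask {self.name!r} has voxels outside the grid")
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"side must be left/right/bilateral, got {self.side!r}")
        # canonical ordering -> deterministic hashing and row reads
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        vox = np.unique(vox[order], axis=0)
        vox.setflags(write=False)
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.voxels.tobytes())
        h.update(self.side.encode())
        return h.hexdigest()[:8]

    def __eq__(self, other):
        if not isinstance(other, SeedMask):
            return NotImplemented
        return (self.grid == other.grid and self.side == other.side
                and np.array_equal(self.voxels, other.voxels))

    def __hash__(self):
        return hash((self.grid, self.voxels.tobytes(), self.side))


def flip_to_left(seed: SeedMask) -> SeedMask:
    """Mirror a right-sided seed across the midsagittal plane.

    Left or bilateral seeds are returned unchanged.  The flip is a pure
    mirror (x index ``i -> nx - 1 - i``); the grid must declare midsagittal
    symmetry for this to be exact.  Voxel count is preserved.
    """
    if seed.side != "right":
        return seed
    if not seed.grid.midsagittal_symmetric:
        raise ValueError("grid is not declared midsagittal-symmetric; mirror flip would be biased")
    nx = seed.grid.shape[0]
    vox = seed.voxels.copy()
    vox[:, 0] = nx - 1 - vox[:, 0]
    assert (vox[:, 0] >= 0).all() and (vox[:, 0] < nx).all()
    return SeedMask(seed.grid, vox, side="left", name=seed.name)


# -- NIfTI I/O ---------------------------------------------------------------

def _provenance_from_header(hdr) -> tuple[str, ...]:
    try:
        desc = hdr["descrip"].tobytes().split(b"\x00", 1)[0].decode("ascii", "ignore")
    except Exception:
        return ()
    if desc.startswith("prov:"):
        return tuple(h for h in desc[5:].split(",") if h)
    return ()


def read_volume(path, grid: VolumeGrid | None = None, treat_nan: str = "missing") -> ScalarMap:
    """Read a NIfTI volume as a ScalarMap on ``grid``.

    If ``grid`` is given, the file's shape and affine must match it exactly
    (no resampling).  Otherwise a whole-volume grid is constructed from the
    header.  ``treat_nan`` controls NaN voxels: "missing" marks them
    uncovered, "zero" sets them to 0, "error" rejects them.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if grid is not None:
        if tuple(data.shape) != grid.shape:
            raise GridMismatchError(
                f"{path}: shape {tuple(data.shape)} does not match grid {grid.shape}"
            )
        if not np.allclose(img.affine, grid.affine, atol=1e-4):
            raise GridMismatchError(f"{path}: affine does not match the analysis grid")
    else:
        grid = VolumeGrid(data.shape, affine=img.affine)
    vals = data[grid.analysis_mask]
    nan = ~np.isfinite(vals)
    if nan.all():
        raise ValueError(f"{path}: volume is all-NaN within the analysis mask")
    if treat_nan == "missing":
        coverage = ~nan
    elif treat_nan == "zero":
        vals = np.where(nan, 0.0, vals)
        coverage = np.ones_like(nan, dtype=bool)
    elif treat_nan == "error":
        if nan.any():
            raise ValueError(f"{path}: NaN voxels present (treat_nan='error')")
        coverage = np.ones_like(nan, dtype=bool)
    else:
        raise ValueError(f"unknown treat_nan mode {treat_nan!r}")
    return ScalarMap(grid, np.where(coverage, vals, 0.0), coverage,
                     provenance=_provenance_from_header(img.header))


def write_volume(smap: ScalarMap, path, fill: str = "nan") -> None:
    """Write a ScalarMap as NIfTI-1; uncovered voxels become NaN (or 0).

    Provenance hashes, if any, are recorded in the header description field.
    """
    if not smap.coverage.any():
        raise ValueError("refusing to write a map with empty coverage")
    fill_value = np.nan if fill == "nan" else 0.0
    vol = smap.to_volume(fill=fill_value)
    img = nib.Nifti1Image(vol.astype(np.float32), smap.grid.affine)
    if smap.provenance:
        img.header["descrip"] = ("prov:" + ",".join(smap.provenance))[:79].encode("ascii")
    nib.save(img, str(path))


def read_seed_mask(path, grid: VolumeGrid, side: str = "bilateral", name: str = "") -> SeedMask:
    """Read a binary seed (VTA/lesion) NIfTI; voxels with value > 0.5 are in."""
    smap = read_volume(path, grid=grid, treat_nan="zero")
    binary = (smap.values > 0.5) & smap.coverage
    if not binary.any():
        raise ValueError(f"seed mask {path} is empty after binarization at 0.5")
    ijk = grid.mask_ijk[binary]
    return SeedMask(grid, ijk, side=side, name=name or str(path))


def write_seed_mask(seed: SeedMask, path) -> None:
    vol = np.zeros(seed.grid.shape, dtype=np.float32)
    vol[seed.voxels[:, 0], seed.voxels[:, 1], seed.voxels[:, 2]] = 1.0
    nib.save(nib.Nifti1Image(vol, seed.grid.affine), str(path))
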