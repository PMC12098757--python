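"""Group voxel-wise functional connectome construction, storage, and seeding.

The group connectome is the element-wise mean over subjects of per-subject
voxel-by-voxel Pearson correlation matrices.  Each subject contributes
several resting-state runs; every run is demeaned per voxel before the runs
are concatenated, so between-run offset differences do not masquerade as
correlation.  Correlations are averaged raw across subjects (no Fisher-z
transform) to match the normative-connectome convention; a ``fisher_z``
option is available.

Seeding a mask averages the matrix rows belonging to the seed voxels,
yielding one mean-connectivity value per in-mask voxel (the "seedmap" of a
stimulation volume or lesion).  When the matrix lives in an HDF5 store the
rows are read directly from disk, so seeding never loads the full matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .grids import ScalarMap, SeedMask, VolumeGrid

__all__ = [
    "Connectome",
    "Seedmap",
    "subject_connectome",
    "build_group_connectome",
    "seed_connectivity",
    "save_connectome",
    "load_connectome",
]


@dataclass(frozen=True)
class Seedmap:
    """Whole-brain average-connectivity profile of one seed mask."""

    seed: SeedMask
    values: ScalarMap

    def __post_init__(self):
        v = self.values.values[self.values.coverage]
        if v.size and (np.abs(v) > 1 + 1e-6).any():
            raise ValueError("seedmap values outside [-1, 1]")


@dataclass
class Connectome:
    """Group-averaged voxel x voxel correlation matrix on a VolumeGrid.

    ``matrix`` may be an in-memory ndarray or an h5py dataset; row access
    works identically for both.
    """

    grid: VolumeGrid
    matrix: "np.ndarray | h5py.Dataset"
    n_subjects: int = 1
    provenance: str = ""
    zero_variance_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self):
        n = self.grid.n_voxels
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grid voxel count {n}"
            )

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    def rows(self, positions: np.ndarray) -> np.ndarray:
        """Read matrix rows at in-mask positions (sorted access for HDF5)."""
        positions = np.asarray(positions, dtype=int)
        order = np.argsort(positions)
        rows = self.matrix[positions[order]]
        out = np.empty_like(rows)
        out[order] = rows
        return np.asarray(out, dtype=float)

    def validate(self, atol: float = 1e-6) -> None:
        """Check symmetry, unit diagonal, and correlation bounds (in-memory only)."""
        m = np.asarray(self.matrix)
        if not np.allclose(m, m.T, atol=atol):
            raise ValueError("connectome matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=atol):
            raise ValueError("connectome diagonal deviates from 1")
        if (np.abs(m) > 1 + atol).any():
            raise ValueError("correlation outside [-1, 1]")


def subject_connectome(runs: list[np.ndarray]) -> np.ndarray:
    """Pearson correlation matrix from one subject's multi-run time series.

    Each run is (samples, n_voxels).  Runs are demeaned per voxel, then
    concatenated, then all pairwise correlations are computed on the
    concatenation.  Voxels whose concatenated series has zero variance get
    correlation 0 to every other voxel (diagonal stays 1) and are reported
    via a warning — 0 rather than NaN keeps downstream averages stable.
    """
    if len(runs) == 0:
        raise ValueError("at least one run is required")
    arrs = []
    n_vox = None
    for i, run in enumerate(runs):
        a = np.asarray(run, dtype=float)
        if a.ndim != 2 or a.shape[0] < 3:
            raise ValueError(f"run {i}: need a (samples >= 3, voxels) array, got {a.shape}")
        if n_vox is None:
            n_vox = a.shape[1]
        elif a.shape[1] != n_vox:
            raise ValueError("runs disagree on voxel count")
        arrs.append(a - a.mean(axis=0, keepdims=True))
    ts = np.concatenate(arrs, axis=0)
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(f"{dead.size} voxel(s) with zero variance; correlations set to 0")
        sd = sd.copy()
        sd[dead] = 1.0
    z = ts / sd
    corr = (z.T @ z) / ts.shape[0]
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def build_group_connectome(
    subjects: list[list[np.ndarray]],
    grid: VolumeGrid,
    fisher_z: bool = False,
    provenance: str = "",
) -> Connectome:
    """Average per-subject correlation matrices into a group connectome.

    ``subjects`` is a list of run-lists.  The default is the plain mean of
    raw correlations; ``fisher_z=True`` averages arctanh-transformed values
    and transforms back (diagonal handled separately).
    """
    if len(subjects) == 0:
        raise ValueError("at least one subject is required")
    n = grid.n_voxels
    acc = np.zeros((n, n))
    dead_any = np.zeros(n, dtype=bool)
    for i, runs in enumerate(subjects):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = subject_connectome(runs)
        if m.shape != (n, n):
            raise ValueError(f"subject {i}: voxel count {m.shape[0]} does not match grid {n}")
        dead_any |= (np.abs(m).sum(axis=0) == 1.0)  # only the diagonal survives
        if fisher_z:
            mz = np.arctanh(np.clip(m, -1 + 1e-12, 1 - 1e-12))
            np.fill_diagonal(mz, 0.0)
            acc += mz
        else:
            acc += m
    mean = acc / len(subjects)
    if fisher_z:
        mean = np.tanh(mean)
        np.fill_diagonal(mean, 1.0)
    mean = (mean + mean.T) / 2.0
    return Connectome(
        grid=grid,
        matrix=mean,
        n_subjects=len(subjects),
        provenance=provenance,
        zero_variance_voxels=np.flatnonzero(dead_any),
    )


def seed_connectivity(conn: Connectome, seed: SeedMask, flip: bool = True) -> Seedmap:
    """Average connectome rows over a seed mask -> one value per in-mask voxel.

    Right-sided seeds are mirrored to the left first (``flip=True``), so all
    hemispheres are analyzed in one hemisphere's frame.  Seed voxels that
    fall outside the analysis mask are ignored; an entirely out-of-mask seed
    is an error that names the seed.
    """
    from .grids import flip_to_left

    if flip:
        seed_used = flip_to_left(seed)
    else:
        seed_used = seed
    pos = conn.grid.flat_positions(seed_used.voxels)
    pos = pos[pos >= 0]
    if pos.size == 0:
        raise ValueError(
            f"seed {seed.name or seed.content_hash()!r} has no voxels inside the analysis mask"
        )
    values = conn.rows(pos).mean(axis=0)
    smap = ScalarMap(conn.grid, np.clip(values, -1.0, 1.0))
    return Seedmap(seed=seed_used, values=smap)


# -- HDF5 store --------------------------------------------------------------

def save_connectome(conn: Connectome, path) -> None:
    """Persist to HDF5: /matrix (float32), /voxel_index, /grid metadata."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("matrix", data=np.asarray(conn.matrix, dtype=np.float32))
        f.create_dataset("voxel_index", data=conn.grid.mask_ijk.astype(np.int32))
        g = f.create_group("grid")
        g.create_dataset("affine", data=conn.grid.affine)
        g.create_dataset("shape", data=np.array(conn.grid.shape, dtype=np.int32))
        g.create_dataset("mask", data=conn.grid.analysis_mask.astype(np.uint8))
        f.attrs["n_subjects"] = conn.n_subjects
        f.attrs["provenance"] = conn.provenance
        f.attrs["midsagittal_symmetric"] = conn.grid.midsagittal_symmetric
        f.create_dataset("zero_variance_voxels", data=conn.zero_variance_voxels.astype(np.int64))


def load_connectome(path, memory_map: bool = True) -> Connectome:
    """Load a stored connectome.

    With ``memory_map=True`` the matrix stays an on-disk HDF5 dataset and
    the open file handle is kept alive by the returned object; seeding then
    reads only the rows it needs.
    """
    f = h5py.File(str(path), "r")
    shape = tuple(int(s) for s in f["grid/shape"][()])
    grid = VolumeGrid(
        shape,
        affine=f["grid/affine"][()],
        analysis_mask=f["grid/mask"][()].astype(bool),
        midsagittal_symmetric=bool(f.attrs.get("midsagittal_symmetric", True)),
    )
    if memory_map:
        matrix = f["matrix"]
    else:
        matrix = f["matrix"][()].astype(float)
    conn = Connectome(
        grid=grid,
        matrix=matrix,
        n_subjects=int(f.attrs.get("n_subjects", 1)),
        provenance=str(f.attrs.get("provenance", "")),
        zero_variance_voxels=f["zero_variance_voxels"][()],
    )
    if memory_map:
        conn._h5file = f  # keep the handle alive with the object
    else:
        f.close()
    return conn
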