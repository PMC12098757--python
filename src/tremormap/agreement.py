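"""Sign-consistent agreement maps and lesion-network overlap maps.

An agreement map condenses several tremor-network maps into the voxels on
which they all agree: a voxel is retained only if every map covering it is
strictly positive or every one strictly negative there (zero counts as "no
sign" and discards the voxel).  To preserve weighting, the absolute values
of the covering maps are multiplied and the common sign restored; maps are
first rescaled by their maximum absolute value so that inputs on wildly
different scales (overlap counts, z-scores, correlation coefficients)
contribute comparably.  A map with partial coverage only informs the voxels
it defines — e.g. a cerebellum-only atrophy network map constrains
cerebellar voxels without vetoing cerebral ones.

The lesion-network overlap map counts, per voxel, how many lesion seedmaps
are (supra-threshold) functionally connected to it; a higher count means a
higher probability that the voxel belongs to the symptom network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import Seedmap
from .grids import ScalarMap

__all__ = ["AgreementMap", "OverlapMap", "agreement_map", "zscore_map", "lesion_overlap_map"]


@dataclass(frozen=True)
class AgreementMap:
    """Signed multiplicative combination of N maps on their sign-consistent voxels."""

    raw: ScalarMap       # signed product on retained voxels, 0 elsewhere
    z: ScalarMap         # z-scored raw over retained voxels; coverage = retention
    retained_mask: np.ndarray
    n_inputs: int

    def __post_init__(self):
        z = self.z.values[self.retained_mask]
        if z.size >= 2 and z.std() > 0:
            assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6


@dataclass(frozen=True)
class OverlapMap:
    """Per-voxel count of lesions whose connectivity reaches the voxel."""

    values: ScalarMap
    n_lesions: int

    def __post_init__(self):
        v = self.values.values[self.values.coverage]
        if (v < 0).any() or (v > self.n_lesions).any():
            raise ValueError("overlap counts outside [0, n_lesions]")


def _as_scalarmap(m) -> ScalarMap:
    if isinstance(m, Seedmap):
        return m.values
    if isinstance(m, ScalarMap):
        return m
    raise TypeError(f"expected ScalarMap or Seedmap, got {type(m)}")


def agreement_map(maps, rescale: str = "maxabs", min_coverage: int = 2) -> AgreementMap:
    """Combine N maps into a sign-consistent agreement map.

    Per voxel, the set C of maps covering it is examined: the voxel is
    retained iff all values in C share a strict sign.  The raw value is
    ``common_sign * prod_{m in C} |m_v|`` after per-map rescaling
    (``'maxabs'`` divides each map by its maximum absolute covered value;
    ``'none'`` multiplies raw values).  Voxels covered by fewer than
    ``min_coverage`` maps are excluded with a warning.  The result is
    permutation-invariant in its inputs.
    """
    maps = [_as_scalarmap(m) for m in maps]
    if len(maps) < 2:
        raise ValueError("agreement requires at least 2 maps")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(grid):
            raise ValueError("agreement maps must share one grid")
    if rescale not in ("maxabs", "none"):
        raise ValueError(f"unknown rescale mode {rescale!r}")

    V = np.stack([m.values for m in maps])          # (n_maps, n_vox)
    C = np.stack([m.coverage for m in maps])
    if rescale == "maxabs":
        scaled = np.empty_like(V)
        for i in range(V.shape[0]):
            peak = np.abs(V[i][C[i]]).max() if C[i].any() else 0.0
            if peak == 0:
                raise ValueError(f"input map {i} is identically zero; no sign to agree on")
            scaled[i] = V[i] / peak
        V = scaled

    n_cover = C.sum(axis=0)
    undercovered = n_cover < min_coverage
    if undercovered.any():
        warnings.warn(
            f"{int(undercovered.sum())} voxel(s) covered by fewer than "
            f"{min_coverage} maps; excluded from agreement"
        )
    pos = ((V > 0) | ~C).all(axis=0)
    neg = ((V < 0) | ~C).all(axis=0)
    retained = (pos | neg) & ~undercovered
    if not retained.any():
        raise ValueError("no voxel is sign-consistent across all maps")

    absV = np.where(C, np.abs(V), 1.0)  # uncovered maps do not weigh in
    magnitude = absV.prod(axis=0)
    sign = np.where(pos, 1.0, -1.0)
    raw_vals = np.where(retained, sign * magnitude, 0.0)
    raw = ScalarMap(grid, raw_vals, coverage=np.ones_like(retained))

    r = raw_vals[retained]
    if r.size >= 2 and r.std() > 0:
        z_vals = np.where(retained, (raw_vals - r.mean()) / r.std(), 0.0)
    else:
        # degenerate retention (a single voxel, or all-equal products): the
        # z-map is defined but carries no contrast
        z_vals = np.zeros_like(raw_vals)
    z = ScalarMap(grid, z_vals, coverage=retained,
                  provenance=tuple(dict.fromkeys(h for m in maps for h in m.provenance)))
    return AgreementMap(raw=raw, z=z, retained_mask=retained, n_inputs=len(maps))


def zscore_map(smap: ScalarMap, over: str = "coverage") -> ScalarMap:
    """Standardize a map to mean 0, SD 1 over its covered voxels."""
    if over != "coverage":
        raise ValueError("only over='coverage' is supported")
    v = smap.values[smap.coverage]
    if v.size < 2:
        raise ValueError("need at least 2 covered voxels to z-score")
    sd = v.std()
    if sd == 0:
        raise ValueError("zero variance; z-score undefined")
    z = np.where(smap.coverage, (smap.values - v.mean()) / sd, 0.0)
    return ScalarMap(smap.grid, z, coverage=smap.coverage, provenance=smap.provenance)


def lesion_overlap_map(lesion_seedmaps, threshold: float, two_sided: bool = False) -> OverlapMap:
    """Count per voxel how many lesion seedmaps exceed a connectivity threshold.

    Each seedmap is binarized at ``value >= threshold`` (``|value| >=
    threshold`` when ``two_sided``); the overlap map is the voxel-wise sum
    of the binarized maps.
    """
    maps = [_as_scalarmap(m) for m in lesion_seedmaps]
    if not maps:
        raise ValueError("at least one lesion seedmap is required")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    grid = maps[0].grid
    counts = np.zeros(grid.n_voxels)
    for m in maps:
        if not m.grid.matches(grid):
            raise ValueError("lesion seedmaps must share one grid")
        v = np.abs(m.values) if two_sided else m.values
        counts += ((v >= threshold) & m.coverage).astype(float)
    return OverlapMap(values=ScalarMap(grid, counts), n_lesions=len(maps))
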