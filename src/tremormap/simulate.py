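"""Synthetic connectomes, planted tremor networks, and DBS cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes, with a known ground truth so every stage can be validated:

* A group connectome built from per-subject multi-run time series.  Voxel
  series are mixtures of smooth latent spatial networks driven by
  independent temporal signals, plus white noise — yielding a smooth
  symmetric correlation matrix with both positively and negatively coupled
  regions.  The first latent network is a deliberately planted "tremor
  circuit": a subcortical node sitting between the cohorts' stimulation
  target boxes plus remote positive nodes and one negative node, so that a
  hub seeded near the targets has a known, recoverable whole-brain
  profile.  The remaining networks are smooth Gaussian random fields that
  act as structured background.
* A planted ground-truth network: the connectivity profile of a small hub
  region inside the circuit's subcortical node, standing in for the
  unknown "optimal connectivity" pattern a cohort R-map estimates.
* Patient cohorts: spherical stimulation volumes scattered in a target box
  (mirrored to the right hemisphere for right-sided electrodes), an
  outcome driven monotonically by each volume's connectivity similarity to
  the truth plus Gaussian noise, and bounded integer clinical scores on a
  cohort-specific scale (UPDRS-like vs FTM-like).

Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .cohorts import HemisphereRecord
from .connectome import Connectome, Seedmap, build_group_connectome, seed_connectivity
from .grids import ScalarMap, SeedMask, VolumeGrid
from .stats import similarity_corr

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_grid",
    "simulate_connectome",
    "plant_truth",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic end-to-end experiment.

    The desk-scale defaults — a 16 x 16 x 8 grid (2048 voxels), 20 subjects
    with 4 runs of 60 samples, 30 patients per cohort with electrodes in
    both hemispheres — keep a full simulated study in the range of seconds
    while preserving every code path of the real analysis.  ``slope`` is
    the outcome gain per unit connectivity similarity; when ``noise_sd`` is
    left unset it is calibrated so that similarity explains ``target_r2``
    (default 50%) of the outcome variance.
    """

    shape: tuple[int, int, int] = (16, 16, 8)
    n_latent: int = 16
    pattern_sigma: float = 2.0      # voxels; size scale of the circuit's nodes
    background_sigma: float = 4.5   # voxels; smoothness of background networks
    circuit_strength: float = 1.3   # amplitude of the planted tremor circuit
    background_strength: float = 0.55  # amplitude of each background network
    ts_noise_sd: float = 0.5        # white noise added to voxel time series
    n_subjects: int = 20
    n_runs: int = 4
    n_samples: int = 60             # per run
    target_box: tuple[tuple[int, int, int], tuple[int, int, int]] = ((1, 2, 1), (6, 7, 6))
    seed_radius_range: tuple[float, float] = (1.2, 2.6)  # voxels
    n_patients: int = 30
    bilateral: bool = True          # electrodes in both hemispheres per patient
    slope: float = 0.5              # normalized outcome per unit similarity
    noise_sd: float | None = None   # normalized outcome units; None -> calibrate
    target_r2: float = 0.5
    mean_improvement: float = 0.45  # cohort mean of the normalized improvement
    scale_max: float = 20.0         # maximum reachable tremor score (points)
    baseline_frac_range: tuple[float, float] = (0.7, 1.0)
    score_resolution: float = 1.0   # clinical scores round to whole points
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.shape) <= 0 or self.n_latent <= 0 or self.n_patients <= 0:
            raise ValueError("counts must be positive")
        if self.n_subjects <= 0 or self.n_runs <= 0 or self.n_samples < 3:
            raise ValueError("need >= 1 subject/run and >= 3 samples per run")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed_radius_range[0] < 1:
            raise ValueError("seed radius must be >= 1 voxel")
        lo, hi = np.array(self.target_box[0]), np.array(self.target_box[1])
        if (lo > hi).any() or (lo < 0).any() or (hi >= np.array(self.shape)).any():
            raise ValueError("target_box outside the grid")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key in ("shape", "seed_radius_range", "baseline_frac_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "target_box" in raw:
            raw["target_box"] = (tuple(raw["target_box"][0]), tuple(raw["target_box"][1]))
        return cls(**raw)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """The planted optimal-connectivity pattern and how it was generated.

    ``hub`` is the seeded region when the truth is a connectivity profile;
    ``None`` for externally supplied patterns (e.g. negative controls).
    """

    truth_map: ScalarMap
    hub: SeedMask | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = self.truth_map.values[self.truth_map.coverage]
        if v.std() == 0:
            raise ValueError("planted truth has zero variance")


def make_grid(config: SimulationConfig) -> VolumeGrid:
    """2 mm isotropic grid, whole box in-mask, symmetric about mid-x."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return VolumeGrid(config.shape, affine=affine, midsagittal_symmetric=True)


def default_hub(grid: VolumeGrid) -> SeedMask:
    """Two-voxel hub at the planted circuit's subcortical node."""
    shape = np.array(grid.shape)
    c = np.round(np.array(_CIRCUIT_NODES[0][0]) * (shape - 1)).astype(int)
    second = np.minimum(c + np.array([1, 1, 0]), shape - 1)
    return SeedMask(grid, np.vstack([c, second]), side="bilateral", name="hub")


def second_target_box(config: SimulationConfig) -> tuple:
    """Target box for the second cohort: the first box mirrored in y across
    the circuit's subcortical node (a second stimulation target on the far
    side of the planted hub)."""
    ny = config.shape[1]
    yc = _CIRCUIT_NODES[0][0][1] * (ny - 1)
    (x0, y0, z0), (x1, y1, z1) = config.target_box
    my0 = int(np.clip(round(2 * yc - y1), 0, ny - 1))
    my1 = int(np.clip(round(2 * yc - y0), 0, ny - 1))
    return ((x0, min(my0, my1), z0), (x1, max(my0, my1), z1))


# circuit node centers as fractions of the grid shape: a subcortical node
# between the two stimulation target boxes, plus remote positive and
# negative nodes arranged symmetrically about the subcortical node's
# y-plane so both cohorts' targets sample comparable circuit gradients
_CIRCUIT_NODES = (
    ((0.22, 0.53, 0.44), 1.5, +1.0),
    ((0.75, 0.20, 0.75), 1.25, +1.0),
    ((0.75, 0.86, 0.75), 1.25, +1.0),
    ((0.50, 0.12, 0.80), 1.25, -1.0),
    ((0.50, 0.94, 0.80), 1.25, -1.0),
)


def _latent_patterns(grid: VolumeGrid, config: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_latent, n_voxels) latent networks: planted circuit + smooth background.

    The first pattern is the fixed tremor circuit (Gaussian nodes at
    shape-relative positions, signed); the rest are Gaussian random fields
    smoothed to ``background_sigma`` voxels, giving every voxel structured
    signal of both signs.  Background fields are smoother than the circuit
    nodes, so near the stimulation targets the dominant connectivity
    gradient is coupling to the planted circuit.
    """
    from scipy.ndimage import gaussian_filter

    ijk = grid.mask_ijk.astype(float)
    shape = np.array(grid.shape, dtype=float)
    pats = np.empty((config.n_latent, grid.n_voxels))
    circuit = np.zeros(grid.n_voxels)
    for rel_center, sigma_scale, sign in _CIRCUIT_NODES:
        center = np.array(rel_center) * (shape - 1)
        s2 = 2.0 * (sigma_scale * config.pattern_sigma) ** 2
        circuit += sign * np.exp(-((ijk - center) ** 2).sum(axis=1) / s2)
    circuit -= circuit.mean()  # no global-signal offset
    pats[0] = config.circuit_strength * circuit / circuit.std()
    for k in range(1, config.n_latent):
        vol = gaussian_filter(rng.standard_normal(grid.shape),
                              sigma=config.background_sigma, mode="wrap")
        v = vol[grid.analysis_mask]
        v = v - v.mean()
        pats[k] = config.background_strength * v / v.std()
    return pats


def simulate_connectome(config: SimulationConfig, seed: int | None = None,
                        grid: VolumeGrid | None = None) -> Connectome:
    """Simulate subjects' run time series and build the group connectome.

    Each voxel's series is the latent-pattern mixture plus iid Gaussian
    noise; latent temporal signals are drawn fresh per subject and run,
    the spatial patterns are shared across subjects (they are the
    population's networks).
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = make_grid(config)
    patterns = _latent_patterns(grid, config, rng)
    subjects = []
    for _ in range(config.n_subjects):
        runs = []
        for _ in range(config.n_runs):
            signals = rng.standard_normal((config.n_samples, config.n_latent))
            ts = signals @ patterns
            if config.ts_noise_sd > 0:
                ts = ts + config.ts_noise_sd * rng.standard_normal(ts.shape)
            runs.append(ts)
        subjects.append(runs)
    provenance = (
        f"synthetic: {config.n_subjects} subjects x {config.n_runs} runs "
        f"x {config.n_samples} samples, {config.n_latent} latent networks, seed={seed}"
    )
    return build_group_connectome(subjects, grid, provenance=provenance)


def plant_truth(conn: Connectome, hub: SeedMask) -> GroundTruth:
    """Declare a hub region's connectivity profile the ground-truth network."""
    seedmap = seed_connectivity(conn, hub, flip=False)
    return GroundTruth(truth_map=seedmap.values, hub=hub,
                       params={"hub_voxels": int(hub.n_voxels)})


def _sphere_seed(grid: VolumeGrid, center: np.ndarray, radius: float,
                 side: str, name: str) -> SeedMask:
    ijk = grid.mask_ijk.astype(float)
    inside = ((ijk - center) ** 2).sum(axis=1) <= radius**2
    vox = grid.mask_ijk[inside]
    if vox.shape[0] == 0:  # radius >= 1 guarantees at least the center voxel
        vox = np.round(center[None, :]).astype(int)
    return SeedMask(grid, vox, side=side, name=name)


def simulate_cohort(conn: Connectome, truth: GroundTruth, config: SimulationConfig,
                    cohort_label: str, seed: int | None = None,
                    ) -> tuple[list[HemisphereRecord], list[Seedmap]]:
    """Simulate one DBS cohort: seeds, seedmaps, and bounded clinical scores.

    Per hemisphere a spherical stimulation volume is placed uniformly in
    the cohort's target box (mirrored across the midline for right-sided
    electrodes), its seedmap computed, and the latent response taken as
    the seedmap's rank correlation with the planted truth.  The normalized
    improvement is linear in that similarity plus Gaussian noise, clipped
    to [0, 1]; scores are rounded to the scale resolution and kept inside
    [0, baseline], and baselines always satisfy the >= 3-point inclusion
    rule by construction.

    Returns the records together with the (left-mirrored) seedmaps, in
    matching order.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    grid = conn.grid
    lo = np.array(config.target_box[0], dtype=float)
    hi = np.array(config.target_box[1], dtype=float)
    nx = grid.shape[0]

    records_meta = []
    seedmaps: list[Seedmap] = []
    sims = []
    for p in range(config.n_patients):
        pid = f"{cohort_label}-{p:03d}"
        sides = ("left", "right") if config.bilateral else ("left",)
        for side in sides:
            center = rng.uniform(lo, hi)
            if side == "right":
                center = center.copy()
                center[0] = (nx - 1) - center[0]
            radius = rng.uniform(*config.seed_radius_range)
            vta = _sphere_seed(grid, center, radius, side, name=f"{pid}-{side}")
            sm = seed_connectivity(conn, vta)  # flips right-sided seeds
            s = similarity_corr(sm, truth.truth_map, method="spearman")
            records_meta.append((pid, side))
            seedmaps.append(sm)
            sims.append(s)

    sims = np.array(sims)
    signal = config.slope * (sims - sims.mean())
    if config.noise_sd is None:
        # calibrate noise so similarity explains target_r2 of outcome variance
        sd_sig = signal.std()
        r2 = config.target_r2
        if sd_sig == 0 or r2 <= 0:
            noise_sd = 0.05  # pure-noise outcomes; keeps scores non-constant
        else:
            noise_sd = sd_sig * np.sqrt((1 - r2) / r2)
    else:
        noise_sd = config.noise_sd
    y = config.mean_improvement + signal + noise_sd * rng.standard_normal(len(sims))
    y = np.clip(y, 0.0, 1.0)

    res = config.score_resolution
    f_lo, f_hi = config.baseline_frac_range
    records = []
    for (pid, side), yi in zip(records_meta, y):
        baseline = np.round(rng.uniform(f_lo, f_hi) * config.scale_max / res) * res
        baseline = max(baseline, 3.0)  # inclusion rule holds by construction
        post = baseline - yi * config.scale_max
        post = float(np.clip(np.round(post / res) * res, 0.0, baseline))
        records.append(
            HemisphereRecord(
                patient_id=pid, cohort=cohort_label, hemisphere=side,
                baseline=float(baseline), post=post, scale_max=config.scale_max,
                seed=seedmaps[len(records)].seed,
            )
        )
    return records, seedmaps
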