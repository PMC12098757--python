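"""Statistical core: outcome R-maps, map similarity, permutation inference.

The central object is the *R-map*: for every in-mask voxel, the correlation
(Spearman by default) between seed connectivity to that voxel and clinical
improvement across the hemispheres of a cohort.  Positive voxels are
regions whose connectivity to the stimulation volume predominates in top
responders; negative voxels mark connectivity of poor responders.

Scalar correlations are Spearman rank correlations throughout, with
p-values from permutation testing (5000 permutations by default) and 95%
confidence intervals from a seeded bootstrap.  Spatial similarity between
two maps is either a voxel-wise multiplication sum (``similarity_dot``,
used against published a-priori maps) or a spatial rank correlation
(``similarity_corr``, used between R-maps and for cross-cohort
prediction).  The significance of R-map similarity across cohorts is
assessed by permuting outcomes within one (or both) cohorts, rebuilding
the R-map each time, and comparing the observed spatial correlation with
the permutation null (one-sided, 10,000 iterations by default).

All randomness flows from explicit integer seeds through the Philox
counter-based bit generator, so identical seeds give bit-identical results
across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .connectome import Seedmap
from .grids import ScalarMap, VolumeGrid

__all__ = [
    "RMap",
    "CorrelationResult",
    "JointModelResult",
    "CVResult",
    "MapPermutationResult",
    "compute_rmap",
    "similarity_dot",
    "similarity_corr",
    "predict_with_map",
    "residualize_on_cohort",
    "spearman_perm",
    "joint_cohort_model",
    "kfold_cv",
    "rmap_similarity_permtest",
    "seedmap_matrix",
]

_EPS = 1e-12


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed) & (2**63 - 1)))


# -- containers --------------------------------------------------------------

@dataclass(frozen=True)
class RMap:
    """Voxel-wise correlation of connectivity with improvement across a cohort."""

    values: ScalarMap
    method: str
    n: int

    @property
    def valid_mask(self) -> np.ndarray:
        """Voxels with non-degenerate connectivity variance (= map coverage)."""
        return self.values.coverage


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_perm: float
    ci_low: float
    ci_high: float
    n_perm: int

    @property
    def df(self) -> int:
        """Degrees of freedom, n - 2 (the rho(df) reporting convention)."""
        return self.n - 2

    def to_dict(self) -> dict:
        return {
            "rho": self.rho, "n": self.n, "df": self.df, "p_perm": self.p_perm,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "n_perm": self.n_perm,
        }


@dataclass(frozen=True)
class JointModelResult:
    r_squared: float
    adj_r_squared: float
    f_stat: float
    p: float
    coefficients: dict
    n: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared, "adj_r_squared": self.adj_r_squared,
            "f_stat": self.f_stat, "p": self.p, "coefficients": dict(self.coefficients),
            "n": self.n,
        }


@dataclass(frozen=True)
class CVResult:
    fold_assignment: dict
    predictions: np.ndarray
    pooled: CorrelationResult
    fold_rmaps: tuple = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {"fold_assignment": dict(self.fold_assignment),
                "predictions": list(map(float, self.predictions)),
                "pooled": self.pooled.to_dict()}


@dataclass(frozen=True)
class MapPermutationResult:
    observed_similarity: float
    null_similarities: np.ndarray
    p: float
    permute: str

    @property
    def n_perm(self) -> int:
        return int(len(self.null_similarities))

    def to_dict(self) -> dict:
        null = np.asarray(self.null_similarities)
        return {"observed_similarity": self.observed_similarity, "p": self.p,
                "permute": self.permute, "n_perm": self.n_perm,
                "null_mean": float(null.mean()), "null_sd": float(null.std(ddof=1))}


# -- helpers -----------------------------------------------------------------

def seedmap_matrix(seedmaps: list[Seedmap]) -> tuple[np.ndarray, VolumeGrid]:
    """Stack seedmaps into a (hemispheres, voxels) connectivity matrix."""
    if not seedmaps:
        raise ValueError("no seedmaps given")
    grid = seedmaps[0].values.grid
    X = np.stack([sm.values.values for sm in seedmaps])
    return X, grid


def _as_values_coverage(m) -> tuple[np.ndarray, np.ndarray, VolumeGrid]:
    if isinstance(m, Seedmap):
        m = m.values
    if isinstance(m, RMap):
        m = m.values
    if isinstance(m, ScalarMap):
        return m.values, m.coverage, m.grid
    raise TypeError(f"expected ScalarMap/Seedmap/RMap, got {type(m)}")


def _pearson_cols(Xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between centered columns of Xc and centered yc."""
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return sps.rankdata(a, axis=axis)


def _resolve_xy(seedmaps, outcomes, grid=None):
    if isinstance(seedmaps, np.ndarray):
        X = np.asarray(seedmaps, dtype=float)
    else:
        X, grid = seedmap_matrix(list(seedmaps))
    y = np.asarray(outcomes, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} seedmaps but {y.shape[0]} outcomes")
    return X, y, grid


# -- operations --------------------------------------------------------------

def compute_rmap(seedmaps, outcomes, method: str = "spearman",
                 grid: VolumeGrid | None = None) -> RMap:
    """Correlate connectivity with improvement at every voxel.

    ``seedmaps`` is a list of Seedmap objects or an (n_hemispheres, n_voxels)
    array (then ``grid`` is required).  Voxels whose connectivity is constant
    across hemispheres are excluded from the map's coverage; constant
    outcomes make no map definable and raise.
    """
    X, y, grid = _resolve_xy(seedmaps, outcomes, grid)
    if grid is None:
        raise ValueError("grid is required when seedmaps are given as an array")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 hemispheres, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("outcomes are constant across the cohort; no R-map definable")
    if method == "spearman":
        Xw, yw = _rank(X, axis=0), _rank(y)
    elif method == "pearson":
        Xw, yw = X, y
    else:
        raise ValueError(f"unknown method {method!r}")
    Xc = Xw - Xw.mean(axis=0)
    yc = yw - yw.mean()
    r = _pearson_cols(Xc, yc)
    valid = (Xc**2).sum(axis=0) > 0
    values = ScalarMap(grid, np.where(valid, np.nan_to_num(r), 0.0), coverage=valid)
    return RMap(values=values, method=method, n=n)


def similarity_dot(map_a, map_b, mask: np.ndarray | None = None) -> float:
    """Sum of voxel-wise products over the maps' shared coverage.

    The metric used to compare a seedmap against a published a-priori map:
    large when the two spatial profiles load the same voxels with the same
    sign.
    """
    va, ca, grid_a = _as_values_coverage(map_a)
    vb, cb, grid_b = _as_values_coverage(map_b)
    if not grid_a.matches(grid_b):
        raise ValueError("maps are on different grids")
    common = ca & cb
    if mask is not None:
        common &= np.asarray(mask, dtype=bool)
    if not common.any():
        raise ValueError("maps share no covered voxels")
    return float(va[common] @ vb[common])


def similarity_corr(map_a, map_b, mask: np.ndarray | None = None,
                    method: str = "spearman") -> float:
    """Spatial correlation between two maps over their shared coverage."""
    va, ca, grid_a = _as_values_coverage(map_a)
    vb, cb, grid_b = _as_values_coverage(map_b)
    if not grid_a.matches(grid_b):
        raise ValueError("maps are on different grids")
    common = ca & cb
    if mask is not None:
        common &= np.asarray(mask, dtype=bool)
    a, b = va[common], vb[common]
    if a.size < 3:
        raise ValueError(f"only {a.size} shared covered voxels; need >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) map over the shared voxels")
    if method == "spearman":
        r = sps.spearmanr(a, b).statistic
    elif method == "pearson":
        r = sps.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def predict_with_map(seedmaps, reference_map, mode: str = "corr",
                     mask: np.ndarray | None = None, method: str = "spearman") -> np.ndarray:
    """One similarity coefficient per hemisphere against a reference map.

    ``mode='dot'`` is the multiplication-sum metric (a-priori map
    validation); ``mode='corr'`` the spatial correlation (R-map prediction).
    Order of the input seedmaps is preserved.
    """
    out = np.empty(len(seedmaps))
    for i, sm in enumerate(seedmaps):
        if mode == "dot":
            out[i] = similarity_dot(sm, reference_map, mask=mask)
        elif mode == "corr":
            out[i] = similarity_corr(sm, reference_map, mask=mask, method=method)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def residualize_on_cohort(values, cohort_labels) -> np.ndarray:
    """Residuals after regressing out cohort membership (dummy regressors).

    With an intercept plus cohort dummies this is exactly within-cohort mean
    centering.  Single-member cohorts get residual 0 and a warning.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(cohort_labels)
    if v.shape[0] != labels.shape[0]:
        raise ValueError("values and cohort labels differ in length")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 values to residualize")
    out = np.empty_like(v)
    for lab in np.unique(labels):
        idx = labels == lab
        if idx.sum() == 1:
            warnings.warn(f"cohort {lab!r} has a single member; residual forced to 0")
        out[idx] = v[idx] - v[idx].mean()
    return out


def spearman_perm(x, y, n_perm: int = 5000, seed: int = 0,
                  n_boot: int = 2000) -> CorrelationResult:
    """Spearman correlation with permutation p-value and bootstrap 95% CI.

    Two-sided p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm), permuting
    y; never exactly 0.  Ties take average ranks.  The CI is a percentile
    bootstrap over pairs (``n_boot`` resamples; 0 disables it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3 or y.shape[0] != n:
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; Spearman correlation undefined")
    rx, ry = _rank(x), _rank(y)
    rho = float(sps.spearmanr(x, y).statistic)

    rng = _rng(seed)
    rxc = rx - rx.mean()
    nrm_x = np.sqrt((rxc**2).sum())
    nrm_y = np.sqrt(((ry - ry.mean()) ** 2).sum())
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rho_perm = (perms - ry.mean()) @ rxc / (nrm_x * nrm_y)
    p = (1 + int((np.abs(rho_perm) >= abs(rho) - _EPS).sum())) / (1 + n_perm)

    ci_low = ci_high = float("nan")
    if n_boot > 0:
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        ok = (np.ptp(xb, axis=1) > 0) & (np.ptp(yb, axis=1) > 0)
        rxb = _rank(xb[ok], axis=1)
        ryb = _rank(yb[ok], axis=1)
        rxb = rxb - rxb.mean(axis=1, keepdims=True)
        ryb = ryb - ryb.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (rxb * ryb).sum(axis=1) / np.sqrt(
                (rxb**2).sum(axis=1) * (ryb**2).sum(axis=1)
            )
        rb = rb[np.isfinite(rb)]
        if rb.size:
            ci_low, ci_high = (float(q) for q in np.percentile(rb, [2.5, 97.5]))
    return CorrelationResult(rho=rho, n=n, p_perm=float(p),
                             ci_low=ci_low, ci_high=ci_high, n_perm=n_perm)


def joint_cohort_model(similarity, cohort_labels, outcomes,
                       interaction: bool = False) -> JointModelResult:
    """OLS of outcome on similarity plus dummy-coded cohort membership.

    The alternative to residualizing: cohort enters the model as a
    covariate, and the overall F-test judges the joint fit.  An optional
    similarity-by-cohort interaction can be added.
    """
    import pandas as pd
    import statsmodels.api as sm

    s = np.asarray(similarity, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    labels = pd.Series(np.asarray(cohort_labels).astype(str), name="cohort")
    X = pd.DataFrame({"similarity": s})
    dummies = pd.get_dummies(labels, prefix="cohort", drop_first=True, dtype=float)
    X = pd.concat([X, dummies], axis=1)
    if interaction:
        for c in dummies.columns:
            X[f"similarity:{c}"] = s * dummies[c].to_numpy()
    X = sm.add_constant(X)
    if len(y) <= X.shape[1]:
        raise ValueError("not enough observations for the requested model")
    fit = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return JointModelResult(
        r_squared=float(fit.rsquared), adj_r_squared=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue), p=float(fit.f_pvalue),
        coefficients={k: float(v) for k, v in fit.params.items()}, n=int(fit.nobs),
    )


def _patient_folds(patient_ids, cohorts, k: int, rng: np.random.Generator) -> dict:
    """Assign patients to k folds; both hemispheres of a patient share a fold.

    With more than one cohort the split is stratified by cohort so every
    fold mixes cohorts in roughly the input proportions.
    """
    patient_ids = np.asarray(patient_ids)
    cohorts = np.asarray(cohorts)
    # patient -> cohort of first appearance
    seen: dict = {}
    for pid, coh in zip(patient_ids, cohorts):
        seen.setdefault(pid, coh)
    if len(seen) < k:
        raise ValueError(f"only {len(seen)} patients for {k} folds")
    assignment: dict = {}
    for lab in sorted(set(seen.values())):
        pids = [p for p, c in seen.items() if c == lab]
        pids = list(np.array(pids, dtype=object)[rng.permutation(len(pids))])
        for fold, chunk in enumerate(np.array_split(pids, k)):
            for p in chunk:
                assignment[p] = fold
    return assignment


def kfold_cv(records, seedmaps, k: int = 5, seed: int = 0, method: str = "spearman",
             similarity: str = "corr", n_perm: int = 5000,
             adjust_cohort: bool | None = None) -> CVResult:
    """Patient-level k-fold cross-validation of the R-map prediction.

    Patients (never single hemispheres) are shuffled into ``k`` near-equal
    folds; per fold the R-map is rebuilt on the remaining hemispheres and
    left-out hemispheres are scored by spatial similarity to it.  Pooled
    predictions are then rank-correlated with the observed improvements
    (permutation p).  When the records span several cohorts the folds are
    stratified by cohort and cohort membership is regressed out of the
    pooled predictions.
    """
    records = list(records)
    X, y, grid = _resolve_xy(seedmaps, [r.normalized_improvement for r in records])
    pids = np.array([r.patient_id for r in records], dtype=object)
    cohs = np.array([r.cohort for r in records], dtype=object)
    rng = _rng(seed)
    assignment = _patient_folds(pids, cohs, k, rng)
    fold_of = np.array([assignment[p] for p in pids])

    predictions = np.full(len(records), np.nan)
    fold_rmaps = []
    for f in range(k):
        train = fold_of != f
        test = ~train
        if train.sum() < 3 or test.sum() == 0:
            raise ValueError(f"fold {f} leaves too few hemispheres to train or test")
        rmap = compute_rmap(X[train], y[train], method=method, grid=grid)
        fold_rmaps.append(rmap)
        for i in np.flatnonzero(test):
            if similarity == "corr":
                predictions[i] = similarity_corr(
                    ScalarMap(grid, X[i]), rmap, method=method)
            else:
                predictions[i] = similarity_dot(ScalarMap(grid, X[i]), rmap)
    assert np.isfinite(predictions).all(), "a hemisphere was never predicted"

    multi = len(set(cohs)) > 1
    if adjust_cohort is None:
        adjust_cohort = multi
    pooled_pred = residualize_on_cohort(predictions, cohs) if adjust_cohort else predictions
    pooled = spearman_perm(pooled_pred, y, n_perm=n_perm,
                           seed=int(rng.integers(2**31)))
    return CVResult(fold_assignment=assignment, predictions=predictions,
                    pooled=pooled, fold_rmaps=tuple(fold_rmaps))


def _null_rmaps(Xc: np.ndarray, col_nrm: np.ndarray, y_rank_perms: np.ndarray) -> np.ndarray:
    """(voxels, n_perm) R-map values for permuted outcome ranks (or raw values)."""
    P = y_rank_perms - y_rank_perms.mean(axis=1, keepdims=True)
    nrm_y = np.sqrt((P**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ P.T) / (col_nrm[:, None] * nrm_y[None, :])
    return np.nan_to_num(R)


def rmap_similarity_permtest(seedmaps_a, outcomes_a, seedmaps_b, outcomes_b,
                             n_perm: int = 10000, permute: str = "both", seed: int = 0,
                             method: str = "spearman", map_method: str = "spearman",
                             grid: VolumeGrid | None = None,
                             chunk: int = 2000) -> MapPermutationResult:
    """Permutation test of spatial similarity between two cohorts' R-maps.

    Outcomes are shuffled within the permuted cohort(s) (``permute`` =
    ``'a'``, ``'b'`` or ``'both'``), the affected R-map(s) rebuilt, and the
    spatial correlation recorded, building a null distribution against which
    the observed similarity is compared one-sided (greater):
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if permute not in ("a", "b", "both"):
        raise ValueError(f"permute must be 'a', 'b' or 'both', got {permute!r}")
    Xa, ya, grid_a = _resolve_xy(seedmaps_a, outcomes_a, grid)
    Xb, yb, grid_b = _resolve_xy(seedmaps_b, outcomes_b, grid)
    grid = grid_a or grid_b
    rmap_a = compute_rmap(Xa, ya, method=method, grid=grid)
    rmap_b = compute_rmap(Xb, yb, method=method, grid=grid)
    valid = rmap_a.valid_mask & rmap_b.valid_mask
    if valid.sum() < 3:
        raise ValueError("fewer than 3 voxels valid in both R-maps")
    observed = similarity_corr(rmap_a, rmap_b, method=map_method)

    def prep(X, yv):
        if method == "spearman":
            Xw, yw = _rank(X, axis=0), _rank(yv)
        else:
            Xw, yw = X, yv
        Xc = (Xw - Xw.mean(axis=0))[:, valid]
        return Xc, np.sqrt((Xc**2).sum(axis=0)), yw

    Xc_a, nrm_a, yw_a = prep(Xa, ya)
    Xc_b, nrm_b, yw_b = prep(Xb, yb)
    obs_a = rmap_a.values.values[valid]
    obs_b = rmap_b.values.values[valid]

    def spatial(colsA: np.ndarray, colsB: np.ndarray) -> np.ndarray:
        """Per-column spatial correlation between paired map columns."""
        if map_method == "spearman":
            colsA, colsB = _rank(colsA, axis=0), _rank(colsB, axis=0)
        A = colsA - colsA.mean(axis=0)
        B = colsB - colsB.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (A * B).sum(axis=0) / np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
        return np.nan_to_num(r)

    rng = _rng(seed)
    nulls = []
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if permute in ("a", "both"):
            Pa = rng.permuted(np.tile(yw_a, (m, 1)), axis=1)
            RA = _null_rmaps(Xc_a, nrm_a, Pa)
        else:
            RA = np.broadcast_to(obs_a[:, None], (valid.sum(), m))
        if permute in ("b", "both"):
            Pb = rng.permuted(np.tile(yw_b, (m, 1)), axis=1)
            RB = _null_rmaps(Xc_b, nrm_b, Pb)
        else:
            RB = np.broadcast_to(obs_b[:, None], (valid.sum(), m))
        nulls.append(spatial(np.ascontiguousarray(RA), np.ascontiguousarray(RB)))
        done += m
    null = np.concatenate(nulls)
    p = (1 + int((null >= observed - _EPS).sum())) / (1 + n_perm)
    return MapPermutationResult(observed_similarity=observed, null_similarities=null,
                                p=float(p), permute=permute)
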