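"""End-to-end analyses mirroring the study structure, with JSON reports.

Three orchestrated analyses:

* ``run_apriori_validation`` — does connectivity of stimulation volumes to
  published a-priori tremor maps track clinical improvement?  (Pooled,
  cohort-residualized rank correlation; joint linear model; per-cohort
  correlations.)
* ``run_cross_cohort`` — within-cohort circular fit and fivefold
  cross-validation of each cohort's R-map, both cross-prediction
  directions, and the three R-map-similarity permutation tests.
* ``run_convergent_and_holdout`` — the multi-map sign-consistent
  convergent map, its evaluation on a held-out cohort, and the
  leave-one-map-out sensitivity check.  The hold-out firewall is
  mechanical: any map whose provenance contains the hold-out cohort's
  content hash is rejected.

Reports are plain dictionaries (JSON-serializable) carrying every
statistic plus the seeds and input hashes needed to reproduce them.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from . import __version__
from .agreement import agreement_map
from .cohorts import HemisphereRecord, OutcomeVector, cohort_hash
from .connectome import Connectome, Seedmap, seed_connectivity
from .grids import ScalarMap
from .stats import (
    compute_rmap,
    joint_cohort_model,
    kfold_cv,
    predict_with_map,
    residualize_on_cohort,
    rmap_similarity_permtest,
    seedmap_matrix,
    spearman_perm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "cohort_seedmaps",
    "build_cohort_rmap",
    "run_apriori_validation",
    "run_cross_cohort",
    "run_convergent_and_holdout",
    "save_report",
    "load_report",
]


def cohort_seedmaps(conn: Connectome, records: list[HemisphereRecord]) -> list[Seedmap]:
    """Seed the connectome with every record's stimulation volume (flipped left)."""
    maps = []
    for r in records:
        if r.seed is None:
            raise ValueError(f"record {r.patient_id}/{r.hemisphere} has no seed mask")
        maps.append(seed_connectivity(conn, r.seed))
    return maps


def build_cohort_rmap(records: list[HemisphereRecord], seedmaps: list[Seedmap],
                      method: str = "spearman"):
    """Cohort R-map with the cohort's content hash attached as provenance."""
    outcomes = OutcomeVector(records).normalized_improvement
    rmap = compute_rmap(seedmaps, outcomes, method=method)
    values = rmap.values.with_provenance(cohort_hash(records))
    return type(rmap)(values=values, method=rmap.method, n=rmap.n)


def _pooled(records_by_cohort: list[list[HemisphereRecord]]):
    records = [r for cohort in records_by_cohort for r in cohort]
    ov = OutcomeVector(records)
    return records, ov


def run_apriori_validation(cohorts: list[list[HemisphereRecord]],
                           seedmaps_by_cohort: list[list[Seedmap]],
                           apriori_maps: dict[str, ScalarMap],
                           mode: str = "dot", n_perm: int = 5000,
                           seed: int = 0, interaction: bool = False) -> dict:
    """Validate a-priori tremor maps against pooled DBS improvements.

    Per map: similarity coefficient per hemisphere (multiplication sum by
    default), pooled Spearman after residualizing cohort membership out of
    the coefficients, the joint linear model with a cohort dummy, and
    per-cohort correlations.
    """
    records, ov = _pooled(cohorts)
    seedmaps = [sm for group in seedmaps_by_cohort for sm in group]
    y = ov.normalized_improvement
    labels = ov.cohorts
    rng = np.random.default_rng(seed)
    report: dict = {
        "analysis": "apriori_validation",
        "provenance": _provenance(seed, cohorts=cohorts),
        "maps": {},
    }
    for name, amap in apriori_maps.items():
        coeffs = predict_with_map(seedmaps, amap, mode=mode)
        adj = residualize_on_cohort(coeffs, labels)
        pooled = spearman_perm(adj, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
        joint = joint_cohort_model(coeffs, labels, y, interaction=interaction)
        per_cohort = {}
        for cohort_records, cohort_maps in zip(cohorts, seedmaps_by_cohort):
            lab = cohort_records[0].cohort
            c = predict_with_map(cohort_maps, amap, mode=mode)
            yc = OutcomeVector(cohort_records).normalized_improvement
            per_cohort[lab] = spearman_perm(
                c, yc, n_perm=n_perm, seed=int(rng.integers(2**31))).to_dict()
        report["maps"][name] = {
            "pooled": pooled.to_dict(),
            "joint_model": joint.to_dict(),
            "per_cohort": per_cohort,
        }
        logger.info("a-priori map %s: pooled rho(%d)=%.3f p=%.4g",
                    name, pooled.df, pooled.rho, pooled.p_perm)
    return report


def run_cross_cohort(records_a: list[HemisphereRecord], seedmaps_a: list[Seedmap],
                     records_b: list[HemisphereRecord], seedmaps_b: list[Seedmap],
                     n_perm: int = 10000, n_perm_scalar: int = 5000, k: int = 5,
                     seed: int = 0, method: str = "spearman") -> dict:
    """Compare two cohorts' optimal-connectivity maps and cross-predict outcomes."""
    rng = np.random.default_rng(seed)
    ya = OutcomeVector(records_a).normalized_improvement
    yb = OutcomeVector(records_b).normalized_improvement
    lab_a, lab_b = records_a[0].cohort, records_b[0].cohort
    rmap_a = build_cohort_rmap(records_a, seedmaps_a, method=method)
    rmap_b = build_cohort_rmap(records_b, seedmaps_b, method=method)

    def circular(seedmaps, rmap, y):
        # in-sample fit; reported as R without a p-value (circular by design)
        coeffs = predict_with_map(seedmaps, rmap, mode="corr", method=method)
        from scipy import stats as sps
        return {"R": float(sps.spearmanr(coeffs, y).statistic), "n": len(y),
                "circular": True}

    report: dict = {
        "analysis": "cross_cohort",
        "provenance": _provenance(seed, cohorts=[records_a, records_b]),
        "circular": {lab_a: circular(seedmaps_a, rmap_a, ya),
                     lab_b: circular(seedmaps_b, rmap_b, yb)},
        "crossval": {},
        "cross_prediction": {},
        "map_permutation": {},
    }
    for lab, recs, maps in ((lab_a, records_a, seedmaps_a), (lab_b, records_b, seedmaps_b)):
        cv = kfold_cv(recs, maps, k=k, seed=int(rng.integers(2**31)),
                      method=method, n_perm=n_perm_scalar)
        report["crossval"][lab] = cv.pooled.to_dict()
        logger.info("%s fivefold CV: rho(%d)=%.3f p=%.4g",
                    lab, cv.pooled.df, cv.pooled.rho, cv.pooled.p_perm)

    for (src_lab, src_rmap), (dst_lab, dst_maps, dst_y) in (
        ((lab_b, rmap_b), (lab_a, seedmaps_a, ya)),
        ((lab_a, rmap_a), (lab_b, seedmaps_b, yb)),
    ):
        coeffs = predict_with_map(dst_maps, src_rmap, mode="corr", method=method)
        res = spearman_perm(coeffs, dst_y, n_perm=n_perm_scalar,
                            seed=int(rng.integers(2**31)))
        report["cross_prediction"][f"{src_lab}_map_predicts_{dst_lab}"] = res.to_dict()
        logger.info("%s map predicts %s: rho(%d)=%.3f p=%.4g",
                    src_lab, dst_lab, res.df, res.rho, res.p_perm)

    Xa, grid = seedmap_matrix(seedmaps_a)
    Xb, _ = seedmap_matrix(seedmaps_b)
    for permute in ("a", "b", "both"):
        res = rmap_similarity_permtest(
            Xa, ya, Xb, yb, n_perm=n_perm, permute=permute,
            seed=int(rng.integers(2**31)), method=method, grid=grid)
        key = {"a": f"permute_{lab_a}", "b": f"permute_{lab_b}", "both": "permute_both"}[permute]
        report["map_permutation"][key] = res.to_dict()
        logger.info("map permutation (%s): observed=%.3f p=%.4g",
                    key, res.observed_similarity, res.p)
    report["rmaps"] = {lab_a: rmap_a, lab_b: rmap_b}
    return report


def run_convergent_and_holdout(maps: dict[str, ScalarMap],
                               holdout_records: list[HemisphereRecord],
                               holdout_seedmaps: list[Seedmap],
                               mode: str = "corr", n_perm: int = 5000,
                               seed: int = 0, rescale: str = "maxabs") -> dict:
    """Build the convergent map and test it on an untouched hold-out cohort.

    Raises if any input map's provenance contains the hold-out cohort's
    hash — the firewall that guarantees the cohort never informed the map.
    Also runs the leave-one-map-out variant for each input map.
    """
    hold_hash = cohort_hash(holdout_records)
    for name, m in maps.items():
        if hold_hash in m.provenance:
            raise ValueError(
                f"data leakage: map {name!r} was built using the hold-out cohort "
                f"(hash {hold_hash})"
            )
    if len(maps) < 2:
        raise ValueError("need at least 2 maps for a convergent map")
    rng = np.random.default_rng(seed)
    y = OutcomeVector(holdout_records).normalized_improvement

    def evaluate(selected: dict[str, ScalarMap]) -> dict:
        agr = agreement_map(list(selected.values()), rescale=rescale)
        coeffs = predict_with_map(holdout_seedmaps, agr.z, mode=mode)
        res = spearman_perm(coeffs, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
        return {"result": res.to_dict(),
                "n_retained_voxels": int(agr.retained_mask.sum()),
                "maps_used": sorted(selected)}

    report: dict = {
        "analysis": "convergent_holdout",
        "provenance": _provenance(seed, cohorts=[holdout_records]),
        "holdout_cohort": holdout_records[0].cohort,
        "holdout_hash": hold_hash,
        "full": evaluate(maps),
        "leave_one_out": {},
    }
    logger.info("convergent map vs hold-out: rho=%.3f p=%.4g",
                report["full"]["result"]["rho"], report["full"]["result"]["p_perm"])
    if len(maps) > 2:
        for name in maps:
            subset = {k: v for k, v in maps.items() if k != name}
            report["leave_one_out"][f"without_{name}"] = evaluate(subset)
    return report


def _provenance(seed: int, cohorts: list[list[HemisphereRecord]] | None = None) -> dict:
    prov = {"seed": int(seed), "package_version": __version__}
    if cohorts:
        prov["cohort_hashes"] = {c[0].cohort: cohort_hash(c) for c in cohorts if c}
    return prov


def save_report(report: dict, path) -> None:
    """Write a report as JSON (non-serializable entries like RMaps dropped)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return None

    clean = {k: v for k, v in report.items() if k != "rmaps"}
    with open(path, "w") as f:
        json.dump(clean, f, indent=2, default=default)


def load_report(path) -> dict:
    with open(path) as f:
        return json.load(f)
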