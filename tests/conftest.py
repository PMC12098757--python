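import numpy as np
import pytest

import tremormap as tm


@pytest.fixture(scope="session")
def small_grid():
    """10x6x4 grid, 2 mm isotropic, fully in-mask."""
    return tm.VolumeGrid((10, 6, 4), affine=np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture(scope="session")
def toy_connectome(small_grid):
    """Deterministic small group connectome (3 subjects, 2 runs each)."""
    rng = np.random.default_rng(7)
    n_vox = small_grid.n_voxels
    subjects = []
    for _ in range(3):
        runs = [rng.standard_normal((12, n_vox)) for _ in range(2)]
        subjects.append(runs)
    return tm.build_group_connectome(subjects, small_grid)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study shared across tests.

    Default desk-scale config: two cohorts with disjoint target boxes and
    different clinical scales, generated from the same planted truth, plus
    a hold-out cohort at a third target.
    """
    cfg = tm.SimulationConfig()
    conn = tm.simulate_connectome(cfg, seed=101)
    grid = conn.grid
    hub = tm.default_hub(grid)
    truth = tm.plant_truth(conn, hub)
    cfg_b = cfg.with_(target_box=tm.second_target_box(cfg), scale_max=40.0,
                      baseline_frac_range=(0.6, 1.0))
    cfg_c = cfg.with_(target_box=((2, 5, 2), (6, 12, 5)), n_patients=16)
    rec_a, maps_a = tm.simulate_cohort(conn, truth, cfg, "STN", seed=111)
    rec_b, maps_b = tm.simulate_cohort(conn, truth, cfg_b, "VIM", seed=112)
    rec_c, maps_c = tm.simulate_cohort(conn, truth, cfg_c, "GPi", seed=113)
    return {
        "cfg": cfg, "conn": conn, "grid": grid, "truth": truth,
        "rec_a": rec_a, "maps_a": maps_a,
        "rec_b": rec_b, "maps_b": maps_b,
        "rec_c": rec_c, "maps_c": maps_c,
    }


def brute_force_pearson_matrix(runs):
    """Independent oracle: per-pair Pearson on the demeaned concatenation."""
    demeaned = [np.asarray(r, float) - np.asarray(r, float).mean(axis=0) for r in runs]
    ts = np.concatenate(demeaned, axis=0)
    n = ts.shape[1]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = ts[:, i], ts[:, j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            out[i, j] = out[j, i] = num / den
    return out


def brute_force_rank(v):
    """Average ranks by counting, independent of scipy."""
    v = np.asarray(v, float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = (v < x).sum()
        equal = (v == x).sum()
        out[i] = less + (equal + 1) / 2.0
    return out


def brute_force_spearman(x, y):
    rx, ry = brute_force_rank(x), brute_force_rank(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return float((rxc * ryc).sum() / np.sqrt((rxc**2).sum() * (ryc**2).sum()))
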