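import numpy as np
import pandas as pd
import pytest

from podmap import make_design
from podmap.design import to_model_coords


@pytest.fixture(scope="session")
def design():
    """The canonical 18/54/162 ug x 1/3/28 d design, 5 treated + 5 controls."""
    return make_design([18, 54, 162], [1, 3, 28], 5, 5, seed=11)


def records_from_surface(design, fn, noise_sd=0.0, reps=5, rng=None):
    """Fold-change records at the design points from a surface z = fn(d, t).

    ``fn`` takes normalized coordinates.  One record per (dose, time, rep).
    """
    rows = []
    for dose in design.doses:
        for time in design.times:
            d, t = to_model_coords(dose, time, design)
            for _ in range(reps):
                rows.append((dose, time, float(fn(float(d), float(t)))))
    frame = pd.DataFrame(rows, columns=["dose", "time", "log2fc"])
    if noise_sd > 0:
        frame["log2fc"] += (rng or np.random.default_rng(0)).normal(0, noise_sd, len(frame))
    return frame


def oracle_responsive_region(grid, threshold):
    """Brute-force monotone-run detector used as an independent oracle.

    For each time column, enumerates every suffix of dose bins, checks strict
    sign-constant monotonicity directly, keeps the longest suffix run ending
    at the top dose, and applies the activity-threshold rules.
    """
    grid = np.asarray(grid, dtype=float)
    nd, nt = grid.shape
    mask = np.zeros_like(grid, dtype=bool)
    pods, signs = [], []
    for j in range(nt):
        col = grid[:, j]
        run_start, run_sign = None, 0
        for a in range(nd - 1):  # longest suffix first
            diffs = np.diff(col[a:])
            if np.all(diffs > 0):
                run_start, run_sign = a, 1
                break
            if np.all(diffs < 0):
                run_start, run_sign = a, -1
                break
        pod = None
        if run_start is not None and abs(col[-1]) >= threshold:
            for i in range(run_start, nd):
                if abs(col[i]) >= threshold:
                    pod = i
                    break
        pods.append(pod)
        if pod is not None:
            signs.append(run_sign)
            mask[pod:, j] = True
    responsive = any(p is not None for p in pods)
    if not responsive:
        direction = "none"
    else:
        n_up = sum(1 for s in signs if s > 0)
        direction = "increasing" if n_up >= len(signs) - n_up else "decreasing"
    return mask, pods, direction, responsive


def random_fitted_surfaces(design, n, seed):
    """Fit linear+quadratic candidates to n random noisy polynomial datasets."""
    from podmap.surface import fit_surface

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        coefs = {
            term: rng.uniform(-2, 2)
            for term in ("intercept", "d", "t", "d2", "t2", "dt")
            if rng.random() < 0.7
        }
        fn = lambda d, t: (
            coefs.get("intercept", 0)
            + coefs.get("d", 0) * d
            + coefs.get("t", 0) * t
            + coefs.get("d2", 0) * d * d
            + coefs.get("t2", 0) * t * t
            + coefs.get("dt", 0) * d * t
        )
        rec = records_from_surface(design, fn, noise_sd=0.3, rng=rng)
        lin, quad = fit_surface(rec, design, entity_id=f"rand{i}")
        out.extend([lin, quad])
    return out
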