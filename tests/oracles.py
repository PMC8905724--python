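"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by the most literal route available —
per-voxel scalar geometry, exhaustive enumeration, full sorting — and is
kept free of any code path it is checking.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_cylinder(geom, grid, diameter_mm, length_mm) -> np.ndarray:
    """Per-voxel point-in-cylinder test via the vector rejection formula."""
    entry = np.asarray(geom.entry_mm, float)
    axis = np.asarray(geom.axis, float)
    world = grid.world_coordinates().reshape(-1, 3)
    v = world - entry
    s = v @ axis
    radial = np.linalg.norm(np.cross(v, axis), axis=1)  # |v| sin(angle)
    inside = (s >= 0) & (s <= length_mm) & (radial <= diameter_mm / 2.0)
    return inside.reshape(grid.shape)


def brute_force_box(geom, grid, dims_mm) -> np.ndarray:
    """Per-voxel point-in-prism test using scalar projections."""
    w, h, depth = dims_mm
    e1, e2 = geom.basis()
    entry = np.asarray(geom.entry_mm, float)
    axis = np.asarray(geom.axis, float)
    out = np.zeros(grid.shape, bool)
    world = grid.world_coordinates()
    for idx in np.ndindex(grid.shape):
        v = world[idx] - entry
        out[idx] = (
            0 <= float(v @ axis) <= depth
            and abs(float(v @ e1)) <= w / 2.0
            and abs(float(v @ e2)) <= h / 2.0
        )
    return out


def wilcoxon_enumeration(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(np.dot(signs, ranks)))
    ws = np.asarray(ws)
    p_le = float((ws <= w_obs + 1e-12).mean())
    p_ge = float((ws >= w_obs - 1e-12).mean())
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def adaptive_threshold_brute(values: np.ndarray, fraction: float) -> float:
    """Smallest observed value with strict exceedance fraction below target,
    found by checking every candidate."""
    values = np.asarray(values, float)
    n = values.size
    best = None
    for t in sorted(values):
        if (values > t).sum() / n < fraction:
            best = t
            break
    assert best is not None
    return float(best)


def match_controls_brute(index, pool, k, mmse_tol, match_diagnosis=False):
    """Full sort of the eligible pool by (|age gap|, |mmse gap|, id)."""
    eligible = sorted(
        (
            c
            for c in pool
            if c.gender == index.gender
            and abs(c.mmse - index.mmse) <= mmse_tol
            and (not match_diagnosis or c.diagnosis == index.diagnosis)
        ),
        key=lambda c: (abs(c.age - index.age), abs(c.mmse - index.mmse), c.id),
    )
    return [c.id for c in eligible[:k]], len(eligible) < k


def fisher_lda_two_class(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-class Fisher discriminant direction by the closed form
    ``w ∝ Sw^-1 (m1 - m0)`` computed directly in feature space."""
    classes = sorted(set(y.tolist()))
    assert len(classes) == 2
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
    Sw = Sw / (len(X) - 2)
    Sw = Sw + 1e-9 * np.trace(Sw) / len(Sw) * np.eye(len(Sw))
    return np.linalg.solve(Sw, m1 - m0)
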