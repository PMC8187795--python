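"""Independent reference implementations used only to cross-check camfuse.

These deliberately share no code path with the package: membership shapes
are evaluated with ``np.interp`` / ``math.exp``, Mamdani inference runs as
explicit loops on a dense grid with Riemann-sum centroids, the DLT oracle
solves the inhomogeneous 8-parameter linear system with ``np.linalg.lstsq``
(no conditioning, no SVD nullspace), and NMS is a quadratic
suppression-table sweep.
"""

from __future__ import annotations

import math

import numpy as np

from camfuse.fuzzy import Gaussian, Trapezoidal, Triangular


# ---------------------------------------------------------------------------
# fuzzy reference

def membership_reference(mf, x):
    """Evaluate a membership function by piecewise-linear interpolation /
    direct exponential, independent of the package's min/clip formulas."""
    x = np.asarray(x, dtype=float)
    if isinstance(mf, Triangular):
        xs, ys = [mf.a, mf.b, mf.c], [0.0, 1.0, 0.0]
    elif isinstance(mf, Trapezoidal):
        xs, ys = [mf.a, mf.b, mf.c, mf.d], [0.0, 1.0, 1.0, 0.0]
    elif isinstance(mf, Gaussian):
        return np.exp(np.array([-((v - mf.mean) ** 2) / (2.0 * mf.sigma**2) for v in np.atleast_1d(x)])).reshape(x.shape)
    else:  # pragma: no cover
        raise TypeError(type(mf))
    # drop duplicate breakpoints (np.interp needs increasing xp)
    pts = []
    for xv, yv in zip(xs, ys):
        if pts and pts[-1][0] == xv:
            pts[-1] = (xv, max(pts[-1][1], yv))
        else:
            pts.append((xv, yv))
    xp, fp = zip(*pts)
    return np.interp(x, xp, fp)


def mamdani_reference(rulebase, crisp_inputs, grid_step=0.01):
    """Full Mamdani pipeline recomputed with loops on a dense output grid.

    Clamps inputs to each variable's universe, takes min over antecedent
    degrees (1 - mu when negated), clips consequents, aggregates by max and
    returns the Riemann-sum centroid; None when nothing fired.
    """
    variables = {v.name: v for v in rulebase.inputs}
    lo, hi = rulebase.output.universe
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    agg = np.zeros_like(grid)
    fired_any = False
    for rule in rulebase.rules:
        act = 1.0
        for ant in rule.antecedents:
            var = variables[ant.variable]
            x = min(max(float(crisp_inputs[ant.variable]), var.universe[0]), var.universe[1])
            mu = float(membership_reference(var.sets[ant.label], np.array([x]))[0])
            if ant.negated:
                mu = 1.0 - mu
            act = min(act, mu)
        if act > 0.0:
            fired_any = True
            out_mu = membership_reference(rulebase.output.sets[rule.consequent], grid)
            agg = np.maximum(agg, np.minimum(out_mu, act))
    if not fired_any or agg.sum() == 0.0:
        return None
    return float((grid * agg).sum() / agg.sum())


# ---------------------------------------------------------------------------
# homography reference

def dlt_reference(src, dst):
    """Inhomogeneous DLT: fix h33 = 1 and solve the 8-unknown linear least
    squares built directly from the transfer equations."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    a = np.zeros((2 * n, 8))
    b = np.zeros(2 * n)
    for i, ((x, y), (xp, yp)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1.0, 0.0, 0.0, 0.0, -xp * x, -xp * y]
        b[2 * i] = xp
        a[2 * i + 1] = [0.0, 0.0, 0.0, x, y, 1.0, -yp * x, -yp * y]
        b[2 * i + 1] = yp
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.append(sol, 1.0).reshape(3, 3)


def project_reference(m, pts):
    """Homogeneous matrix arithmetic: stack, multiply, dehomogenize."""
    pts = np.asarray(pts, dtype=float)
    hom = np.c_[pts, np.ones(len(pts))]
    mapped = hom @ np.asarray(m, dtype=float).T
    return mapped[:, :2] / mapped[:, 2:3]


# ---------------------------------------------------------------------------
# box references

def iou_shapely(a, b):
    from shapely.geometry import box as shapely_box

    pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
    pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def nms_reference(detections, threshold):
    """Quadratic suppression table: repeatedly take the best unsuppressed
    detection and mark everything it dominates."""
    from camfuse.boxes import iou as impl_iou

    remaining = list(detections)
    kept = []
    while remaining:
        best_idx = 0
        for i, d in enumerate(remaining):
            bb, db = remaining[best_idx], d
            if (d.score, -db.box.x_min, -db.box.y_min) > (
                bb.score, -bb.box.x_min, -bb.box.y_min
            ):
                best_idx = i
        best = remaining.pop(best_idx)
        kept.append(best)
        remaining = [d for d in remaining if impl_iou(best.box, d.box) <= threshold]
    return kept
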