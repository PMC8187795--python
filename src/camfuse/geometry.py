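"""Planar projective geometry between two camera image planes.

A planar homography is a non-singular 3x3 matrix ``H`` mapping homogeneous
image coordinates of one camera's plane to another's.  Because ``H`` is
homogeneous only the ratios of its entries matter (8 degrees of freedom);
matrices here are stored normalized so that ``h33 = 1``.  Pixel coordinates
follow image convention: origin at the top-left corner, y increasing
downward, continuous (never snapped to integers).

Estimation from point correspondences uses the direct linear transform with
Hartley-style isotropic conditioning, optionally wrapped in robust loops
(RANSAC consensus or least-median-of-squares) to reject gross outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .boxes import BoundingBox
from .errors import (
    DegenerateGeometryError,
    DegenerateProjectionError,
    SingularMatrixError,
)

__all__ = [
    "ImagePoint",
    "PointCorrespondence",
    "Homography",
    "EstimationResult",
    "project_point",
    "invert",
    "project_box",
    "reprojection_error",
    "estimate_homography",
    "ESTIMATION_METHODS",
]

ESTIMATION_METHODS = ("least_mean_square", "ransac", "least_median_square")


class ImagePoint(NamedTuple):
    """A continuous pixel coordinate (origin top-left, y downward)."""

    x: float
    y: float


class PointCorrespondence(NamedTuple):
    """A matched point pair: ``source`` on the left/camera-2 plane, ``target`` on the right/camera-1 plane."""

    source: ImagePoint
    target: ImagePoint


@dataclass(frozen=True)
class Homography:
    """A non-singular 3x3 planar projective map, normalized so h33 = 1.

    If the natural scale has ``|h33|`` below machine-noise level the matrix
    is instead normalized to unit Frobenius norm and ``h33_normalized`` is
    False; such maps send finite points near the principal axis to infinity
    and are rare in practice.
    """

    h: np.ndarray
    h33_normalized: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.h, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography entries must be finite")
        if abs(np.linalg.det(m)) < 1e-15 * max(np.abs(m).max() ** 3, 1e-30):
            raise SingularMatrixError("homography matrix is singular")
        if abs(m[2, 2]) > 1e-12:
            m = m / m[2, 2]
            object.__setattr__(self, "h33_normalized", True)
        else:
            m = m / np.linalg.norm(m)
            object.__setattr__(self, "h33_normalized", False)
        m.setflags(write=False)
        object.__setattr__(self, "h", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Homography":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls(m)


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of a homography fit.

    ``reprojection_error`` is the mean Euclidean transfer distance in pixels
    per point, reported uniformly for every method so they are comparable;
    each method still optimizes its own criterion (mean of squares, inlier
    consensus, or median of squares).  ``inlier_flags`` marks the
    correspondences the final fit treated as inliers (all True for the
    non-robust method).
    """

    homography: Homography
    reprojection_error: float
    method: str
    inlier_flags: np.ndarray

    def __post_init__(self) -> None:
        if self.reprojection_error < 0:
            raise ValueError("reprojection error must be non-negative")


# ---------------------------------------------------------------------------
# point and box mapping

def project_point(h: Homography, p: ImagePoint | tuple[float, float]) -> ImagePoint:
    """Map a point through the homography (homogeneous multiply then dehomogenize).

    Raises :class:`DegenerateProjectionError` when the point lies on the line
    that ``h`` sends to infinity (projective denominator ~ 0).
    """
    x, y = float(p[0]), float(p[1])
    m = h.h
    den = m[2, 0] * x + m[2, 1] * y + m[2, 2]
    if abs(den) < 1e-10 * (1.0 + abs(x) + abs(y)):
        raise DegenerateProjectionError(
            f"point ({x}, {y}) maps to the plane at infinity (denominator {den:.3e})"
        )
    xp = (m[0, 0] * x + m[0, 1] * y + m[0, 2]) / den
    yp = (m[1, 0] * x + m[1, 1] * y + m[1, 2]) / den
    return ImagePoint(xp, yp)


def invert(h: Homography) -> Homography:
    """Inverse map, renormalized to h33 = 1 (round-trips points to ~1e-6 px)."""
    return Homography(np.linalg.inv(h.h))


def project_box(h: Homography, b: BoundingBox) -> BoundingBox:
    """Project a box's four corners and return their axis-aligned hull.

    A rectangle generally maps to a quadrilateral under a projective map;
    overlap in this package is defined on axis-aligned boxes, so the hull of
    the mapped corners is returned.
    """
    corners = [
        (b.x_min, b.y_min),
        (b.x_max, b.y_min),
        (b.x_min, b.y_max),
        (b.x_max, b.y_max),
    ]
    mapped = [project_point(h, c) for c in corners]
    xs = [p.x for p in mapped]
    ys = [p.y for p in mapped]
    return BoundingBox(min(xs), min(ys), max(xs), max(ys))


# ---------------------------------------------------------------------------
# estimation

def _as_arrays(correspondences: Sequence[PointCorrespondence]) -> tuple[np.ndarray, np.ndarray]:
    src = np.array([[c.source[0], c.source[1]] for c in correspondences], dtype=float)
    dst = np.array([[c.target[0], c.target[1]] for c in correspondences], dtype=float)
    return src, dst


def _transfer_distances(m: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Euclidean distance between H*src and dst for each correspondence."""
    ones = np.ones((len(src), 1))
    ph = np.hstack([src, ones]) @ m.T
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = ph[:, :2] / ph[:, 2:3]
    d = np.linalg.norm(proj - dst, axis=1)
    # points sent to infinity count as unbounded error
    d[~np.isfinite(d)] = np.inf
    return d


def reprojection_error(
    h: Homography,
    correspondences: Sequence[PointCorrespondence],
    mask: np.ndarray | None = None,
) -> float:
    """Mean Euclidean deviation (pixels per point) of mapped source points from targets."""
    if len(correspondences) == 0:
        raise ValueError("reprojection error requires at least one correspondence")
    src, dst = _as_arrays(correspondences)
    d = _transfer_distances(h.h, src, dst)
    if mask is not None:
        d = d[np.asarray(mask, dtype=bool)]
        if len(d) == 0:
            raise ValueError("mask selects no correspondences")
    return float(np.mean(d))


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate centroid to origin and scale mean distance to sqrt(2)."""
    centroid = pts.mean(axis=0)
    shifted = pts - centroid
    mean_dist = np.mean(np.linalg.norm(shifted, axis=1))
    scale = math.sqrt(2.0) / mean_dist if mean_dist > 1e-12 else 1.0
    t = np.array(
        [
            [scale, 0.0, -scale * centroid[0]],
            [0.0, scale, -scale * centroid[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    return t, shifted * scale


def _dlt(src: np.ndarray, dst: np.ndarray, rank_tol: float = 1e-8) -> np.ndarray:
    """Direct linear transform with isotropic conditioning.

    Raises :class:`DegenerateGeometryError` when the linear system is rank
    deficient (e.g. three of four points collinear), in which case the
    homography is not uniquely determined.
    """
    ts, sn = _hartley_normalize(src)
    td, dn = _hartley_normalize(dst)
    n = len(src)
    a = np.zeros((2 * n, 9))
    x, y = sn[:, 0], sn[:, 1]
    xp, yp = dn[:, 0], dn[:, 1]
    a[0::2, 0] = x
    a[0::2, 1] = y
    a[0::2, 2] = 1.0
    a[0::2, 6] = -xp * x
    a[0::2, 7] = -xp * y
    a[0::2, 8] = -xp
    a[1::2, 3] = x
    a[1::2, 4] = y
    a[1::2, 5] = 1.0
    a[1::2, 6] = -yp * x
    a[1::2, 7] = -yp * y
    a[1::2, 8] = -yp
    _, s, vh = np.linalg.svd(a)
    if s[7] <= rank_tol * s[0]:
        raise DegenerateGeometryError(
            "correspondence configuration is degenerate (collinear points?)"
        )
    hn = vh[-1].reshape(3, 3)
    return np.linalg.inv(td) @ hn @ ts


def _refine(m0: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Nonlinear refinement of the geometric transfer error, h33 fixed at 1."""
    if abs(m0[2, 2]) < 1e-12:
        return m0  # pathological scale; keep the linear solution

    m0 = m0 / m0[2, 2]
    ones = np.ones((len(src), 1))
    src_h = np.hstack([src, ones])

    def residuals(params: np.ndarray) -> np.ndarray:
        m = np.append(params, 1.0).reshape(3, 3)
        ph = src_h @ m.T
        den = ph[:, 2:3]
        den = np.where(np.abs(den) < 1e-12, 1e-12, den)
        return ((ph[:, :2] / den) - dst).ravel()

    sol = least_squares(residuals, m0.ravel()[:8], method="lm")
    return np.append(sol.x, 1.0).reshape(3, 3)


def _fit_all(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT followed by geometric (mean-squared transfer distance) refinement."""
    return _refine(_dlt(src, dst), src, dst)


def _resolve_rng(seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError(
            "robust estimation (ransac / least_median_square) requires an explicit "
            "seed or rng for reproducibility"
        )
    return np.random.default_rng(seed)


def _minimal_samples(
    n: int, iterations: int, rng: np.random.Generator
) -> Iterable[np.ndarray]:
    for _ in range(iterations):
        yield rng.choice(n, size=4, replace=False)


def estimate_homography(
    correspondences: Sequence[PointCorrespondence],
    method: str = "least_mean_square",
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    iterations: int | None = None,
    inlier_threshold: float = 3.0,
) -> EstimationResult:
    """Estimate the homography mapping source points onto target points.

    Parameters
    ----------
    correspondences
        At least four matched point pairs; for a minimal four-point set no
        three points may be collinear (no n-1 collinear in general).
    method
        ``least_mean_square`` minimizes the mean squared Euclidean transfer
        distance over all points; ``ransac`` maximizes the inlier consensus
        under ``inlier_threshold`` (default 3 px, default 2000 iterations)
        then refits on the inliers; ``least_median_square`` minimizes the
        median squared transfer distance over minimal samples (default 1000)
        then refits on points within 2.5 robust standard deviations.
    seed, rng
        Required for the two stochastic methods; all sampling flows through
        one :class:`numpy.random.Generator`.
    """
    n = len(correspondences)
    if n < 4:
        raise ValueError(f"homography estimation needs >= 4 correspondences, got {n}")
    if method not in ESTIMATION_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {ESTIMATION_METHODS}")
    src, dst = _as_arrays(correspondences)
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise ValueError("correspondences must be finite")

    if method == "least_mean_square":
        m = _fit_all(src, dst)
        flags = np.ones(n, dtype=bool)
    elif method == "ransac":
        iterations = 2000 if iterations is None else iterations
        generator = _resolve_rng(seed, rng)
        best_mask: np.ndarray | None = None
        best_count = -1
        best_sse = np.inf
        for idx in _minimal_samples(n, iterations, generator):
            try:
                cand = _dlt(src[idx], dst[idx])
            except DegenerateGeometryError:
                continue
            d = _transfer_distances(cand, src, dst)
            mask = d < inlier_threshold
            count = int(mask.sum())
            sse = float(np.sum(np.minimum(d, inlier_threshold) ** 2))
            if count > best_count or (count == best_count and sse < best_sse):
                best_count, best_sse, best_mask = count, sse, mask
        if best_mask is None or best_count < 4:
            raise DegenerateGeometryError("ransac found no non-degenerate consensus set")
        m = _fit_all(src[best_mask], dst[best_mask])
        flags = _transfer_distances(m, src, dst) < inlier_threshold
        if flags.sum() >= 4:
            m = _fit_all(src[flags], dst[flags])
        else:
            flags = best_mask
    else:  # least_median_square
        iterations = 1000 if iterations is None else iterations
        generator = _resolve_rng(seed, rng)
        best_med = np.inf
        best_m: np.ndarray | None = None
        for idx in _minimal_samples(n, iterations, generator):
            try:
                cand = _dlt(src[idx], dst[idx])
            except DegenerateGeometryError:
                continue
            med = float(np.median(_transfer_distances(cand, src, dst) ** 2))
            if med < best_med:
                best_med, best_m = med, cand
        if best_m is None:
            raise DegenerateGeometryError("all least-median samples were degenerate")
        # robust scale (Rousseeuw-Leroy) -> inlier set -> ordinary refit
        sigma = 1.4826 * (1.0 + 5.0 / max(n - 4, 1)) * math.sqrt(max(best_med, 0.0))
        d = _transfer_distances(best_m, src, dst)
        flags = d <= max(2.5 * sigma, 1e-9)
        if flags.sum() >= 4:
            m = _fit_all(src[flags], dst[flags])
        else:
            m, flags = best_m, d <= np.inf

    hom = Homography(m)
    err = reprojection_error(hom, correspondences, mask=flags)
    return EstimationResult(
        homography=hom, reprojection_error=err, method=method, inlier_flags=flags
    )
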