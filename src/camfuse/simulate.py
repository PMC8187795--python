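"""Synthetic two-camera pinhole test bed.

Emulates the physical rig the confidence system is calibrated on: two
fronto-parallel pinhole cameras with a horizontal baseline viewing an object
(a weed plant, modeled as a fronto-planar patch) at four distance classes,
"too far" (~36 in) down to "too close" (~8 in).  A pinhole camera maps a
world point (X, Y, Z) to pixel (f X / Z, f Y / Z) relative to its own center
and principal point.  Because the calibration checkerboard is planar, the
two image planes are related exactly by a plane-induced homography; for this
parallel rig that map is a pure pixel translation of f B / Z_plane.

The object sits at its own depth, not at the calibration-plane depth, so the
reprojected boxes still mis-align more and more as the object approaches the
cameras — overlap after reprojection falls toward zero at "too close" while
remaining at or above the un-reprojected overlap at every class.  The module
generates checkerboard correspondences (with optional noise and outliers),
perfect and perturbed bounding-box pairs, and the per-class IOU anchors the
fuzzy system is built on.  All randomness flows through one explicit seeded
generator; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .boxes import BoundingBox, Detection, iou
from .errors import ConfigError
from .geometry import (
    Homography,
    ImagePoint,
    PointCorrespondence,
    project_box,
)

__all__ = [
    "CameraModel",
    "StereoRig",
    "ScenePose",
    "SyntheticFrame",
    "CLASS_DEPTHS",
    "DISTANCE_PEAKS",
    "DISTANCE_CLASSES",
    "DEFAULT_BOX_SIZE",
    "default_rig",
    "render_box",
    "fixed_size_box",
    "ground_truth_homography",
    "generate_correspondences",
    "calibrate_iou_anchors",
    "generate_scenario",
]

#: Object-to-camera depth (inches) for each distance class.  The two
#: endpoints are physical rig measurements (~36 in and ~8 in); the middle
#: classes interpolate between them.
CLASS_DEPTHS: dict[str, float] = {
    "too far": 36.0,
    "far": 22.0,
    "close": 14.0,
    "too close": 8.0,
}

DISTANCE_CLASSES = ("too far", "far", "close", "too close")

#: Vertical pixel position (from the top of a 720-px-high view) at which a
#: perfectly detected box is centered for each class: a closer object sits
#: lower in the frame.  The too-far peak (150 px) is a rig measurement; the
#: rest spread uniformly to the bottom quarter of the frame.
DISTANCE_PEAKS: dict[str, float] = {
    "too far": 150.0,
    "far": 300.0,
    "close": 450.0,
    "too close": 600.0,
}

#: Fixed detector bounding-box size in pixels (width, height).
DEFAULT_BOX_SIZE: tuple[float, float] = (500.0, 350.0)


@dataclass(frozen=True)
class CameraModel:
    """A pinhole camera: focal length f (px), principal point, image size,
    and a horizontal world-position offset (inches) of the camera center."""

    f: float
    principal_point: tuple[float, float] = (640.0, 360.0)
    image_size: tuple[float, float] = (1280.0, 720.0)
    position: float = 0.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ConfigError(f"focal length must be positive, got {self.f}")

    def project(self, x: float, y: float, z: float) -> ImagePoint:
        """Pinhole projection of a world point; requires z > 0 (in front)."""
        if z <= 0:
            raise ValueError(f"point must lie in front of the camera (Z > 0), got Z={z}")
        cx, cy = self.principal_point
        return ImagePoint(cx + self.f * (x - self.position) / z, cy + self.f * y / z)


@dataclass(frozen=True)
class StereoRig:
    """Two cameras sharing orientation and intrinsics, horizontal baseline.

    ``left`` is the source (camera-2) view that gets reprojected onto
    ``right`` (camera-1); ``calibration_depth`` is the depth of the planar
    checkerboard that induces the ground-truth homography.
    """

    left: CameraModel
    right: CameraModel
    calibration_depth: float

    def __post_init__(self) -> None:
        if self.calibration_depth <= 0:
            raise ConfigError("calibration plane must lie in front of the cameras")
        if self.left.f != self.right.f:
            raise ConfigError("rig cameras must share intrinsics")

    @property
    def baseline(self) -> float:
        return abs(self.left.position - self.right.position)


@dataclass(frozen=True)
class ScenePose:
    """The object's world position (inches) and fronto-planar physical extent."""

    x: float
    y: float
    z: float
    width: float = 10.0
    height: float = 7.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError(f"object depth must be positive, got {self.z}")

    @property
    def distance_class(self) -> str:
        return min(CLASS_DEPTHS, key=lambda lbl: abs(CLASS_DEPTHS[lbl] - self.z))


@dataclass(frozen=True)
class SyntheticFrame:
    """One simulated two-camera frame: ground-truth boxes, (possibly
    perturbed) detections, the true distance class and the rig homography."""

    kind: str
    distance_class: str
    left_box: BoundingBox
    right_box: BoundingBox
    left_detection: Detection
    right_detection: Detection
    homography: Homography
    seed: int | None = None

    def to_dict(self) -> dict:
        def box(b: BoundingBox) -> dict:
            return {"x_min": b.x_min, "y_min": b.y_min, "x_max": b.x_max, "y_max": b.y_max}

        def det(d: Detection) -> dict:
            return {"label": d.label, "score": d.score, "box": box(d.box)}

        return {
            "kind": self.kind,
            "distance_class": self.distance_class,
            "left_box": box(self.left_box),
            "right_box": box(self.right_box),
            "left_detection": det(self.left_detection),
            "right_detection": det(self.right_detection),
            "homography": {"h": self.homography.h.tolist()},
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def default_rig(
    f: float = 700.0,
    image_size: tuple[float, float] = (1280.0, 720.0),
    calibration_depth: float = 48.0,
    close_iou_pin: float = 15.0,
    box_size: tuple[float, float] = DEFAULT_BOX_SIZE,
) -> StereoRig:
    """The rig the default confidence configuration is calibrated on.

    The baseline is solved analytically so that the reprojected IOU of
    perfect fixed-size boxes at the "close" depth equals ``close_iou_pin``
    percent, tying the synthetic geometry to the one measured overlap anchor.
    With full vertical overlap the horizontal box offset d gives
    IOU = (w - d) / (w + d), so d = w (1 - t) / (1 + t) for target t.
    """
    if not 0 < close_iou_pin < 100:
        raise ConfigError("close-class IOU pin must lie in (0, 100)")
    t = close_iou_pin / 100.0
    w = box_size[0]
    d_close = w * (1.0 - t) / (1.0 + t)
    z_close = CLASS_DEPTHS["close"]
    k = abs(1.0 / z_close - 1.0 / calibration_depth)
    if k <= 0:
        raise ConfigError("calibration plane must differ from the close-class depth")
    fb = d_close / k
    baseline = fb / f
    cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
    # the source ("left", camera-2) view maps onto the destination by a
    # positive pixel shift; positions are symmetric about the object axis
    left = CameraModel(f=f, principal_point=(cx, cy), image_size=image_size,
                       position=+baseline / 2.0)
    right = CameraModel(f=f, principal_point=(cx, cy), image_size=image_size,
                        position=-baseline / 2.0)
    return StereoRig(left=left, right=right, calibration_depth=calibration_depth)


def render_box(cam: CameraModel, pose: ScenePose) -> BoundingBox:
    """Project the object's fronto-planar extent: image size = f * physical / Z."""
    tl = cam.project(pose.x - pose.width / 2.0, pose.y - pose.height / 2.0, pose.z)
    br = cam.project(pose.x + pose.width / 2.0, pose.y + pose.height / 2.0, pose.z)
    return BoundingBox(tl.x, tl.y, br.x, br.y)


def fixed_size_box(
    cam: CameraModel, pose: ScenePose, box_size: tuple[float, float] = DEFAULT_BOX_SIZE
) -> BoundingBox:
    """A fixed-size detector box centered on the projected object centroid."""
    c = cam.project(pose.x, pose.y, pose.z)
    return BoundingBox.from_center(c.x, c.y, box_size[0], box_size[1])


def ground_truth_homography(rig: StereoRig, plane_depth: float | None = None) -> Homography:
    """The exact left-to-right map induced by the calibration plane.

    For parallel fronto-planar cameras this is a pure pixel translation of
    f * B / Z_plane; a zero baseline yields the identity.
    """
    z = rig.calibration_depth if plane_depth is None else plane_depth
    if z <= 0:
        raise ValueError("calibration plane must lie in front of both cameras")
    dx = rig.left.f * (rig.left.position - rig.right.position) / z
    return Homography.translation(dx, 0.0)


def generate_correspondences(
    rig: StereoRig,
    plane_depth: float | None = None,
    grid: tuple[int, int] = (9, 6),
    noise_sigma: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    fill: float = 0.6,
) -> list[PointCorrespondence]:
    """Checkerboard-like corner correspondences between the two views.

    An n x m grid of coplanar world points at ``plane_depth`` is projected
    into both cameras.  ``noise_sigma`` adds i.i.d. Gaussian pixel noise to
    both views; ``outlier_fraction`` replaces that fraction of target points
    with uniform gross outliers.  Reproducible per seed.
    """
    n, m = grid
    if n * m < 4:
        raise ValueError(f"correspondence grid needs at least 4 points, got {n}x{m}")
    if (noise_sigma > 0 or outlier_fraction > 0) and rng is None:
        if seed is None:
            raise ValueError("noise or outliers require an explicit seed or rng")
        rng = np.random.default_rng(seed)
    z = rig.calibration_depth if plane_depth is None else plane_depth
    if z <= 0:
        raise ValueError("plane must lie in front of the cameras")
    width, height = rig.right.image_size
    half_x = fill * (width / 2.0) * z / rig.right.f
    half_y = fill * (height / 2.0) * z / rig.right.f
    xs = np.linspace(-half_x, half_x, n)
    ys = np.linspace(-half_y, half_y, m)
    src = np.array([rig.left.project(x, y, z) for y in ys for x in xs])
    dst = np.array([rig.right.project(x, y, z) for y in ys for x in xs])
    total = n * m
    if noise_sigma > 0:
        src = src + rng.normal(0.0, noise_sigma, size=src.shape)
        dst = dst + rng.normal(0.0, noise_sigma, size=dst.shape)
    if outlier_fraction > 0:
        n_out = int(round(outlier_fraction * total))
        idx = rng.choice(total, size=n_out, replace=False)
        dst[idx, 0] = rng.uniform(0.0, width, size=n_out)
        dst[idx, 1] = rng.uniform(0.0, height, size=n_out)
    return [
        PointCorrespondence(ImagePoint(*s), ImagePoint(*d)) for s, d in zip(src, dst)
    ]


def _class_pose(rig: StereoRig, distance_class: str) -> ScenePose:
    """Object pose whose perfect boxes sit at the class's vertical peak."""
    z = CLASS_DEPTHS[distance_class]
    cy = rig.right.principal_point[1]
    y = (DISTANCE_PEAKS[distance_class] - cy) * z / rig.right.f
    return ScenePose(x=0.0, y=y, z=z)


def calibrate_iou_anchors(
    rig: StereoRig,
    box_size: tuple[float, float] = DEFAULT_BOX_SIZE,
    reproject: bool = True,
) -> dict[str, float]:
    """Per-class IOU percentage of perfect fixed-size boxes across the two views.

    With ``reproject`` the left box is first mapped through the rig's
    ground-truth homography (the deployed configuration); without it the raw
    cross-camera overlap is returned.  Anchors increase monotonically with
    distance: the farther the object, the better the planar homography
    approximates its parallax, so the boxes align better.
    """
    h = ground_truth_homography(rig)
    anchors: dict[str, float] = {}
    for label in DISTANCE_CLASSES:
        pose = _class_pose(rig, label)
        lb = fixed_size_box(rig.left, pose, box_size)
        rb = fixed_size_box(rig.right, pose, box_size)
        if reproject:
            lb = project_box(h, lb)
        anchors[label] = float(100.0 * iou(lb, rb))
    return anchors


def generate_scenario(
    kind: str,
    rig: StereoRig | None = None,
    distance_class: str = "too close",
    seed: int = 0,
    box_size: tuple[float, float] = DEFAULT_BOX_SIZE,
    ok_iou_target: float = 50.0,
    low_displaced_class: str = "far",
    jitter_sigma: float = 0.0,
    label: str = "cocklebur",
    score: float = 1.0,
) -> SyntheticFrame:
    """Build one of the three canonical test frames at a distance class.

    ``high``: both detections are the perfect boxes — the rule base should
    report high confidence.  ``ok``: both vertical centers are correct but
    the left detection is shifted laterally so the reprojected IOU lands at
    ``ok_iou_target`` percent, far from the class anchor (the only evidence
    against the frame is the overlap).  ``low``: the left detection is
    displaced vertically to the ``low_displaced_class`` position — the two
    cameras disagree about where the object is.  ``jitter_sigma`` adds
    seeded Gaussian pixel noise to the detection corners (default off).
    """
    if kind not in ("high", "ok", "low"):
        raise ValueError(f"scenario kind must be high, ok or low, got {kind!r}")
    if rig is None:
        rig = default_rig(box_size=box_size)
    pose = _class_pose(rig, distance_class)
    h = ground_truth_homography(rig)
    left_true = fixed_size_box(rig.left, pose, box_size)
    right_true = fixed_size_box(rig.right, pose, box_size)
    left_det_box = left_true

    if kind == "ok":
        # lateral shift so the reprojected horizontal offset yields the
        # target IOU (full vertical overlap: IOU = (w - d) / (w + d))
        t = ok_iou_target / 100.0
        d_target = box_size[0] * (1.0 - t) / (1.0 + t)
        reproj = project_box(h, left_true)
        d0 = (reproj.x_min + reproj.x_max - right_true.x_min - right_true.x_max) / 2.0
        new_d = math.copysign(d_target, d0) if d0 != 0 else d_target
        left_det_box = left_true.shifted(new_d - d0, 0.0)
    elif kind == "low":
        dy = DISTANCE_PEAKS[low_displaced_class] - DISTANCE_PEAKS[distance_class]
        left_det_box = left_true.shifted(0.0, dy)

    right_det_box = right_true
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        jl = rng.normal(0.0, jitter_sigma, size=2)
        jr = rng.normal(0.0, jitter_sigma, size=2)
        left_det_box = left_det_box.shifted(*jl)
        right_det_box = right_det_box.shifted(*jr)

    return SyntheticFrame(
        kind=kind,
        distance_class=distance_class,
        left_box=left_true,
        right_box=right_true,
        left_detection=Detection(box=left_det_box, label=label, score=score),
        right_detection=Detection(box=right_det_box, label=label, score=score),
        homography=h,
        seed=seed,
    )
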