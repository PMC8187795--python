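"""End-to-end detection-confidence scoring for a two-camera rig.

The pipeline trusts a frame's detections to the degree that three crisp
measurements agree with the calibrated geometry: the vertical center of the
right camera's box, the vertical center of the left camera's box (measured
on its own plane, before reprojection), and the IOU overlap (in percent)
between the left box reprojected through the rig homography and the right
box.  Each measurement is fuzzified against four distance classes ("too
far" ... "too close"); a 20-rule Mamdani base maps the three inputs to a
Confidence output (low / ok / high) defuzzified by centroid to a 0-100 %
score.

The rule base encodes one idea: if both cameras place the object at the
same distance class AND the overlap matches that class's calibrated anchor,
confidence is High (rules 1-4); if the cameras disagree about the distance
class, confidence is Low regardless of overlap (rules 5-16, which carry no
IOU antecedent); if the cameras agree but the overlap is NOT at its anchor,
confidence is OK (rules 17-20, with a negated IOU antecedent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .boxes import BoundingBox, Detection, iou, nms, vertical_center
from .errors import ConfigError, NoDetectionError, NoRuleFiredError
from .fuzzy import (
    AggregatedOutput,
    Antecedent,
    FuzzyRule,
    Gaussian,
    LinguisticVariable,
    MembershipFunction,
    RuleBase,
    Triangular,
    Trapezoidal,
    aggregate,
    defuzzify_centroid,
)
from .geometry import Homography, project_box
from .simulate import DISTANCE_CLASSES, DISTANCE_PEAKS, calibrate_iou_anchors, default_rig

__all__ = [
    "VAR_RIGHT",
    "VAR_LEFT",
    "VAR_IOU",
    "VAR_OUT",
    "ConfidenceConfig",
    "ScenarioInput",
    "ConfidenceResult",
    "build_confidence_system",
    "evaluate_system",
    "score_pair",
    "score_frame",
    "classify_score",
]

VAR_RIGHT = "RightCam BB"
VAR_LEFT = "LeftCam BB"
VAR_IOU = "IOU overlap"
VAR_OUT = "Confidence"

# half-width factor turning a mean gap into the sigma at which two adjacent
# Gaussians cross at degree 0.5: exp(-(gap/2)^2 / (2 sigma^2)) = 1/2
_CROSS_AT_HALF = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _default_output_sets() -> dict[str, MembershipFunction]:
    return {
        "low": Triangular(0.0, 0.0, 30.0),
        "ok": Triangular(30.0, 50.0, 70.0),
        "high": Triangular(70.0, 100.0, 100.0),
    }


def _default_iou_sigmas(anchors: Mapping[str, float]) -> dict[str, float]:
    """Sigmas so each Gaussian crosses its nearest neighbor at degree 0.5."""
    ordered = sorted(anchors.items(), key=lambda kv: kv[1])
    sigmas: dict[str, float] = {}
    for i, (label, value) in enumerate(ordered):
        gaps = []
        if i > 0:
            gaps.append(value - ordered[i - 1][1])
        if i < len(ordered) - 1:
            gaps.append(ordered[i + 1][1] - value)
        sigmas[label] = min(gaps) / _CROSS_AT_HALF
    return sigmas


@dataclass(frozen=True)
class ConfidenceConfig:
    """Full parameterization of the confidence system.

    ``distance_anchors`` holds, per camera ('right'/'left'), the vertical
    pixel at which each class's membership peaks; ``iou_anchors`` the
    perfect-detection reprojected IOU percentage per class (calibrated from
    the rig); ``iou_sigmas`` the Gaussian widths of the IOU sets.
    """

    distance_anchors: dict[str, dict[str, float]]
    iou_anchors: dict[str, float]
    iou_sigmas: dict[str, float]
    output_sets: dict[str, MembershipFunction] = field(default_factory=_default_output_sets)
    distance_universe: tuple[float, float] = (0.0, 720.0)
    iou_universe: tuple[float, float] = (0.0, 100.0)
    output_universe: tuple[float, float] = (0.0, 100.0)
    nms_threshold: float = 0.5
    resolution: float = 0.1

    def __post_init__(self) -> None:
        for cam in ("right", "left"):
            if cam not in self.distance_anchors:
                raise ConfigError(f"distance_anchors missing camera {cam!r}")
            peaks = [self.distance_anchors[cam].get(lbl) for lbl in DISTANCE_CLASSES]
            if any(p is None for p in peaks):
                raise ConfigError(f"distance_anchors[{cam!r}] must define all four classes")
            # closer object sits lower in frame: peaks strictly increase
            if not all(a < b for a, b in zip(peaks, peaks[1:])):
                raise ConfigError(
                    f"distance anchors for {cam!r} must strictly increase from "
                    f"'too far' to 'too close', got {peaks}"
                )
        ious = [self.iou_anchors.get(lbl) for lbl in DISTANCE_CLASSES]
        if any(v is None for v in ious):
            raise ConfigError("iou_anchors must define all four classes")
        # overlap grows with distance: too far > far > close > too close
        if not all(a > b for a, b in zip(ious, ious[1:])):
            raise ConfigError(
                f"IOU anchors must strictly increase from 'too close' to 'too far', got {ious}"
            )
        for lbl in DISTANCE_CLASSES:
            if self.iou_sigmas.get(lbl, 0.0) <= 0.0:
                raise ConfigError(f"iou_sigmas[{lbl!r}] must be positive")
        for name in ("low", "ok", "high"):
            if name not in self.output_sets:
                raise ConfigError(f"output_sets missing {name!r}")
        if not 0.0 <= self.nms_threshold <= 1.0:
            raise ConfigError("nms_threshold must lie in [0, 1]")
        if self.resolution <= 0.0:
            raise ConfigError("centroid resolution must be positive")

    @classmethod
    def default(cls) -> "ConfidenceConfig":
        """Defaults calibrated on the package's default synthetic rig."""
        anchors = calibrate_iou_anchors(default_rig())
        return cls(
            distance_anchors={"right": dict(DISTANCE_PEAKS), "left": dict(DISTANCE_PEAKS)},
            iou_anchors=anchors,
            iou_sigmas=_default_iou_sigmas(anchors),
        )

    def to_dict(self) -> dict:
        return {
            "distance_anchors": {
                c: {k: float(x) for k, x in v.items()}
                for c, v in self.distance_anchors.items()
            },
            "iou_anchors": {k: float(x) for k, x in self.iou_anchors.items()},
            "iou_sigmas": {k: float(x) for k, x in self.iou_sigmas.items()},
            "output_sets": {k: mf.to_dict() for k, mf in self.output_sets.items()},
            "distance_universe": [float(x) for x in self.distance_universe],
            "iou_universe": [float(x) for x in self.iou_universe],
            "output_universe": [float(x) for x in self.output_universe],
            "nms_threshold": float(self.nms_threshold),
            "resolution": float(self.resolution),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConfidenceConfig":
        try:
            return cls(
                distance_anchors={c: dict(v) for c, v in d["distance_anchors"].items()},
                iou_anchors=dict(d["iou_anchors"]),
                iou_sigmas=dict(d["iou_sigmas"]),
                output_sets={
                    k: MembershipFunction.from_dict(v) for k, v in d["output_sets"].items()
                },
                distance_universe=tuple(d.get("distance_universe", (0.0, 720.0))),
                iou_universe=tuple(d.get("iou_universe", (0.0, 100.0))),
                output_universe=tuple(d.get("output_universe", (0.0, 100.0))),
                nms_threshold=float(d.get("nms_threshold", 0.5)),
                resolution=float(d.get("resolution", 0.1)),
            )
        except KeyError as exc:
            raise ConfigError(f"confidence config missing key {exc}") from exc


@dataclass(frozen=True)
class ScenarioInput:
    """A single cross-camera box pair plus the left-to-right homography."""

    right_box: BoundingBox
    left_box: BoundingBox
    homography: Homography


@dataclass(frozen=True)
class ConfidenceResult:
    score: float
    label: str
    iou_after_reprojection: float
    crisp_inputs: dict[str, float]
    input_degrees: dict[str, dict[str, float]]
    fired_rules: dict[str, float]


def _distance_variable(name: str, peaks: Mapping[str, float],
                       universe: tuple[float, float]) -> LinguisticVariable:
    """Ruspini partition over the vertical-position universe: interior
    triangles with feet at the neighboring peaks, shouldered end sets."""
    lo, hi = universe
    ordered = sorted(peaks.items(), key=lambda kv: kv[1])
    sets: dict[str, MembershipFunction] = {}
    for i, (label, p) in enumerate(ordered):
        if i == 0:
            sets[label] = Trapezoidal(lo, lo, p, ordered[i + 1][1])
        elif i == len(ordered) - 1:
            sets[label] = Trapezoidal(ordered[i - 1][1], p, hi, hi)
        else:
            sets[label] = Triangular(ordered[i - 1][1], p, ordered[i + 1][1])
    return LinguisticVariable(name=name, universe=universe, sets=sets)


def build_confidence_system(config: ConfidenceConfig) -> RuleBase:
    """Assemble the three input variables, output variable and 20 rules.

    Rules 1-4 (High) require all three inputs at the same class; 5-16 (Low)
    cover every cross-camera class disagreement and deliberately omit the
    IOU antecedent; 17-20 (OK) require class agreement with a negated IOU
    antecedent.
    """
    right_var = _distance_variable(VAR_RIGHT, config.distance_anchors["right"],
                                   config.distance_universe)
    left_var = _distance_variable(VAR_LEFT, config.distance_anchors["left"],
                                  config.distance_universe)
    iou_var = LinguisticVariable(
        name=VAR_IOU,
        universe=config.iou_universe,
        sets={
            lbl: Gaussian(config.iou_anchors[lbl], config.iou_sigmas[lbl])
            for lbl in DISTANCE_CLASSES
        },
    )
    out_var = LinguisticVariable(
        name=VAR_OUT, universe=config.output_universe, sets=dict(config.output_sets)
    )

    rules: list[FuzzyRule] = []
    # R1-R4: full three-way agreement -> High
    for i, lbl in enumerate(DISTANCE_CLASSES, start=1):
        rules.append(
            FuzzyRule(
                name=f"R{i}",
                antecedents=(
                    Antecedent(VAR_RIGHT, lbl),
                    Antecedent(VAR_IOU, lbl),
                    Antecedent(VAR_LEFT, lbl),
                ),
                consequent="high",
            )
        )
    # R5-R16: cameras disagree on the class -> Low (no IOU antecedent)
    low_pairs = [
        ("too far", "too close"), ("too far", "close"), ("too far", "far"),
        ("far", "too far"), ("far", "close"), ("far", "too close"),
        ("close", "too far"), ("close", "far"), ("close", "too close"),
        ("too close", "close"), ("too close", "far"), ("too close", "too far"),
    ]
    for i, (r_lbl, l_lbl) in enumerate(low_pairs, start=5):
        rules.append(
            FuzzyRule(
                name=f"R{i}",
                antecedents=(Antecedent(VAR_RIGHT, r_lbl), Antecedent(VAR_LEFT, l_lbl)),
                consequent="low",
            )
        )
    # R17-R20: cameras agree but the overlap is off its anchor -> OK
    for i, lbl in enumerate(DISTANCE_CLASSES, start=17):
        rules.append(
            FuzzyRule(
                name=f"R{i}",
                antecedents=(
                    Antecedent(VAR_RIGHT, lbl),
                    Antecedent(VAR_IOU, lbl, negated=True),
                    Antecedent(VAR_LEFT, lbl),
                ),
                consequent="ok",
            )
        )
    return RuleBase(rules=tuple(rules), inputs=(right_var, iou_var, left_var), output=out_var)


def evaluate_system(
    system: RuleBase, crisp_inputs: Mapping[str, float], resolution: float = 0.1
) -> tuple[float, dict[str, float]]:
    """Run Mamdani inference: returns (centroid score, per-rule activations)."""
    agg = aggregate(system, crisp_inputs)
    score = defuzzify_centroid(agg, resolution)
    return score, dict(agg.activations)


def classify_score(score: float, config: ConfidenceConfig | None = None) -> str:
    """Label of the output set with maximum membership at the score.

    Ties break toward the higher-confidence label (the set peaking at the
    larger output value).
    """
    sets = (config.output_sets if config is not None else _default_output_sets())

    def peak_position(mf: MembershipFunction) -> float:
        if isinstance(mf, Triangular):
            return mf.b
        if isinstance(mf, Trapezoidal):
            return (mf.b + mf.c) / 2.0
        if isinstance(mf, Gaussian):
            return mf.mean
        return 0.0

    ordered = sorted(sets.items(), key=lambda kv: peak_position(kv[1]))
    best_label, best_mu = ordered[0][0], -1.0
    for label, mf in ordered:  # later (higher) sets win ties
        mu = float(mf.degree(score))
        if mu >= best_mu:
            best_label, best_mu = label, mu
    return best_label


def score_pair(
    scenario: ScenarioInput,
    config: ConfidenceConfig,
    system: RuleBase | None = None,
) -> ConfidenceResult:
    """Score one already-paired left/right box pair."""
    if system is None:
        system = build_confidence_system(config)
    reproj = project_box(scenario.homography, scenario.left_box)
    overlap_pct = 100.0 * iou(reproj, scenario.right_box)
    crisp = {
        VAR_RIGHT: vertical_center(scenario.right_box),
        VAR_LEFT: vertical_center(scenario.left_box),
        VAR_IOU: overlap_pct,
    }
    try:
        score, activations = evaluate_system(system, crisp, config.resolution)
    except NoRuleFiredError as exc:
        raise NoRuleFiredError(
            f"no rule fired for crisp inputs {crisp}"
        ) from exc
    degrees = {v.name: v.degrees(crisp[v.name]) for v in system.inputs}
    fired = {name: act for name, act in activations.items() if act > 0.0}
    return ConfidenceResult(
        score=score,
        label=classify_score(score, config),
        iou_after_reprojection=overlap_pct,
        crisp_inputs=crisp,
        input_degrees=degrees,
        fired_rules=fired,
    )


def score_frame(
    left_detections: Sequence[Detection],
    right_detections: Sequence[Detection],
    h: Homography,
    config: ConfidenceConfig,
    system: RuleBase | None = None,
) -> ConfidenceResult:
    """Score a frame: NMS per camera, pick the cross-camera pair with the
    highest reprojected IOU, then run the rule base on that pair."""
    if len(left_detections) == 0 or len(right_detections) == 0:
        raise NoDetectionError("both cameras must contribute at least one detection")
    left_kept = nms(left_detections, config.nms_threshold)
    right_kept = nms(right_detections, config.nms_threshold)
    best: tuple[float, Detection, Detection] | None = None
    for ld in left_kept:
        reproj = project_box(h, ld.box)
        for rd in right_kept:
            o = iou(reproj, rd.box)
            if best is None or o > best[0]:
                best = (o, ld, rd)
    _, left, right = best
    return score_pair(
        ScenarioInput(right_box=right.box, left_box=left.box, homography=h),
        config,
        system=system,
    )
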