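"""File readers and writers shared by the library and the CLI.

Structured records use JSON, correspondences use CSV (header
``x1,y1,x2,y2``), configuration uses YAML or JSON.  All numeric output is
written at full double precision (Python ``repr``) so files round-trip
bit-exactly.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .boxes import BoundingBox, Detection
from .confidence import ConfidenceConfig
from .errors import ConfigError
from .geometry import EstimationResult, Homography, ImagePoint, PointCorrespondence

__all__ = [
    "read_detections",
    "write_detections",
    "read_correspondences",
    "write_correspondences",
    "read_homography",
    "write_homography",
    "load_config",
    "save_config",
    "RunManifest",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def _parse_box(raw: Mapping, index: int) -> BoundingBox:
    if not isinstance(raw, Mapping):
        raise ValueError(f"detection {index}: 'box' must be an object, got {type(raw).__name__}")
    corner = {"x_min", "y_min", "x_max", "y_max"}
    center = {"cx", "cy", "width", "height"}
    keys = set(raw)
    try:
        if corner <= keys:
            return BoundingBox(float(raw["x_min"]), float(raw["y_min"]),
                               float(raw["x_max"]), float(raw["y_max"]))
        if center <= keys:
            return BoundingBox.from_center(float(raw["cx"]), float(raw["cy"]),
                                           float(raw["width"]), float(raw["height"]))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"detection {index}: invalid box values: {exc}") from exc
    raise ValueError(
        f"detection {index}: 'box' needs keys {sorted(corner)} or {sorted(center)}, "
        f"got {sorted(keys)}"
    )


def read_detections(path: str | Path) -> dict[str, list[Detection]]:
    """Read a detections JSON file, grouped by camera name.

    Each record is ``{camera, frame?, label, score, box}``.  Scores given as
    percentages (in (1, 100]) are coerced to fractions with a logged warning.
    Malformed records raise :class:`ValueError` naming the field and index.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: detections file must hold a JSON array")
    out: dict[str, list[Detection]] = {}
    for i, rec in enumerate(data):
        if not isinstance(rec, Mapping):
            raise ValueError(f"detection {i}: expected an object, got {type(rec).__name__}")
        for fld in ("camera", "box"):
            if fld not in rec:
                raise ValueError(f"detection {i}: missing field {fld!r}")
        box = _parse_box(rec["box"], i)
        score = float(rec.get("score", 1.0))
        if 1.0 < score <= 100.0:
            logger.warning(
                "detection %d: score %.6g looks like a percentage; coerced to %.6g",
                i, score, score / 100.0,
            )
            score /= 100.0
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"detection {i}: score {score} outside [0, 1]")
        out.setdefault(str(rec["camera"]), []).append(
            Detection(box=box, label=str(rec.get("label", "")), score=score)
        )
    return out


def write_detections(path: str | Path, detections: Mapping[str, Sequence[Detection]],
                     frame: int = 0) -> None:
    records = []
    for camera, dets in detections.items():
        for d in dets:
            records.append(
                {
                    "camera": camera,
                    "frame": frame,
                    "label": d.label,
                    "score": d.score,
                    "box": {
                        "x_min": d.box.x_min, "y_min": d.box.y_min,
                        "x_max": d.box.x_max, "y_max": d.box.y_max,
                    },
                }
            )
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_correspondences(path: str | Path) -> list[PointCorrespondence]:
    """Read a correspondence CSV (header ``x1,y1,x2,y2``); (x1,y1) is the
    source/left point, (x2,y2) the target/right point, in pixels."""
    corrs: list[PointCorrespondence] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty correspondence file") from None
        expected = ["x1", "y1", "x2", "y2"]
        if [c.strip().lower() for c in header] != expected:
            raise ValueError(f"{path}: expected header {','.join(expected)}, got {header}")
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: row {row_no}: expected 4 columns, got {len(row)}")
            try:
                x1, y1, x2, y2 = (float(c.strip()) for c in row)
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_no}: non-numeric value: {exc}") from exc
            corrs.append(PointCorrespondence(ImagePoint(x1, y1), ImagePoint(x2, y2)))
    if not corrs:
        raise ValueError(f"{path}: no correspondences found")
    return corrs


def write_correspondences(path: str | Path, corrs: Sequence[PointCorrespondence]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x1", "y1", "x2", "y2"])
        for c in corrs:
            writer.writerow([repr(float(v)) for v in (*c.source, *c.target)])


def read_homography(path: str | Path) -> Homography:
    with open(path) as fh:
        data = json.load(fh)
    if "h" not in data:
        raise ValueError(f"{path}: homography file must hold a JSON object with key 'h'")
    return Homography(data["h"])


def write_homography(path: str | Path, est: EstimationResult | Homography) -> None:
    """Write ``{"h": [[...]]}`` (plus fit diagnostics for estimation results)."""
    if isinstance(est, EstimationResult):
        payload = {
            "h": est.homography.h.tolist(),
            "method": est.method,
            "reprojection_error": est.reprojection_error,
            "inlier_flags": est.inlier_flags.tolist(),
        }
    else:
        payload = {"h": est.h.tolist()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> ConfidenceConfig:
    """Load a confidence configuration from YAML or JSON."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return ConfidenceConfig.from_dict(data)


def save_config(path: str | Path, config: ConfidenceConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    inputs: list[str]
    config_digest: str
    seed: int | None
    version: str
    timestamp: str


def write_manifest(
    out_path: str | Path,
    command: str,
    inputs: Sequence[str | Path] = (),
    config_path: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Write ``<out>.manifest.json`` next to an output file."""
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    else:
        digest = "default"
    manifest = RunManifest(
        command=command,
        inputs=[str(p) for p in inputs],
        config_digest=digest,
        seed=seed,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path
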