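"""How bounding-box overlap depends on object distance.

Places a perfectly detected object at the four distance classes of the
synthetic rig and prints the cross-camera IOU of its fixed-size boxes,
before and after reprojecting the left view through the calibration-plane
homography.  These after-reprojection percentages are the anchors the
confidence system's Gaussian IOU sets are centered on.
"""

from camfuse import calibrate_iou_anchors, default_rig
from camfuse.simulate import CLASS_DEPTHS, DISTANCE_CLASSES

rig = default_rig()
after = calibrate_iou_anchors(rig)
before = calibrate_iou_anchors(rig, reproject=False)

print(f"rig: f = {rig.left.f:g} px, baseline = {rig.baseline:.2f} in, "
      f"calibration plane at {rig.calibration_depth:g} in\n")
print(f"{'class':>10s} {'depth':>7s} {'IOU before':>11s} {'IOU after':>10s}")
for lbl in DISTANCE_CLASSES:
    print(f"{lbl:>10s} {CLASS_DEPTHS[lbl]:5.0f} in {before[lbl]:10.1f}% {after[lbl]:9.1f}%")

print(
    "\nOverlap falls as the object approaches: the planar homography models"
    "\nthe calibration plane, so the 3D object's parallax mismatch grows at"
    "\nshort range.  Reprojection always helps (after >= before); the close"
    "\nclass is calibrated to exactly 15% by the rig construction."
)
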