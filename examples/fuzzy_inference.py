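"""Peek inside one Mamdani inference step.

Feeds hand-picked crisp inputs to the 20-rule confidence base and prints
the fuzzification of each input, every nonzero rule activation, and the
defuzzified score.  The inputs sit between the "close" and "too close"
anchors, so several rules fire partially at once.
"""

from camfuse import ConfidenceConfig, build_confidence_system
from camfuse.confidence import VAR_IOU, VAR_LEFT, VAR_RIGHT, classify_score, evaluate_system

config = ConfidenceConfig.default()
system = build_confidence_system(config)

crisp = {VAR_RIGHT: 520.0, VAR_LEFT: 560.0, VAR_IOU: 9.0}
print("crisp inputs:", {k: f"{v:g}" for k, v in crisp.items()})

for var in system.inputs:
    degs = var.degrees(crisp[var.name])
    active = {lbl: round(d, 3) for lbl, d in degs.items() if d > 1e-3}
    print(f"  {var.name:12s} -> {active}")

score, activations = evaluate_system(system, crisp, resolution=config.resolution)
print("\nfired rules (activation = min over antecedent degrees):")
for name, act in activations.items():
    if act > 0:
        rule = next(r for r in system.rules if r.name == name)
        clause = " and ".join(a.describe() for a in rule.antecedents)
        print(f"  {name:4s} {clause}  ->  {rule.consequent:4s} @ {act:.3f}")

print(f"\ncentroid of the aggregated output: {score:.1f}%  "
      f"-> classified {classify_score(score, config)!r}")
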