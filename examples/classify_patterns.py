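"""Temporal response quadrants and qPCR relative copy numbers.

Classifies log2 fold-change pairs (30 and 90 minutes post-treatment vs
control) into the four temporal quadrants, then quantifies a qPCR
measurement and normalizes it to a reference gene.
"""

from gsanova import (
    QpcrMeasurement,
    classify_quadrant,
    normalize_to_reference,
    qpcr_relative_copy_number,
)

pairs = [
    ("sustained-up gene", 0.9, 1.3),
    ("transient up-down gene", 1.1, -0.4),
    ("transient down-up gene", -0.8, 0.6),
    ("sustained-down gene", -1.2, -0.7),
    ("unchanged at 30'", 0.0, 1.0),
]
print("quadrants by fold-change signs (t1 = 30 min, t2 = 90 min):")
for name, lfc1, lfc2 in pairs:
    quadrant, label = classify_quadrant(lfc1, lfc2)
    print(f"  {name:<24} ({lfc1:+.1f}, {lfc2:+.1f}) -> {quadrant or 'NA':<3} {label}")

target = qpcr_relative_copy_number(QpcrMeasurement(E=90, Ct=20))
reference = qpcr_relative_copy_number(QpcrMeasurement(E=95, Ct=18))
print(f"\nqPCR target  (E=90%, Ct=20): relative copy number {target:.3e}")
print(f"qPCR reference (E=95%, Ct=18): relative copy number {reference:.3e}")
print(f"target normalized to reference: {normalize_to_reference(target, reference):.3f}")
print("(1 + E/100)^(-Ct): one extra cycle to threshold ~ half the template.")
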