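"""The five rule-strength metrics from three supports.

compute_metrics takes supp(X u Y), supp(X), supp(Y) and returns support,
confidence, lift, leverage and conviction.  A confidence-1 rule has
infinite conviction (it is never wrong on the data).
"""

from raremine import compute_metrics

print("hand-checkable case: supp(XY)=0.20, supp(X)=0.25, supp(Y)=0.50")
m = compute_metrics(0.2, 0.25, 0.5)
print(f"  confidence={m.confidence:.2f} lift={m.lift:.2f} "
      f"leverage={m.leverage:.3f} conviction={m.conviction:.2f}")
print("  (confidence 0.80 sits exactly on the strong-rule boundary and")
print("   would be rejected: the filter requires strictly more than 0.80)")

print("\nindependent antecedent and consequent: supp(XY) = supp(X)*supp(Y)")
m = compute_metrics(0.3 * 0.4, 0.3, 0.4)
print(f"  lift={m.lift:.2f} leverage={m.leverage:.3f} conviction={m.conviction:.2f}"
      "   (all neutral)")

print("\nperfect rule: every X-transaction contains Y")
m = compute_metrics(0.004, 0.004, 0.53)
print(f"  confidence={m.confidence:.2f} conviction={m.conviction}")
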