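"""Screening statistics for a published-style validation table.

Builds the 146-patient cross-tabulation of tool output against self-reported
service status (111/1/23/11) and computes every statistic the evaluation
layer offers, under both class conventions.
"""

from msit import ConfusionMatrix, format_table, validation_report

m = ConfusionMatrix(a=111, b=1, c=23, d=11)
print(format_table(m), "\n")

study = validation_report(m, convention="study")
std = validation_report(m, convention="veteran_positive")

print(f"agreement:           {study.agreement:.4f} "
      f"({m.a + m.d}/{m.n} = {100 * study.agreement:.1f}%)")
print(f"sensitivity (study convention, non-veteran detection): "
      f"{study.sensitivity:.4f} -> 0.83 at 2 dp")
print(f"specificity (study convention, veteran recovery):      "
      f"{study.specificity:.4f} -> 0.92 at 2 dp")
print(f"sensitivity (veteran-positive convention): {std.sensitivity:.4f}")
print(f"specificity (veteran-positive convention): {std.specificity:.4f}")
print(f"PPV (veteran): {study.ppv_veteran:.4f}   NPV (veteran): {study.npv_veteran:.4f}")
print(f"Youden J: {study.youden_j:.4f}  (= sens + spec - 1; distinct from agreement)")

# The two conventions simply swap sensitivity and specificity; the Youden
# index is the same under both. Note that agreement (a+d)/n and J answer
# different questions and must never be conflated.
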