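"""Subgroup meta-analysis by liver-disease etiology.

Each etiology (HCC, cirrhosis, chronic hepatitis B/C, ...) is pooled
independently with its own heterogeneity estimate and model choice, which
can expose associations the pooled analysis dilutes — here the codon 10
variant's association with chronic hepatitis B.
"""

from snpmeta import Contrast, load_fixture, subgroup_analysis
from snpmeta.reporting import fmt_het, fmt_or_ci, fmt_p

report = subgroup_analysis(
    load_fixture("tgfb1_codon10"), Contrast.HOMOZYGOTE, by="disease"
)

print("codon 10, homozygote contrast (Pro/Pro vs Leu/Leu)\n")
print(f"{'subgroup':10s} {'k':>2s} {'OR (95% CI)':22s} {'P':>8s} {'I2%':>4s} {'P_het':>6s} model")
rows = [("Overall", report.overall)] + list(report.groups.items())
for label, r in rows:
    i2, p_het = fmt_het(r)
    model = "-" if r.single_study else r.model
    print(f"{label:10s} {r.k:>2d} {fmt_or_ci(r):22s} {fmt_p(r.p):>8s} {i2:>4s} {p_het:>6s} {model}")

print(
    "\nThe CHB subgroup's OR (2.33) is far above the overall 1.28: the"
    "\nProline homozygote's disease association concentrates in chronic"
    "\nhepatitis B. Single-study subgroups print '-' for heterogeneity."
)
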