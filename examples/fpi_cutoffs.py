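"""Derive a log2-ratio cutoff from a false-positive list at a target FPI.

Uses a transparent constructed example — 100 distinct false-positive
ratios 0.01 … 1.00 — so the order-statistic behaviour is visible: at a
target FPI of 0.03 exactly 3 of the 100 false positives may exceed the
cutoff, which lands on the 97th smallest ratio.
"""

from turboprox import (
    CompartmentList,
    EnrichmentTable,
    cutoff_at_fpi,
    fpi_curve,
)

values = {f"FP{i:03d}": 0.01 * i for i in range(1, 101)}
table = EnrichmentTable(axis="vs_no_ligase", replicate="rep1", values=values)
fp_list = CompartmentList(name="ER_membrane", accessions=frozenset(values))

curve = fpi_curve(table, fp_list)
for target in (0.03, 0.05, 0.10):
    result = cutoff_at_fpi(curve, target)
    print(
        f"target FPI {target:.2f}: log2 cutoff {result.cutoff:.2f} "
        f"({result.n_fp_above} of {curve.n_fp_observed} FP above, "
        f"achieved FPI {result.achieved_fpi:.2f})"
    )
# The cutoff is always an observed false-positive ratio, and the achieved
# FPI can never exceed the target — that inequality is the filter's
# defining guarantee.
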