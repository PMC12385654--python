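"""Build a space-filling storage-experiment design.

Generates a plain Latin hypercube and an MOEA-optimized one for the three
storage factors (temperature, time, initial maturity), then compares their
uniformity.  A larger minimum pairwise distance and a smaller centered L2
discrepancy both mean the 40 runs cover the factor space more evenly, which
is what makes the downstream surrogate models identifiable.
"""

import wolfberry as wb

n = wb.required_sample_size(3)
print(f"sample-size rule: 2(N+1)(N+2) = {n} runs for N = 3 factors")

plain = wb.random_lhs(n, 3, seed=0)
optimized = wb.optimize_design(n, 3, wb.MOEAConfig(population_size=20, generations=30, seed=0))

for label, design in (("plain LHS", plain), ("optimized LHS", optimized)):
    rep = wb.uniformity_report(design)
    print(
        f"{label:>14}: maximin distance {rep.min_pairwise_distance:.4f}, "
        f"centered-L2 discrepancy {rep.centered_l2_discrepancy:.5f}"
    )

space = wb.wolfberry_space()
first = optimized.denormalize(space)[0]
print(
    "first optimized run in physical units: "
    f"{first[0]:.1f} degC, {first[1]:.1f} d, {first[2]:.0f} % maturity"
)
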