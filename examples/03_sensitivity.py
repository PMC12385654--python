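"""Decompose the reference response surfaces into factor sensitivities.

Prints the signed contribution share of every quadratic term for each
quality response, plus the ends of the temperature main-effect curves.  A
large share means the term moves that response strongly over the studied
ranges; the sign is the direction of the correlation (x1 = temperature,
x2 = storage time, x3 = initial maturity, all normalized to [0, 1]).
"""

import wolfberry as wb
from wolfberry.surrogates import rsm_evaluate_batch

rsm = wb.reference_rsm()
table = wb.term_contributions(rsm)

for resp in rsm.response_names:
    top = sorted(table.for_response(resp), key=lambda e: -e[1])[:3]
    pretty = ", ".join(f"{t} {s * p:+.1f}%" for t, p, s in top)
    print(f"{resp:>9}: {pretty}")

curves = wb.main_effects(lambda X: rsm_evaluate_batch(rsm, X), d=3, n_levels=5)
temp = curves[0]
hardness = temp.mean_response[:, 0]
print(
    "\nhardness main effect of temperature: "
    f"{hardness[0]:.0f} g at the cold end -> {hardness[-1]:.0f} g at the warm end "
    "(averaged over time and maturity)"
)
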