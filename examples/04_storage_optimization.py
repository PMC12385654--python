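"""Optimize storage conditions with SMPSO for several fixed storage times.

Uses the reference quadratic surfaces as the quality predictor, maximizes
hardness, SSC, TA and Vc simultaneously (swarm of 12, 50 generations) and
prints the compromise optimum for 3-, 10- and 24-day storage.  The selected
point is the archive member closest to the ideal point after min-max
normalization; hardness is on the gram scale of the reference surface.
"""

import numpy as np

import wolfberry as wb
from wolfberry.surrogates import rsm_evaluate

rsm = wb.reference_rsm()
problem = wb.MOOProblem(evaluate=lambda x: rsm_evaluate(rsm, x))

archive = wb.run_smpso(problem, wb.SMPSOConfig(seed=0))
print(f"unconstrained run: archive of {archive.size} non-dominated storage conditions")

for days in (3.0, 10.0, 24.0):
    conditions, predicted = wb.scenario_query(problem, days, wb.SMPSOConfig(seed=0))
    hardness, ssc, ta, vc = np.round(predicted, 2)
    print(
        f"{days:4.0f} d: {conditions['temperature']:5.1f} degC, "
        f"maturity {conditions['maturity']:4.1f} % -> hardness {hardness} g, "
        f"SSC {ssc} %, TA {ta} %, Vc {vc} mg/100 g"
    )
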