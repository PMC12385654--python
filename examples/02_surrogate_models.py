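"""Train the three surrogate families on the packaged 40-run dataset.

Splits the 40 experimental runs 80/20, trains the RBF network (width by
leave-one-out cross-validation), the Elman recurrent network and the
quadratic response surface, and prints held-out R² and RMSE per response.
R² near 1 would mean the model explains the held-out variation; values near
or below 0 mean the printed measurements are dominated by run-to-run noise
the factors cannot explain.
"""

import wolfberry as wb
from wolfberry.surrogates import (
    TrainProtocol,
    elman_predict,
    elman_train,
    evaluate_model,
    fit_quadratic_rsm,
    rbf_train,
    rsm_evaluate_batch,
    train_test_split,
)

ds = wb.load_table2()
protocol = TrainProtocol(split_seed=0, init_seed=0)
tr, te = train_test_split(ds.n, protocol.train_fraction, protocol.split_seed)
print(f"training on {len(tr)} runs, evaluating on {len(te)} held-out runs")

rbf = rbf_train(ds.X[tr], ds.Y[tr], protocol, ds.response_names)
print(f"RBF width selected by cross-validation: {rbf.width}")
elman = elman_train(ds.X[tr], ds.Y[tr], protocol, ds.response_names)
print(f"Elman stopped after {elman.history['epochs']} epochs ({elman.history['stop_reason']})")
rsm = fit_quadratic_rsm(ds.X[tr], ds.Y[tr], ds.response_names)

predictors = {
    "rbf": rbf.predict,
    "elman": lambda X: elman_predict(elman, X),
    "rsm": lambda X: rsm_evaluate_batch(rsm, X),
}
print(f"\n{'model':>6} {'response':>9} {'R2':>8} {'RMSE':>8}")
for name, predict in predictors.items():
    metrics = evaluate_model(predict, ds.X[te], ds.Y[te], ds.response_names)
    for resp, fm in metrics.items():
        print(f"{name:>6} {resp:>9} {fm.r2:8.3f} {fm.rmse:8.3f}")
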