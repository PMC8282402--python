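"""Per-segment error metrics and the grouped Ave/Std comparison table.

Generates apnea-like and normal-like surrogate segments, fits plain
ARIMA and the composite ARIMA-EGARCH to each, and aggregates
MSE/RMSE/MAE/MAPE by model and label - the layout of the published
model-comparison tables.
"""

import pandas as pd

import ecgvol as ev
from ecgvol.arima import ArimaOrders
from ecgvol.garch import VolatilityOrders

ao, vo = ArimaOrders(2, 1, 1), VolatilityOrders("EGARCH", 1, 1)
rows = []
for regime, seed in [("apnea_like", 1), ("normal_like", 2)]:
    segments, _ = ev.make_ecg_like(ev.ScenarioSpec(regime=regime, n_segments=4,
                                                   segment_length=3000, seed=seed))
    for seg in segments:
        arima = ev.fit_arima(seg.samples, ao)
        comp = ev.fit_composite(seg.samples, ao, vo, mode="joint")
        for model, fitted in [("ARIMA", ev.arima_fitted(arima, seg.samples)),
                              ("ARIMA-EGARCH", comp.fitted)]:
            m = ev.error_metrics(seg.samples, fitted)
            rows.append({"model": model, "label": seg.label,
                         "record_id": seg.record_id, "index": seg.index,
                         **{k: m[k] for k in ("MSE", "RMSE", "MAE", "MAPE")}})

table = ev.aggregate_metrics(pd.DataFrame(rows))
with pd.option_context("display.width", 120):
    print(table[["model", "label", "n_segments", "MSE_ave", "MSE_std",
                 "RMSE_ave", "MAE_ave", "MAPE_ave"]].round(5).to_string(index=False))

print("\nEach row is the mean +/- spread over segments of one label; RMSE and")
print("MAE are in signal units (mV), MAPE in percent over nonzero samples.")
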