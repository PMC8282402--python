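"""The composite ARIMA-EGARCH fit on a segment with known ground truth.

Simulates an ARMA(1,1) mean with EGARCH(1,1) innovations, fits the
composite model in both two-stage and joint mode, and compares the
recovered coefficients with the generating values.
"""

import ecgvol as ev
from ecgvol.arima import ArimaOrders
from ecgvol.garch import VolatilityOrders

mean_truth = {"ar": [0.6], "ma": [0.3], "d": 0}
vol_truth = {"alpha0": -0.01, "theta": [-0.1], "lam": [0.2], "beta": [0.9]}
sim = ev.simulate_composite(mean_truth, vol_truth, 6000, seed=11)

ao, vo = ArimaOrders(1, 0, 1), VolatilityOrders("EGARCH", 1, 1)
for mode in ("two-stage", "joint"):
    fit = ev.fit_composite(sim["x"], ao, vo, mode=mode)
    d = fit.volatility.params.to_dict(vo)
    print(f"{mode:>9}:  ar={fit.arima.ar_coeffs[0]:+.3f} (truth +0.600)  "
          f"ma={fit.arima.ma_coeffs[0]:+.3f} (truth +0.300)")
    print(f"{'':>9}   theta={d['theta'][0]:+.3f} (truth -0.100)  "
          f"lam={d['lam'][0]:+.3f} (truth +0.200)  "
          f"beta={d['beta'][0]:+.3f} (truth +0.900)")
    print(f"{'':>9}   joint loglik = {fit.joint_loglik:.2f}\n")

print("Joint mode re-estimates the mean coefficients weighting each")
print("innovation by its conditional variance; its likelihood can only")
print("improve on the two-stage start, and on held-out data the weighted")
print("mean estimates predict slightly better.")
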