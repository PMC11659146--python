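"""Survival-input provenance: the pseudo-IPD loop on synthetic data.

Simulates a trial arm from known log-logistic truth, produces the artifacts
figure digitization would yield (step coordinates + numbers at risk),
reconstructs hypothetical individual patient data from them, refits the six
candidate families by censored maximum likelihood, and selects by AIC —
closing the loop back to the generating parameters.
"""

from hcc_cea import SurvivalParams
from hcc_cea.ipd import pipeline

truth = SurvivalParams(gamma=1.516, lam=0.008)  # combination-arm OS curve
res = pipeline(truth, n=500, censor_time=36.0, seed=11)

km = res["km"]
print(f"simulated n={res['ipd'].n}, events={res['ipd'].n_events}, "
      f"KM steps={len(km.times)}")
print(f"reconstructed n={res['reconstructed'].n}, "
      f"events={res['reconstructed'].n_events}\n")

print(res["report"].table().to_string(index=False))
fit = res["fits"]["loglogistic"]
print(f"\nselected family: {res['report'].selected}")
print(f"truth  gamma={truth.gamma:.3f}  lam={truth.lam:.4f}  "
      f"median={truth.median():.1f} mo")
print(f"fit    gamma={fit.params[0]:.3f}  lam={fit.params[1]:.4f}  "
      f"median={fit.params[1] ** (-1 / fit.params[0]):.1f} mo")
# At n=500 with 36-month censoring the shape and median are recovered well;
# the raw scale lam is noisier because it is a power of the median.
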