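"""The transfer SVM on a problem small enough to solve by hand.

Two points x = ±(1, 0) with labels ±1, and a source classifier
w_s = (2, 0). Primal stationarity with the margin active at w = 1 gives
beta = (1 - 2*mu)/2, so the dual solution is known exactly; the script
also sweeps mu to show the fitted weights shrinking toward the source.
"""

import logging

import numpy as np

from sleeptransfer import LabeledDataset, SourceModel, TsvmConfig, fit_tsvm, solve_dual

# large mu drives every multiplier to a box bound on this tiny problem, so
# the midpoint-bias fallback (normally worth a warning) is expected here
logging.getLogger("sleeptransfer.tsvm").setLevel(logging.ERROR)

data = LabeledDataset(X=np.array([[1.0, 0.0], [-1.0, 0.0]]), y=np.array([1.0, -1.0]))
source = SourceModel(w_s=np.array([2.0, 0.0]))

cfg = TsvmConfig(C_t=10.0, mu=0.25)
sol = solve_dual(data, source, cfg)
model = fit_tsvm(data, source, cfg)
print(f"mu=0.25: beta = {np.round(sol.beta, 6)}  (closed form (1-2mu)/2 = 0.25)")
print(f"         w_t  = {np.round(model.w_t, 6)}, b_t = {model.b_t:.6f}")
print(f"         dual objective = {sol.objective:.6f} (primal optimum is its negation)")

print("\nshrinkage toward the source as mu grows:")
for mu in (0.0, 0.5, 2.0, 10.0, 100.0):
    m = fit_tsvm(data, source, TsvmConfig(C_t=10.0, mu=mu))
    print(f"  mu={mu:6.1f}  w_t = {np.round(m.w_t, 4)}  ||w_t - w_s|| = "
          f"{np.linalg.norm(m.w_t - source.w_s):.4f}")

# At mu=0 the fit is the classic SVM (w_t = (1,0), the maximum-margin
# separator); as mu grows the transfer penalty dominates and w_t
# approaches w_s = (2,0).
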