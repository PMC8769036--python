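"""Error budget: what each wrong model parameter costs in flow accuracy.

Three closed-form sweeps on the density/flow model: the FiO2 value assumed
for density, the omission of airway pressure from the absolute pressure,
and one-at-a-time fractional perturbations of every model parameter.
"""
import numpy as np

import dlitespiro as ds

# 1) fixed assumed FiO2 while the true FiO2 sweeps 21-100%
for assumed in (21.0, 60.0, 100.0):
    curve = ds.fio2_assumption_error(assumed)
    print(f"assume FiO2={assumed:5.1f}%: max flow error {curve.max_abs_error_percent:4.2f}%")
# assuming 60% keeps the error under 3% anywhere; assuming air only
# (or pure O2) exceeds 5% at the far end of the range.

# 2) omitting airway pressure from the density's absolute pressure
grid = np.array([5.0, 15.0, 30.0]) * 98.0665  # cmH2O in Pa
curve = ds.pressure_omission_error(81800.0, grid)
for paw, err in zip(grid, curve.flow_error_percent):
    print(f"omit {paw:6.0f} Pa airway pressure: flow error {err:4.2f}%")

# 3) +/-1% in each parameter, exact re-evaluation of the full model
for c in ds.parameter_sensitivity(np.array([-0.01, 0.01])):
    print(f"{c.parameter:12s}: -1% -> {c.flow_error_percent[0]:+6.3f}%   +1% -> {c.flow_error_percent[1]:+6.3f}%")
# Cd and Ac enter linearly (1% in, 1% out); dP and the pressure/temperature
# family enter through a square root (about 0.5% per 1%).
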