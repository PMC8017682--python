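"""Closed-form theory on a single substrate-consumer pair.

Computes the subsistence concentration C* (the minimum concentration to
which a population can deplete its resource) and the recalcitrance
indicator Q for a specialist, then shows the priming effect: realised
uptake of a second pool raises Q for the first.
"""

import numpy as np

from omaccum import recalcitrance_indicator, subsistence_concentration
from omaccum.consumption_matrix import ConsumptionMatrix
from omaccum.parameters import ParameterSet

# a viable specialist: P y rho_max = 0.5*0.3*10 = 1.5 > L = 1
k, P, y, rho_max, L = 0.1, 0.5, 0.3, 10.0, 1.0
c_star = subsistence_concentration(k, P, y, rho_max, L)
print(f"specialist: C* = {c_star:.4f} uM  (k={k}, P={P}, y={y}, "
      f"rho_max={rho_max}/d, L={L}/d)")
print(f"specialist: Q  = {P * y * rho_max / L:.2f}  (> 1: functionally labile)")

# an unviable interaction: maximum biosynthesis below the loss rate
print(f"unviable:   C* = {subsistence_concentration(k, P, y, 1.0, 1.0)}"
      "  (P y rho_max < L: the pool accumulates)")

# priming: a generalist that also eats a second pool
matrix = ConsumptionMatrix(2, 1, np.array([0, 1]), np.array([0, 0]))
params = ParameterSet(
    supply_potential=np.full(2, 1e-4),
    supply_probability=np.ones(2),
    rho_max=np.array([1.0, 1.0]),
    k=np.array([0.1, 0.1]),
    yield_=np.array([0.1, 0.25]),
    presence=np.array([1.0]),
    mortality_quadratic=np.array([0.5]),
    mortality_linear=np.array([0.005]),
)
for other_uptake in (0.0, 0.8, 2.0):
    q0 = recalcitrance_indicator(
        0, params, matrix, np.array([0.0, other_uptake]), np.array([0.5])
    )
    print(f"generalist, realised uptake of pool 2 = {other_uptake:.1f}/d "
          f"-> Q(pool 1) = {q0:.2f}")
# Q crosses 1 as the subsidy grows: consuming other substrates makes the
# first one functionally labile (the priming effect).
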