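"""Spin the 1-D marine water column to quasi-equilibrium and show the
vertical DOC structure and the depth-dependence of functional recalcitrance.
"""

import numpy as np

from omaccum import ColumnConfig, column_diagnostics, run_to_quasi_equilibrium

config = ColumnConfig()  # 50 levels over 1,000 m, 25 DOC pools
state, report = run_to_quasi_equilibrium(config)
print(f"spin-up: {report['t_years']:.0f} years, converged = {report['converged']}, "
      f"DOC drift over final decade = {report['drift']:.1%}")
print(f"carbon budget residual: {report['carbon_residual']:.1e}")

doc = state.total_doc_profile()
z = np.linspace(10, 990, 50)
for depth in (0, 12, 24, 37, 49):
    print(f"  z = {z[depth]:5.0f} m   total DOC = {doc[depth]:6.1f} uM C")

diag = column_diagnostics(state, config)
lab = diag.pivot(index="pool", columns="depth", values="labile")
surface, bottom = lab.iloc[:, 0], lab.iloc[:, -1]
print(f"labile pools at surface: {int(surface.sum())}/25, "
      f"at 1,000 m: {int(bottom.sum())}/25")
transition = ((~surface) & bottom)
print(f"pools recalcitrant at the surface but labile at depth: "
      f"{int(transition.sum())} (indices {[int(i) for i in np.where(transition)[0]]})")
# Loss rates peak where productivity peaks, so mid-ladder pools accumulate
# at the surface yet are consumed at depth: the vertical DOC gradient is an
# ecological transition, not an intrinsic property of the substrate.
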