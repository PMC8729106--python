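"""Two enzymes cycling each other's product, advanced by closed forms.

A constitutive gene supplies substrate N; enzyme F converts N to M and
enzyme G converts M back to N.  Each element is advanced over every
synchronization interval with the exact solution of its local rate
equation, exchanging catalytic fluxes at interval boundaries.  The steady
state matches the global ODE solution independent of the step size; only
the transient degrades as the step grows.
"""

import numpy as np

from grnsync import SimConfig, run
from grnsync.fixtures import two_enzyme_loop
from grnsync.reference import solve_ode

spec = two_enzyme_loop()
t_end = 40_000.0
ode = solve_ode(spec, t_end, t_eval=np.arange(0.0, t_end + 1, 100.0),
                rtol=1e-10, atol=1e-10)
ode_ss = ode.series("M")[-1]
print(f"global ODE steady state of free M: {ode_ss:.4f} molecules")

for dt in (1.0, 10.0):
    traj = run(spec, SimConfig(dt=dt, t_end=t_end, scenario=1, seed=0,
                               record_every=1))
    free_m = traj.series("M") - traj.series("GM")
    common = np.isin(traj.times, ode.times)
    sub = np.isin(ode.times, traj.times)
    dev = np.max(np.abs(free_m[common] - ode.series("M")[sub])) / np.max(ode.series("M"))
    print(f"dt = {dt:5.1f} s: steady state {free_m[-1]:.4f}  "
          f"(max transient deviation {dev:.2%})")

print("\nBoth step sizes land on the ODE steady state; the larger step only")
print("delays the transient because fluxes are exchanged less often.")
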