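"""Simulate an idling persister population and check it against theory.

An "idling" drug-tolerant population keeps dividing and dying at balanced,
non-zero rates, so its size stays roughly constant while individual cells
turn over. We simulate a two-state landscape (slow- and fast-dividing
persister states with equal per-state division and death) and compare the
stochastic trajectory to the deterministic mean-field expectation.
"""

import numpy as np

from idletrace import LineagePopulation, mean_field_solution, simulate
from idletrace.synthetic import idling_landscape

landscape = idling_landscape(coupled=False)  # both states net-zero growth
init = LineagePopulation({"cloneA": np.array([800, 200]),
                          "cloneB": np.array([400, 100])})
times = [0.0, 48.0, 96.0, 144.0]

traj = simulate(landscape, init, t_max=144.0, record_times=times, seed=17)
expected = mean_field_solution(landscape, init.state_totals(), times)

print("time_h  simulated_total  expected_total")
for t, snap, exp in zip(traj.times, traj.snapshots, expected.sum(axis=0)):
    print(f"{t:6.0f}  {snap.total():15d}  {exp:14.1f}")
print()
print("The stochastic totals fluctuate around the flat mean-field line:")
print("division and death are balanced, so the population idles near its")
print("initial size of", init.total(), "cells while lineages drift.")
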