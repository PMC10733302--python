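"""Evaluate the three membrane/rod interactions at reference separations.

Prints the WCA contact values (energy eps, force 24 eps/sigma at r = sigma),
the FENE bond at half extension, and the active force of a Pe = 75 rod at
k_BT = 0.01 (F_A = Pe k_BT = 0.75 along the rod axis).
"""

import numpy as np

import kinkvesicle as kv

params = kv.SimulationParams()

f, u = kv.wca_pair(np.array([1.0, 0.0]), epsilon=params.epsilon_wca)
print(f"WCA at r = sigma:        U = {u:.3f} eps, |F| = {f[0]:.1f} (repulsive)")
f, u = kv.wca_pair(np.array([2 ** (1 / 6), 0.0]), epsilon=params.epsilon_wca)
print(f"WCA at cutoff 2^1/6:     U = {u:.3f}, |F| = {np.linalg.norm(f):.3f}")

f, u = kv.fene_bond(np.array([1.0, 0.0]), kappa_b=1.0, r0=2.0)
print(f"FENE at r = r0/2:        U = {u:.3f}, |F| = {np.linalg.norm(f):.3f} "
      "(attractive)")

rod = kv.RodSpec(n_disks=3, peclet=75)
fa = kv.active_force(rod, 0.0, params.temperature)
print(f"active force (Pe = 75):  F_A = {fa[0]:.2f} along the rod axis "
      f"-> free speed v_a = {rod.active_speed(params.temperature):.2f} sigma/tau")

b = kv.realized_bond_length(kv.VesicleSpec(), params)
print(f"realized membrane bond:  b = {b:.3f} sigma (WCA push = FENE pull)")
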