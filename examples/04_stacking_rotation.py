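"""Analytic angular velocity of ideal rod stackings at the kink.

For five rods at a pi/3 kink there are three symmetry-distinct stackings
that cause rotation - (5,0), (4,1) and (3,2) rods on the two kink arms -
plus none that are balanced (5 is odd). Each class predicts a vesicle
angular velocity from the momentum-transfer balance
sum |v_perp| |l| = I omega; more asymmetric stackings rotate faster, and
the rotation is linear in the active speed v_a = Pe k_BT / gamma.
"""

import math

import kinkvesicle as kv

params = kv.SimulationParams()
vesicle = kv.VesicleSpec(kink_angle=math.pi / 3)
membrane = kv.build_vesicle(vesicle, params)
dimer = kv.RodSpec(n_disks=2, peclet=75)

print(f"I_vesicle = {kv.moment_of_inertia(membrane):.0f} (unit masses, sigma^2)")
print(f"{'class':>8} {'rotating':>9} {'omega (rad/tau)':>16}")
for seq in kv.enumerate_stackings(5, vesicle.kink_angle):
    pred = kv.predict_omega(seq, membrane, dimer, vesicle, params)
    print(f"{str(seq.partition):>8} {str(seq.rotating):>9} {pred.omega:+16.6f}")

pred1 = kv.predict_omega(kv.StackingSequence.from_partition(5, 0),
                         membrane, dimer, vesicle, params)
pred2 = kv.predict_omega(kv.StackingSequence.from_partition(5, 0),
                         membrane, dimer.with_(peclet=150), vesicle, params)
print(f"\ndoubling Pe doubles omega: {pred2.omega / pred1.omega:.3f}x")
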