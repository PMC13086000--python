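"""The 4PNO response function and its mixture reading.

Builds one item, traces its response curve, and shows how the latent
"knows the item" responsibility reacts to a correct and an incorrect
response at different ability levels.
"""

import numpy as np

from nuts4pno import ItemParameters, expected_z, irf, probability_surface

item = ItemParameters(alpha=[1.5], beta=[0.5], g=[0.15], s=[0.10])
print("item: alpha=1.5, beta=0.5, g=0.15, s=0.10")
print(f"{'theta':>6} {'P(correct)':>11} {'z^E | y=1':>10} {'z^E | y=0':>10}")
for theta in (-2.0, -1.0, 0.0, 1.0, 2.0):
    p_star, p = probability_surface([theta], item)
    z1 = expected_z(1, p_star[0, 0], p[0, 0], 0.15, 0.10)
    z0 = expected_z(0, p_star[0, 0], p[0, 0], 0.15, 0.10)
    print(f"{theta:6.1f} {irf(theta, item)[0]:11.3f} {z1:10.3f} {z0:10.3f}")

print()
print("P(correct) runs from the guessing floor 0.15 up to the slipping")
print("ceiling 0.90; the responsibility z^E is the posterior probability")
print("that the examinee actually knew the item given the response, which")
print("drives the MMNUTS gradients.")
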