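"""Two-step control: exact drivers become the structural stage's targets.

The exact stage guarantees Kalman's condition for the original targets; the
structural stage then finds an even smaller input set that structurally
controls those exact drivers, compounding the reduction in external signals.
"""

import targetctrl as tc

net, targets = tc.feedforward_example()
res = tc.two_step(net, targets, tc.GTCAConfig(seed=1))

print(f"targets                 : {targets.labels}  (|T| = {res.target_count})")
print(f"exact drivers (stage 1) : {res.exact.drivers}  "
      f"ratio |D|/|T| = {res.exact_ratio:.3f}")
print(f"structural (stage 2)    : {res.structural_drivers}  "
      f"ratio = {res.structural_ratio:.3f}")

# Stage 1 needs 4 exact drivers for the 6 targets (ratio 0.667); stage 2
# drives those 4 vertices structurally with only 3 inputs (ratio 0.5).
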