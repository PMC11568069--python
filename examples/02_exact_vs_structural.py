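"""The gap between structural and exact target control.

The three sources {1, 7, 8} of the feed-forward network control the six
targets for almost every choice of edge weights — but not for unit weights,
where two targets receive identical walk patterns and the rank drops to 5.
"""

import targetctrl as tc

net, targets = tc.feedforward_example()
A = tc.state_matrix(net)

unit_rank = tc.control_matrix_rank(A, ["1", "7", "8"], targets)
print(f"unit-weight rank of CM(A, B_{{1,7,8}}, C_T): {unit_rank}  (|T| = {len(targets)})")

frac, max_rank = tc.generic_rank_check(net, ["1", "7", "8"], targets,
                                       trials=100, seed=11)
print(f"random-weight draws reaching full rank     : {100 * frac:.0f}% of 100")
print(f"maximum rank over the draws                : {max_rank}")

# 100% of continuous random-weight draws reach rank 6 while the unit-weight
# rank is 5: {1,7,8} controls the targets structurally (a generic property)
# yet fails Kalman's exact condition on this particular system — the reason
# exact target control needs a fourth driver here.
structural = tc.structural_target_control(net, targets)
exact = tc.run_gtca(net, targets, tc.GTCAConfig(seed=1))
print(f"structural drivers: {structural}  vs  exact drivers: {exact.drivers}")
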