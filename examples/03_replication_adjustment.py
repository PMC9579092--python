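"""Adjust a replicated design for within-participant correlation.

Each participant contributes k response pairs, but participants who differ
systematically in their "A"-answer tendency make those pairs partially
redundant.  The adjustment factor C (a design effect, clamped to [1, k])
converts n*k raw pairs into an effective N and tells you how many
participants you actually need.
"""

from anota import (
    ObserverConfig, simulate_responses, answers_A_per_participant,
    estimate_adjustment, required_participants,
)

# a heterogeneous population: participants differ in criterion placement
cfg = ObserverConfig(n=120, k=6, d_prime_true=1.0, sd_between_criterion=0.6,
                     seed=7)
rm = simulate_responses(cfg)
x = answers_A_per_participant(rm)
adj = estimate_adjustment(x, rm.k)

print(f"n = {adj.n} participants x k = {adj.k} pairs = {adj.n * adj.k} "
      f"response pairs")
print(f"adjustment factor C = {adj.C:.2f} "
      f"(intra-participant correlation ~ {adj.rho:.3f})")
print(f"effective N = {adj.N_effective:.0f}")

N_required = 75  # e.g. the exact-method requirement for OR=5, p_D=.2
n_needed = required_participants(N_required, adj.k, adj.C)
print(f"to reach an effective N of {N_required} you need "
      f"n = {n_needed} participants (vs {required_participants(N_required, adj.k, 1.0)} "
      f"if answers were exchangeable, C = 1)")
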