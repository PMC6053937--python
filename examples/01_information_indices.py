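"""Caller consistency and call reliability for a small synthetic community.

Generates a 12-herbivore / 5-predator community, estimates alarm
propensities from a balanced predator-model experiment, and prints the two
information-content indices for a few receiver-caller pairs.
"""

import alarmnet as an

cfg = an.generate_community(seed=1)
trials = an.simulate_predator_trials(cfg, n_per_combination=9, seed=2)
print(f"{len(trials)} predator-simulation trials "
      f"({cfg.n_herbivores} species x {cfg.n_predators + 1} models x 9)")

I, n = an.estimate_alarm_propensity(trials, species=cfg.species,
                                    predators=cfg.predators)
C = an.estimate_call_profile(I)
L = an.caller_consistency(I, cfg.epsilon, cfg.predator_abundances)
V = an.call_reliability(C, cfg.epsilon)

print("\nCaller consistency L (rows: receivers, cols: callers, head):")
print(L.iloc[:4, :4].round(3))
print("\nCall reliability V (head):")
print(V.iloc[:4, :4].round(3))
print("\nA high L(i, j) means caller j reliably alarms whenever one of "
      "receiver i's predators is around (few false negatives); a high "
      "V(i, j) means a single call from j usually concerns a predator of i "
      "(few false positives).  The non-vocal species has L = 0 and "
      "undefined V:")
silent = [s for s in cfg.species if not cfg.vocal_flags[s]][0]
print(f"  {silent}: L = {L[silent].iloc[0]:.1f}, V = {V[silent].iloc[0]}")
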