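"""n-back behavioral scoring: d' with log-linear correction and the
continuous trial-performance index on the fMRS window grid.

Simulates a 2-Back session (4 blocks x 44 trials, 9 congruent per block),
computes signal-detection sensitivity, scores every trial in [0, 1], and
averages scores within the same sliding windows used for the EIB kinetics.
"""

from eibdyn import behavior, kinetics, synthgen

design = synthgen.SessionDesign.for_condition("2back")
trials = synthgen.simulate_behavior_session(
    design, hit_rate=0.78, fa_rate=0.12, rt_mean_ms=640.0, seed=4)
scored = behavior.score_session(trials)

congruent = scored["type"] == "congruent"
sdt = behavior.dprime_loglinear(
    int((congruent & scored["responded"]).sum()), int(congruent.sum()),
    int((~congruent & scored["responded"]).sum()), int((~congruent).sum()))

grid = kinetics.window_indices(design.n_on_off_pairs)
curve, auc = behavior.windowed_performance_auc(scored, grid.windows,
                                               design.n_on_off_pairs)

print(f"{len(trials)} trials, {int(congruent.sum())} congruent")
print(f"hit rate {sdt.hit_rate:.3f}, FA rate {sdt.fa_rate:.3f}, "
      f"d' = {sdt.dprime:.2f}")
print(f"mean trial score   : {scored['score'].mean():.3f} (hits ~1-RTn, "
      f"CR=1, miss=0, FA<=0.25)")
print(f"windowed curve     : {curve.size} windows (same grid as EIB kinetics)")
print(f"behavioral AUC     : {auc:.3f}")
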