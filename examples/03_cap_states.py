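"""Coactivation-pattern analysis of a simulated BOLD session.

A 5-state latent Markov chain (non-active state + 4 seed-coupled spatial
patterns) emits noisy volumes; frames where the spherical seed's z-scored
signal exceeds 1 are clustered, with k chosen by consensus (1 - PAC), and the
state sequence yields the CAP temporal metrics.
"""

import numpy as np

from eibdyn import capstates, synthgen

K, n_frames, grid = 4, 800, (6, 6, 6)
P = np.zeros((K + 1, K + 1))
P[0, 0] = 0.85
P[0, 1:] = 0.15 / K
for m in range(1, K + 1):
    P[m, m] = 0.6
    P[m, 0] = 0.35
    P[m, [s for s in range(1, K + 1) if s != m]] = 0.05 / (K - 1)

rng = np.random.default_rng(0)
patterns = np.zeros((K + 1,) + grid)
patterns[1:] = rng.normal(0, 2.0, (K,) + grid)
model = synthgen.MarkovStateModel(
    transition_matrix=P, emission_patterns=patterns, emission_noise_sd=0.5,
    seed_coupled=tuple(range(1, K + 1)), seed_boost=4.0, seed=1)
vol, true_states, affine = synthgen.simulate_bold_session(
    model, n_frames, seed_center_mm=(7.5, 7.5, 7.5), seed_radius_mm=9.0)

seed = capstates.SeedSpec((7.5, 7.5, 7.5), radius_mm=9.0)
z = capstates.seed_timecourse(vol, affine, seed)
sel = capstates.select_frames(z, threshold=1.0)
frames = vol[..., sel].reshape(-1, sel.size).T

k, stats = capstates.choose_k_consensus(frames, range(2, 7), n_subsamples=20,
                                        seed=2)
caps, seq = capstates.fit_caps(frames, k, sel, n_frames, grid_shape=grid, seed=3)

print(f"selected {sel.size}/{n_frames} frames with seed z > 1")
print("consensus stability:",
      {kk: round(v, 3) for kk, v in stats.items()}, f"-> k = {k}")
print(f"{'CAP':>4} {'occ %':>7} {'resil':>7} {'in':>7} {'out':>7} {'btw':>7}")
for m in capstates.temporal_metrics(seq):
    print(f"{m.cap:>4} {m.occurrences_pct:7.1f} {m.resilience:7.3f} "
          f"{m.in_degree:7.3f} {m.out_degree:7.3f} {m.betweenness:7.3f}")
# occurrences sum to 100% over all states incl. CAP0; resilience + exits and
# resilience + entries each sum to 1 over states (every transition counted once)
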