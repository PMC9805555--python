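"""Score per-state differences between two groups with planted changes.

Two synthetic 3-sample groups share a consensus except in planted regions
where a segment's state was rewritten to state 3.  The signed differential
matrix D12 = R1 - R2 localizes the change: ranking bins by |D12| for state 3
recovers the planted bins almost perfectly.
"""

import numpy as np

from csrep import (
    GeneratorConfig,
    differential_scores,
    generate_consensus,
    generate_differential_pair,
    region_recovery_auroc,
    summarize_group,
)

seed, S, G, N, state_to = 13, 5, 5000, 3, 3
base = GeneratorConfig(S=S, G=G, N=N, seed=seed)
consensus = generate_consensus(base, seed=np.random.SeedSequence(seed).spawn(3)[0])
regions, i = [], 200
while len(regions) < 4 and i < G - 200:
    s, j = consensus[i], i
    while j < min(i + 40, G) and consensus[j] == s:
        j += 1
    if j - i >= 25 and s != state_to:
        regions.append((i, j, int(s), state_to))
        i = j + 800
    else:
        i += 10

cfg = GeneratorConfig(S=S, G=G, N=N, seed=seed, planted_regions=tuple(regions))
truth = generate_differential_pair(cfg)
r1 = summarize_group(truth.group1, seed=2)
r2 = summarize_group(truth.group2, seed=2)
d = differential_scores(r1, r2)

planted = np.flatnonzero(truth.planted_mask)
print(f"planted {len(regions)} regions ({planted.size} bins) rewriting "
      f"consensus segments to state {state_to} in group 2")
print(f"differential scores bounded: min {d.scores.min():.3f}, max {d.scores.max():.3f}")
print(f"mean D12 for state {state_to} on planted bins: "
      f"{d.scores[planted, state_to - 1].mean():.3f} "
      "(negative: group 2 gained the state)")

a = region_recovery_auroc(np.abs(d.scores[:, state_to - 1]), planted, range(G))
print(f"AUROC of |D12(state {state_to})| for recovering planted bins: {a:.3f}")
print("scores near -1 mark bins where group 2 is near-certainly in the planted "
      "state and group 1 never is.")
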