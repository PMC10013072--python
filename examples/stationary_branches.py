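"""Stationary states of the layer dynamics from the self-consistency equation.

For frozen resource levels (r1, r2) the mean-field layer of coupled active
rotators admits up to three stationary states, found as roots B of the
self-consistency function p(B).  Each root carries an effective
excitability B (units with |I| < B rest, the others drift), the stationary
coherence R = |Z| and the stationary population activity A = r1 - Im Z.
"""

from rotorpool.stationary import find_stationary_states

SIGMA = 5.0

for (r1, r2) in [(0.9, 2.0), (1.1, 2.0), (0.9, 2.25)]:
    branches = find_stationary_states(r1, r2, SIGMA)
    print(f"(r1, r2) = ({r1}, {r2}): {len(branches)} stationary state(s)")
    for b in branches:
        print(f"  {b.label}: B = {b.B:7.4f}   R = {b.R:6.4f}   A = {b.activity:7.4f}")
    print()

print("Three coexisting states inside the wedge between the fold curves;")
print("a single state outside. Larger B means a larger excitable (resting)")
print("fraction: B1 is the coherent, nearly quiescent state.")
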