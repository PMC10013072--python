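"""Switching between the steady and bursting regimes by perturbing lam.

Two protocols act on the resource activity variable: an instantaneous
reset to a (large) value, and a clamp that holds lam fixed for a while
before releasing it.  Both can convert the steady state into bursting and
vice versa.  Runtime: ~3 min.
"""

from rotorpool.model import ModelParams
from rotorpool.slowfast import _initial_state, apply_perturbation

params = ModelParams(N=1000)

cases = [
    ("steady state, reset lam = 20", "steady",
     dict(kind="reset", value=20.0, t_p=2000.0)),
    ("bursting state, clamp lam = -0.5 for 500 t.u.", "oscillatory",
     dict(kind="clamp", value=-0.5, t_p=2000.0, duration=500.0)),
]
for title, initial, protocol in cases:
    state0 = _initial_state(initial, params, "network", 42, 201)
    _, verdict = apply_perturbation(state0, protocol, params,
                                    engine="network", t_end=4000.0)
    print(title)
    print(f"  before: {verdict['label_pre']}   after: {verdict['label_post']}"
          f"   switched: {verdict['switched']}")
    print(f"  lam at perturbation: {verdict['lam_at_perturbation']:+.4f}"
          f" ({verdict['application_phase']} phase)")
print()
print("Activating the resources (reset to lam >> 0 or clamp at lam = 1)")
print("kicks the steady state into bursting; deactivating them (reset to")
print("lam < 0 or clamp below 0) quenches the bursting state.")
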