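# rotorpool

Collective dynamics of a heterogeneous population of excitable units
adaptively coupled to a slow pool of resources: direct simulation, the
Ott–Antonsen mean-field reduction, stationary-state and spectral analysis,
two-parameter bifurcation mapping, and slow-fast experiments (adiabatic
sweeps, perturbation-induced switching).

## The model

N active rotators — the paradigmatic model of type-I (SNIPER) excitability —
are globally coupled and driven by inputs that a two-component resource
variable modulates:

```
phi_k' = I_k − sin(phi_k) + (sigma/N) Σ_j sin(phi_j − phi_k),      I_k = r1 + r2 nu_k,
r'     = eps  f(r − s, lam),        f(u, lam) = u (lam + i omega − |u|²),
lam'   = −eps' (lam − lam0 − gamma A),          A = ⟨phi_k'⟩,
```

with frozen heterogeneity `nu_k ~ N(0,1)`, so the instantaneous inputs
follow `g(I) = N(r1, r2²)`. The resource `r = r1 + i r2` is a slow
Stuart–Landau (Hopf normal form) oscillator around the base level
`s = s1 + i s2`, activated (`lam > 0`, limit cycle) or deactivated
(`lam < 0`, stable focus) by the population's mean phase velocity A. A
single rotator is excitable for `|I| < 1` and spikes for `|I| > 1`.

Because `eps = eps' = 0.05 << 1`, the fast layer can be analyzed at frozen
resources. On the Ott–Antonsen manifold the layer closes in the local order
parameter `z(I, t)`:

```
z' = 1/2 (1 − z²) + i I z + (sigma/2) Z − (sigma/2) conj(Z) z²,      Z = ∫ g(I) z(I) dI,
```

and its stationary states are roots B of a scalar self-consistency function

```
p(B) = B² − 2 sigma p2(B) + (sigma²/B²)(p1(B)² + p2(B)²) − 1,      B e^{i beta} = 1 + sigma Z,
```

where B acts as an effective excitability: units with `|I| < B` rest, the
others drift. Up to three states B1 > B2 > B3 coexist; their stability
follows from a continuous spectrum (always marginal or stable) plus a
discrete spectrum, the roots of `det C(mu) = 0` with
`C(mu) = Id + ∫ g(I) (P(I) − mu)⁻¹ Q(I) dI`.

The headline phenomenon is **collective activity bursting**: with the base
level s placed near the layer's criticality, the feedback loop drives
recurrent alternation between quiescence and collective oscillation,
visible as sign alternation of `lam(t)`. Near criticality the bursting
state coexists with a steady state, and resetting or clamping `lam` can
switch between them.

## Worked example

```python
from rotorpool.stationary import find_stationary_states
from rotorpool.spectrum import classify_stability

for b in find_stationary_states(r1=0.9, r2=2.0, sigma=5.0):
    print(b.label, round(b.B, 4), round(b.R, 4), round(b.activity, 4))
```

prints

```
B1 4.8825 0.8932 0.0551
B2 3.6597 0.8019 0.1876
B3 1.9248 0.5252 0.5836
```

three coexisting stationary states of the layer at `(r1, r2) = (0.9, 2)`:
for each, the effective excitability B, the phase coherence `R = |Z|`, and
the stationary population activity `A = r1 − Im Z`. B1 is the coherent,
nearly quiescent state (`classify_stability` labels it a stable node; B2 an
unstable node and B3 an unstable focus, so only B1 is observed in
simulation). The critical line, where B1 is destroyed and collective
oscillation sets in, passes `r1* ≈ 0.963–0.968` at `r2 = 1.2` — just below
the model's default base level `s1 = 0.97`, which is why the full coupled
system bursts.

The `examples/` directory holds one short script per capability
(`stationary_branches.py`, `spectral_stability.py`, `critical_line.py`,
`collective_bursting.py`, `bistability_sweep.py`, `switching.py`); each
prints the numbers it computes and a line on what they mean.
Configuration-driven runs with echoed configs and text outputs go through
`rotorpool.experiments.run_experiment`.

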