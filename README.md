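# gmaid

Simultaneous **kinetic-parameter estimation** and **regulatory-topology
inference** for biochemical networks modeled with power-law (Generalized
Mass Action, GMA) kinetics.

## The problem

Time series of metabolite concentrations carry information both about the
kinetic parameters of a network *and* about its regulatory structure — which
metabolites activate or inhibit which processes. Most estimation methods fix
the regulatory scheme in advance and only fit parameters. `gmaid` treats the
two questions as one problem: every process rate is a power law

```
v_r = γ_r · Π_j X_j^{f_rj},        Ẋ_i = Σ_r μ_ir v_r
```

so a metabolite's regulatory role in process `r` is entirely encoded in the
sign of its kinetic order `f_rj` (positive = activator/substrate, negative =
inhibitor, zero = no effect). The estimation problem

```
min_{γ, f}  Σ_u Σ_i (X_iu^exp − X_iu^mod)²    s.t. the GMA ODE
```

is transcribed into an algebraic system by **orthogonal collocation on
finite elements** (Radau points by default), and each candidate kinetic
order carries a ternary sign choice encoded with binary indicators through a
big-M disjunction. The mixed-integer problem minimizes the **Akaike
criterion**

```
AIC = k·ln(RSS/k) + 2·(number of nonzero kinetic orders)
```

so extra regulatory interactions must pay for themselves in fit quality.
Ranked alternative topologies are enumerated by re-solving under **integer
cuts** that exclude every previously returned sign assignment — the honest
output of such an analysis is a shortlist of plausible topologies, not a
single answer.

The package ships the classic four-metabolite branched pathway (X1 produced
from a constant precursor under feedback inhibition by X3; X1 consumed via
X2→X3 and via X4, which activates X3 degradation) as a fully in-silico
benchmark, with a noise model that perturbs every sampled point by
multiplicative Gaussian noise.

## Worked example

```python
import numpy as np
from gmaid import (reference_network, generate_experiment, make_mesh,
                   SignAssignment, multistart_fit, identify_topologies)

net, params = reference_network()          # γ = (12, 8, 3, 2, 5, 6), ...

# noise-free experiment, known structure: classical parameter estimation
exp = generate_experiment(noise_sd_fraction=0.0, seed=1)
signs = SignAssignment.from_parameters(net, params)
mesh = make_mesh(0.0, 10.0)
fit = multistart_fit(net, [exp], signs, mesh=mesh, n_starts=10, seed=1)
print(f"rss = {fit.rss:.3g}")
print("gamma =", np.round(fit.params.gamma, 3))

# 0.5%-noise experiment, unknown structure: topology identification
noisy = generate_experiment(noise_sd_fraction=0.005, seed=1)
ranking = identify_topologies(net, [noisy], n_topologies=5, seed=1,
                              leaf_starts=2, node_limit=40)
for e in ranking.entries[:3]:
    print(f"AIC {e.aic:8.1f}  rss {e.fit.rss:.4g}  "
          f"active orders {e.sign_pattern.n_active}")
```

Output:

```
rss = 1.48e-10
gamma = [12. 8. 3. 2. 5. 6.]
AIC   -805.6  rss 0.002573  active orders 11
AIC   -794.5  rss 0.002954  active orders 11
AIC   -788.2  rss 0.003197  active orders 11
```

The noise-free fit recovers the generating parameters essentially exactly.
On noisy data the search returns several distinct topologies with
near-identical residuals — all of them inhibit v1 by X3, the dominant
regulatory signal — illustrating that single noisy time series rarely pin
down a unique regulatory structure. Fitting the three X3(0) ∈ {0.2, 1.2,
2.2} perturbation experiments jointly makes the generating pattern (f13 < 0
together with f54 > 0) appear in the shortlist.

A command-line interface mirrors the library:

```
gmaid generate --noise-sd 0.005 --seed 1 --out run/
gmaid estimate --data run/experiments.csv --starts 10 --seed 1 --out run/
gmaid identify --data run/experiments.csv --topologies 5 --seed 1 --out run/
gmaid profile  --data run/experiments.csv --target f32 \
               --values 0.5,0.55,0.6,0.65,0.7,0.75,0.8,0.85,0.9,0.95,1.0 --out run/
```

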