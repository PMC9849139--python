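# npcassembly

Quantitative modelling of **nuclear pore complex (NPC) assembly** for cell
biologists and modellers working with calibrated live-cell imaging of
nucleoporins (Nups).

After an open mitosis, human cells build NPCs through two concurrent
pathways: a fast **postmitotic** pathway (essentially complete ~15 min after
anaphase onset) that dominates the peripheral "non-core" nuclear envelope,
and a slow **interphase** pathway (~100 min) that dominates the central
"core" region. A microscope sees only the mixture. This package implements
the kinetic theory that unmixes the two processes from dual-region
intensity traces, the downstream assembly-order and stoichiometry analysis,
and a reduced-scale integrative spatiotemporal model that scores and ranks
candidate structural assembly pathways — plus synthetic-data generators so
that every stage runs and is tested without any microscopy data.

## The model

The observed normalized nuclear-envelope intensity of a Nup in the two
regions is a linear mixture of the two assembly curves,

    n(t) = f_n pm(t) + (1 − f_n) ip(t)
    c(t) = f_c pm(t) + (1 − f_c) ip(t),

where each curve is a delayed Hill sigmoid,

    pm(t) = (t − d)^{n_p} / ((t − d)^{n_p} + K_p^{n_p}),  t ≥ d  (else 0),

with median assembly time `K`, Hill exponent `n`, and initiation delay
`d` (0 in the non-core region, `d_c ≥ 0` in the core). Inverting the 2×2
mixture gives the unmixed kinetics,

    ip(t) = (f_n c − f_c n) / (f_n − f_c),
    pm(t) = ((1 − f_c) n − (1 − f_n) c) / (f_n − f_c).

Parameters are estimated by weighted least squares,
`χ² = Σ_j [(N_j − n(t_j))²/σ_N² + (C_j − c(t_j))²/σ_C²]`, summed over all
Nups; the **reduced** model shares `(f_n, f_c, d_c)` globally (4P + 3 free
parameters for P Nups), the **full** model fits per-Nup fractions (6P + 1).
The delay is a discrete grid search (0–6 min), confidence intervals come
from the profile likelihood, and the shared-fraction assumption is tested
by BIC. Assembly timing is summarized by the median `K` and the duration
`ΔT = K (9^{1/n} − 9^{−1/n})` (the central 80% of binding events); an
irreversible sequential-chain theory
(`τ_i = τ_g + Σ 1/k_j`, `θ_i = √(θ_g² + Σ 1/k_j²)`) explains why median
time and duration correlate positively in a sequential pathway.
The structural module scores C8-symmetric bead structures against
copy-number restraints, Gō-like mature contacts, excluded volume, membrane
terms and Gaussian-mixture density correlation, then enumerates and ranks
monotone assembly pathways by Boltzmann posterior share.

## Worked example

```python
from npcassembly import (NupAssemblyModel, SimulationConfig,
                         simulate_region_traces)

traces = simulate_region_traces(SimulationConfig(seed=1))   # 10-Nup panel
res = NupAssemblyModel(traces, mode="reduced").fit(multistart=2, seed=0)
print(res.summary())
```

```
Two-component NPC assembly model
================================================================
mode: reduced    nups: 10    free parameters: 43
chi2: 4771.08    residuals: 4820    R2: 0.9986    BIC: 5135.74
core delay d_c: 2 min (grid 0..6)
shared fractions: f_n = 0.8574, f_c = 0.2943
----------------------------------------------------------------
nup            n_p      K_p     n_i      K_i
Nup107       2.483    1.198   4.002   30.028
Nup153       2.615    1.015   4.922   11.973
...
```

The fit recovers the generating global parameters — a postmitotic fraction
of 0.857 in the non-core and 0.295 in the core region, and the 2-min core
initiation delay — with χ² ≈ the number of residuals (the noise level is
matched) and R² > 0.99. Profile-likelihood intervals and ordering
statistics follow from the result object:

```python
ci = res.profile_ci("f_n")            # -> [0.856, 0.859] at 95%
from npcassembly import order_summary, REFERENCE_AMPLITUDES
table = order_summary(res.kinetics, REFERENCE_AMPLITUDES)
```

The order table reports each Nup's median assembly time, duration and
copies per pore, per pathway — e.g. Nup153 (median ≈ 12 min), then Pom121
(≈ 20 min), then the Y-complex members (≈ 30 min) lead the interphase
pathway, and the median-time/duration correlation is strongly positive for
the postmitotic pathway (Spearman r = 1.00 on this panel), the signature
of a sequential mechanism.

The structural stage runs the same way from a synthetic toy system:

```python
from npcassembly import make_toy_assembly_system, model_toy_system
system = make_toy_assembly_system(seed=3)        # planted ground truth
model = model_toy_system(system)                 # enumerate, score, rank
model.best.share                                 # -> 1.0 (planted pathway)
```

A thin CLI wraps the same functions:
`npcassembly simulate traces --seed 7 --out sim/`,
`npcassembly fit --traces sim/traces.csv --mode reduced --out fit.json`,
`npcassembly order --fit fit.json --out order.csv`, and
`npcassembly pathway --seed 3 --out pathways.json`.

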