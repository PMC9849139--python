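# Methods

## Two-component kinetic model

The package models the nuclear-envelope accumulation of each nucleoporin
(Nup) after anaphase onset as a linear mixture of two assembly processes,
postmitotic (`pm`) and interphase (`ip`), with region-specific mixing
fractions `f_n` (non-core) and `f_c` (core) and a core-region initiation
delay `d_c`. Each process is a delayed Hill sigmoid in time with median
assembly time `K` (min) and Hill exponent `n` (dimensionless
cooperativity). Assumptions:

- the two regions see the *same* underlying pm/ip kinetics, differing only
  in mixing fraction and initiation delay;
- curves are normalized (0 before initiation, → 1 at completion); absolute
  copy numbers enter only downstream (stoichiometry module), keeping the
  kinetic equations dimensionless;
- at `t` equal to the delay the left-limit value 0 is returned, making the
  curve continuous for every `n > 0`.

Unmixing is the exact algebraic inverse of the 2×2 mixture applied per
time point, with no smoothing. One subtlety: when `d_c > 0`, the core
region mixes *delayed* copies of pm/ip, so for `t` inside `(0, d_c)` no
single curve pair satisfies both regional equations simultaneously; the
exact round-trip identity therefore holds for the linear mixing map on a
shared curve pair (and for the full forward model whenever the delays
coincide). Both facts are property-tested.

Hill curves are evaluated in log space, `expit(n (log(t−d) − log K))`, so
large exponents neither overflow nor break monotonicity.

## Estimation

Weighted least squares on standardized residuals over all Nups, both
regions and all time points (the displayed sum, not a per-point mean —
scaling does not change the minimizers). Two parameterizations:

- **reduced**: global `(f_n, f_c, d_c)` + 4 kinetic parameters per Nup
  (`4P + 3` free parameters);
- **full**: per-Nup `(f_n, f_c)` + shared `d_c` (`6P + 1`). With the delay
  fixed, the full model decouples into independent 6-parameter per-Nup
  fits, which the implementation exploits.

Numerical choices:

- `K` and `n` are log-parameterized to enforce positivity; bounds are
  `n ∈ [0.2, 50]`, `K ∈ [0.05, 1000]` min, fractions in `[0, 1]`.
- `d_c` is a discrete grid search (default 0–6 min in 1-min steps) with a
  bounded trust-region least-squares fit nested inside each grid point;
  keeping the delay off the continuous parameter vector keeps the
  objective smooth.
- Starting values are data-driven (crude unmixing at `f_n = 0.8`,
  `f_c = 0.3`, then level-crossing estimates of `K` and `n`); additional
  multistarts (default 8) perturb them with seeded noise, and the best
  converged run wins. Hill objectives are multimodal in `(n, K)`, hence
  the multistart guard. Fits are deterministic given the seed.
- The reduced-mode Jacobian is structurally sparse (each Nup's kinetic
  block touches only its own residuals); `jac_sparsity` turns a 43-column
  finite-difference Jacobian into ~6 function evaluations.
- Per-point standard deviations of zero (noiseless synthetic data) are
  floored at a configurable `sigma_floor` (default 1e-3) for weighting;
  passing `sigma_floor=0` makes zero SDs a hard error instead.
- R² is computed on pooled standardized data across both regions (no
  universal convention exists for weighted multi-trace fits; this one is
  recorded here and used consistently).
- BIC is the Gaussian χ² form, `BIC = χ² + k ln m`, with `m` the total
  residual count. Only the *sign* of ΔBIC between reduced and full models
  is a tested contract; magnitudes depend on the BIC convention.

Profile-likelihood intervals: a parameter is stepped away from its
estimate, all others re-optimized (warm-started), and the interval
endpoints are where the profiled χ² crosses the χ²(1 d.f.) quantile above
the minimum; crossings are located by bracketing + Brent root finding. A
direction that reaches a parameter bound first is flagged one-sided. In
the Gaussian limit this reproduces the Wald interval (tested).

## Timing summaries and sequential-chain theory

The median assembly time is `K`; the assembly duration is the window
holding the central 80% of binding events (bracket fractions fixed at
0.1/0.9), `ΔT = K (9^{1/n} − 9^{−1/n})`. Both are delay-independent by
definition (the delay convention for reported timelines is exposed as the
`include_delay` option of `order_summary`; the default keeps timings
delay-free). Ordering ties are broken lexicographically by Nup label.

The irreversible sequential chain (`dX_0/dt = g − k_1 X_0`, …) links
duration to order: the binding-event density of step `i` has mean
`τ_i = τ_g + Σ_{j≤i} 1/k_j` and SD `θ_i = √(θ_g² + Σ_{j≤i} 1/k_j²)`, both
strictly increasing along the chain for any positive rates and any
finite-mass initiation — the kinetic signature behind a positive
median-time/duration correlation. The ODE system is integrated with LSODA
at rtol 1e-9; initiation is a delta pulse (handled as an initial
condition) or a truncated-Gaussian pulse (whose realized moments are
recomputed from the truncated distribution so the closed forms stay
exact). The correlation statistic is Spearman rank by default (robust to
the nonlinear K–ΔT relation), with Pearson optional.

## Stoichiometry

Linear FCS calibration maps background-subtracted intensity to nM;
concentrations inside the 0.75-µm nuclear-envelope mask convert to surface
density treating the mask width as an effective slab thickness (exposed as
a parameter); dividing by the NPC surface density gives copies per NPC.
The fixation-shrinkage correction interprets the stated volume shrinkage
`s` as an area factor `(1−s)^{2/3}` (the measurement is a volume ratio but
the density is areal); a direct volume mode is available and the choice is
an explicit argument. Negative concentrations after background subtraction
are floored at zero with a warning, never propagated. Compartment pools
use `copies = nM × µm³ × 0.602214`. Subphysiologically expressed Nups take
an externally imposed mature amplitude (e.g. 32 for Nup153, 16 for Pom121)
rather than a measured one.

## Synthetic traces

The generator is the forward model itself: exact mixture curves plus
additive Gaussian noise of constant SD on the normalized mean trace
(`noise_sd`, default 0.01 — 1% of the plateau), with the reported σ equal
to the injected SD so that χ² weighting is calibrated. Real per-cell
noise structure (time-correlated fluctuations, heteroscedastic cell-to-cell
variability, segmentation artefacts) is *not* emulated; `cells_per_nup` is
carried as metadata. Passing tests therefore demonstrate correctness of
the estimation machinery under the stated noise model, not robustness to
microscopy systematics.

The default study conditions are a 10-Nup panel on a 0.5-min grid over
0–120 min with global fractions `f_n = 0.857`, `f_c = 0.295` and
`d_c = 2` min. The per-Nup Hill parameters are a reference panel chosen to
reproduce the qualitative biology: postmitotic assembly complete by
~15 min (Y-complex/Pom121/Nup153 within the first minutes, central ring
by ~3 min, filaments later, Nup358 last), interphase assembly over
~100 min initiated by Nup153 → Pom121 → Y-complex with Tpr and Nup214
recruited *before* the central ring — the inverted central-ring/nuclear-
filament order between the two pathways (e.g. Tpr `K_i` < Nup93 `K_i` but
Tpr `K_p` > Nup93 `K_p`). Mature amplitudes lie in the 16/32/48 copy
classes. Note that slow interphase kinetics have not fully plateaued at
120 min, so plateau-window normalization of generated traces is only
approximately idempotent — the same bias any plateau-normalization scheme
has on slow components.

## Toy structural systems and pathway scoring

Subcomplexes are rigid bead arcs (3–10 beads, radii ~1.5–2 nm) at a fixed
fraction (0.83) of the pore radius, at per-type z heights chosen so that
(a) the mature configuration is overlap-free and outside the membrane
volume, and (b) vertically stacked types provide mature contacts within
the 5-nm Gō cutoff whose distances are preserved as the pore dilates (so
the planted ground truth scores zero on every harmonic term). The nuclear
envelope is a toroid-with-planes surface per time point, using the
measured pore diameters and minor radii of the dilating postmitotic pore;
penetration and surface distances are computed analytically.

Scoring terms (additive; breakdown returned per evaluation): Gaussian
copy-number negative log-likelihood (`0.5 ((c − µ)/σ)²` per type), Gō
harmonic restraints toward mature-contact distances linearly ramped from
0 at the first time point to 1 at the mature time point (the ramp schedule
was an open choice; linear in time-point index is the simplest), harmonic
excluded volume between beads of different copies, harmonic attraction of
ALPS-flagged beads to the membrane surface, harmonic repulsion of bead
centres inside the membrane, and a density term `w (1 − cc)`. Strengths
mirror the published constants converted to nm with the score treated as
an energy at unit temperature; the density weight (default 100) makes a
1% correlation loss comparable to a 1.4-σ copy-number violation.

The density correlation `cc` is the normalized L2 inner product of two
Gaussian mixtures, computed in closed form from pairwise Gaussian overlap
integrals; the forward model uses two components per subcomplex copy
(beads split along the copy's principal axis, covariances broadened by
the bead radii). A voxel-grid evaluator in the test suite pins this
convention (agreement to 1e-3). The copy-number variance source is a
config field (`copy_sd` in toy systems).

Monte Carlo refinement is Metropolis at unit temperature — the published
move set (rotations uniform in ±0.04 rad about a random axis, translations
uniform in ±4 Å) with an acceptance rule the source leaves unspecified —
applied to asymmetric-unit poses and expanded by C8 at scoring time, so
symmetry is exact by construction; the best visited configuration is
returned.

Pathways are sequences of per-time-point structures ending at the mature
pore, valid when every copy persists into its successor (monotone
subcomplex inclusion, checked on instance identity). Enumeration is
exhaustive over candidate sets (cross-checked against an independent
DAG path counter); pathway score is the sum of static scores plus a
uniform per-transition constant (which cancels in ranking); posterior
shares are Boltzmann weights `exp(−(score − min))` normalized over the
enumerated set — the "posterior share" is thus a ranking device, not a
calibrated posterior. The planted-recovery helper scores candidates at
their deterministic reference poses; MC refinement is exercised
separately. With target-density jitter up to ~0.5 nm the planted pathway
is recovered at rank 1 with share > 0.5 across seeds (tested at 20
seeds); larger jitter degrades the density term gap first.

## Problem sizes and limitations

Tests and the acceptance script use 20-replicate studies for parameter
recovery and model selection, a 5-step chain for the moment checks, and
the 3-type/6-time-point toy system for pathway recovery; these sizes give
stable pass/fail behaviour at the stated thresholds. Known limitations:
the noise model is the simplest consistent with the χ² weighting; the
full-scale structural problem (PDB-derived spokes, tomography densities,
10⁶-move samplings) is out of scope and represented only at toy scale;
mmCIF/PDB loading is provided for users with real references but no test
depends on real structures; photobleaching correction, image segmentation
and FCS autocorrelation fitting are upstream of this package's inputs.
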