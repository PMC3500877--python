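# Methods

## Model structure

Each topology is a first-order mass-action network over two-tier genes
(mRNA, protein). For gene g:

    dm_g/dt = s_g + Σ_{activating e into g} a_e·P_src(e)
                  − dm_g·m_g
                  − Σ_{repressing e into g} a_e·P_src(e)·m_g
    dp_g/dt = tl_g·m_g − dp_g·p_g

Activation adds a synthesis term linear in the activator's protein;
repression is second-order mass-action removal (repressor × target
mRNA), which keeps the system polynomial rather than introducing
synthesis division or Hill terms. Hormone stimulation is a step input
D(t) = 0 for t < 0 and 1 afterwards (1 μM dexamethasone at t = 0).
Receptor activation — ligand binding, chaperone release — is collapsed
into a single catalytic first-order conversion:

    dGRa/dt = k_act·D·p_GR − dp_GR·GRa

The inactive pool is not depleted by activation (the step stands in for
the whole binding/translocation cascade, which is out of scope along
with compartments), so measured GR protein is the total p_GR + GRa.
Every regulatory edge leaving GR uses GRa as its source, including GR
autoregulation (present in the sensitive-cell models 1–4, absent in the
resistant-cell models 5–6).

**Catalogue.** 1: GR→cJun→Bim; 2: GR→X→cJun→Bim; 3: GR autoregulation
with Erg carried as a basally expressed, unregulated species (no
GR→Erg edge — the topology isolates the loop); 4: autoregulation plus
crosstalk, default wiring Erg→GR activation and GRa⊣Erg repression;
5: GR→Erg; 6: GR→X→Erg. The model-4 edge signs are configurable
(`build_model(4, erg_to_gr=..., gr_to_erg=...)`): the direction of the
crosstalk is documented experimentally but its signs are not, and the
default is the simplest first-order wiring that simultaneously
attenuates GR induction and pushes Erg mRNA below baseline.

**Baseline convention.** Data are folds of the untreated t = 0 control,
so observable species start at exactly 1. Basal synthesis and
translation are derived, not estimated: tl_g = dp_g, and s_g balances
degradation plus any basally active regulation (edges sourced from
proteins sitting at baseline 1, e.g. cJun→Bim or Erg→GR). This removes
structurally unidentifiable degrees of freedom; its flip side is that
an edge rate exceeding its target's mRNA degradation would demand
negative basal synthesis — such combinations are rejected for
user-supplied parameters and penalised during optimisation. The latent
intermediate X is de novo synthesis: zero basal expression, all
turnover rates fixed at 0.1 h⁻¹ (mid-range of the bounds) because X is
never observed; only the two activation rates through it are free, and
only their product is identifiable (the scale of X is arbitrary).

## Simulation

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8 / atol 1e-10, from
the pre-stimulus steady state; default horizon 24 h (fitting uses the
data's sample times; plotting and trend analysis a dense 0.1 h grid).
Off-grid queries interpolate linearly — adequate on the dense grid, and
the refinement-stability test checks the integrator at shared grid
points, where interpolation cannot contribute error.

## Estimation

All estimated rates are bounded to [0.01, 1] h⁻¹, the range motivated
by the receptor's measured 27–42 h protein half-life
(k = ln(2)/t½ = 0.0165–0.0257 h⁻¹). Fitting is two-stage: stage 1
estimates dm_GR, dp_GR, k_act (and the autoregulation rate where
present) on the GR-only subsystem against GR observables; stage 2
estimates everything else with stage 1 frozen. The optimisation
objective is the same normalized deviation that defines the reported
residual ε = (1/n)Σ((y−Y)/Y)² (denominator = simulated value),
minimised as a residual vector over replicate *means* at the data's
sample times (SDs are carried but fitting is unweighted; no weighting
scheme is part of the procedure). Each stage runs a seeded
Latin-hypercube multi-start (default 24 starts; the studies below use
3–8 — noiseless self-fits converge from few starts, and spot checks at
8 starts reproduce the 3-start verdicts) of scipy's bounded
trust-region-reflective least squares, ties broken by smaller parameter
L2 norm, each start capped at 200 function evaluations. Flat or
single-point series are flagged `non_identifiable` rather than raising.

ε is reported per observable over every experimental data point
(including the zero-residual t = 0 anchor) and candidates are ranked by
the arithmetic mean of ε across observables — a scalar is needed for
ranking, but the per-observable table is always reported because split
verdicts are scientifically meaningful. No information-criterion
penalty is applied by default (the comparison is raw ε despite unequal
parameter counts).

## Trend classification

`classify_trend` fits y = a·t + b and y = a·ln(1+t) + b by least
squares and returns the family with smaller SSE (near-ties go to
linear). ln(1+t) rather than ln(t) keeps the family finite at the t = 0
anchor.

## Synthetic data

The generator reproduces the study design: stimulus at t = 0, sparse
sampling at {0, 2, 10} h (optionally 24, 48), three replicates, values
as folds of each replicate's own control. Noise is multiplicative
lognormal with mean 1 and a given CV (fold changes are positive and
right-skewed); no noise is drawn at t = 0, because the control defines
each replicate's unit — the fold there is identically 1 by
construction, and the CV of replicate values at any other time then
equals the configured CV exactly. Random "true" rates for recovery and
discrimination studies are drawn once-for-all from ranges chosen as
realistic study conditions: mRNA degradation 0.07–0.7 h⁻¹ (half-lives
1–10 h), downstream protein degradation 0.028–0.45 h⁻¹, receptor
degradation 0.0165–0.05 h⁻¹ (long-lived), k_act 0.2–0.9 h⁻¹,
autoregulation 0.02–0.15 h⁻¹ (bounded feedback), activation edges
0.1–0.9 h⁻¹ with basally sourced edges capped at 80% of the target's
mRNA degradation so derived basal synthesis stays positive. Draws whose
trajectories exceed 500-fold on [0, 24] h (runaway autoregulation) or
fail to integrate are rejected and redrawn deterministically.

What the generator does *not* emulate: densitometry saturation and
blotting artefacts, qPCR efficiency bias, replicate-level batch
effects, or any biological feedback outside the modelled network.
Passing recovery/discrimination tests therefore demonstrate that the
pipeline is correct and well-conditioned under its own assumptions, not
that the topologies are identifiable from any particular wet-lab
dataset.

## Known limitations (measured, not hypothetical)

These are findings of the package's own seeded studies
(`grkin.experiments`; the corresponding checks are left failing rather
than weakened):

* **Crosstalk recovery (model 4).** The staged procedure cannot recover
  model 4's rates from its own noiseless data (0/20 trials within 10%).
  Stage 1 fits a GR-only submodel, but model 4's GR dynamics include
  the basally active Erg→GR edge, so stage 1 is systematically biased
  (best-fit ε ~1e-5–1e-2 instead of 0); and the crosstalk activation's
  observable signature is only a_Erg_GR·(p_Erg(t)−1) — second-order
  small and trading off against the derived basal synthesis — making it
  practically non-identifiable. This is a property of the staged design
  itself: more starts cannot repair a frozen, biased stage 1. Joint
  (single-stage) estimation would be the remedy but is outside the
  procedure implemented here.
* **Direct-vs-indirect discrimination from sparse early sampling
  (2 vs 1).** With triplicates at {0, 2, 10} h and CV 0.1, the direct
  model fits indirect-cascade means almost as well (both ε ≈ 0.002);
  the generating topology wins only ~60–80% of datasets. The extra
  cascade delay is barely encoded at these sample times; the other two
  pairs (5 vs 6, 4 vs 3) discriminate at 85–100%.
* **Generative trend labels.** Exactly linear/logarithmic curves are
  classified perfectly, but the expectation that direct targets look
  linear *and* indirect ones logarithmic does not emerge from this
  model class under random interior rates: with a long-lived receptor,
  GRa ramps slowly, so a direct target's trajectory is quasi-linear
  (100% classified linear), while an indirect target's is a *delayed,
  convex* version of the same ramp — which the linear family also fits
  better than the concave ln(1+t) family (0% classified logarithmic).
  Structurally, appending first-order stages to a step input delays and
  convexifies early response; it cannot create concavity. The
  logarithmic signature of indirect targets arises when parameters are
  fitted to saturating experimental curves, not from topology alone —
  so the classifier is useful on fitted or measured trajectories, but
  the direct/indirect label is not a parameter-free invariant.

Other numerical choices: integration failures inside a fit score as
large residuals instead of aborting the start; trajectories are clipped
at tiny negative round-off (< 1e-6) and anything worse raises; SBML
export restricts kinetic-law MathML to products of identifiers, which
is exactly what first-order mass action needs and what the bundled
importer re-reads to floating-point identity.
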