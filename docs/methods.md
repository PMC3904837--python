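# Methods

## Model

`geodiv` implements the two-region geographic state speciation–extinction
model (GeoSSE) with regions "temperate" and "tropical". Lineage states
are TEMPERATE, TROPICAL (endemics), and WIDESPREAD (both biomes). The
seven time-constant parameters, all in events/lineage/Myr:

| parameter | meaning | scenario defaults (out_of_tropics) |
|---|---|---|
| λ_temp, λ_trop | within-biome speciation | 0.20, 0.30 |
| λ_TempTrop | biome-divergence speciation of widespread lineages | 0.05 |
| μ_temp, μ_trop | extinction of endemics = range contraction of widespread lineages | 0.12, 0.05 |
| d_temp, d_trop | range expansion (source-labelled: d_temp = temperate endemic expands into the tropics) | 0.05, 0.13 |

The source-labelled dispersal convention matters: the ratio
d_temp/d_trop reads "how much more often does range expansion run from
the temperate zone into the tropics than the reverse", and its meaning
flips if misread. All reports and the sweep use this convention.

Time is measured in Myr before the present (t = 0 now, increasing into
the past). The time-varying extension makes within-biome speciation
linear in that coordinate, λ(t) = λ₀ + r·t, with extinction, dispersal,
and biome-divergence speciation constant; λ(t) ≥ 0 is enforced as a hard
constraint over the tree's height (violations score −∞, not a clamp).
Because λ is linear, checking the interval endpoints suffices. When the
two speciation rates are constrained equal, their slopes are tied too
(one shared slope), since untied slopes would break the equality at
every t > 0.

## Likelihood

The pruning algorithm propagates, per lineage and state, the probability
density D of the observed subtree and the probability E of leaving no
sampled descendant, backward in time along each branch through six
coupled ODEs (the standard GeoSSE system: linear loss terms, dispersal
coupling into the widespread state, range contraction at μ, nonlinear
λ·D·E re-speciation terms, and biome-divergence terms for widespread
lineages). At a node of age t the daughters combine as

* endemic states: D_i = λ_i(t) · D_i(left) · D_i(right);
* widespread state: ½ Σ over the three speciation modes, symmetrized
  over the left/right daughter assignment (no ½ on endemic states).

Sampling fractions f_state (probability that an extant species of each
state is in the tree) enter the tip conditions: D = f for the observed
state, E = 1 − f for every state.

Numerics: an adaptive Dormand–Prince 5(4) pair per branch (default
rtol 1e-8, atol 1e-10), compiled with numba. D is renormalized on the
fly whenever it decays below 0.1 — the D-subsystem is linear in D, so
mid-branch rescaling is exact — with accumulated log factors added back
at the end; this keeps the absolute-tolerance floor from eroding D's
relative accuracy on long branches. Scaling factors are also applied per
branch after node combination. Halving tolerances moves a 100-tip lnL by
far less than 1e-6 (tested); oracle comparisons in the acceptance suite
evaluate at rtol 1e-10 / atol 1e-12 so integration error sits well below
the comparison scale.

Root treatment (the model literature is conventional here, and both
choices are exposed): root-state weights proportional to the relative
root D values ("likelihood-weighted", FitzJohn-style), equal weights, or
a fixed state; conditioning on survival of both root lineages is ON by
default, dividing by Σ_s w_s · λ_eff,s · (1 − E_s)², where λ_eff is
(λ_temp, λ_trop, λ_temp + λ_trop + λ_TempTrop) per state — a widespread
root can found the two observed daughter lineages through any of its
three speciation modes. These defaults are recorded in run metadata.
The decisive correctness check is simulator↔likelihood coherence: the
forward simulator realizes exactly the events above, and the test suite
verifies (a) reduction to the closed-form constant-rate birth–death
likelihood in the single-region limit, (b) unbiased ML recovery of
generating parameters, and (c) that the likelihood at truth beats
region-swapped parameter vectors.

## Inference

**ML.** Free parameters of a constrained model are optimized on log-rate
scale (slopes linear) with L-BFGS-B, bounds mapping rates to
[1e-10, 50] events/lineage/Myr — the lower bound avoids the zero
boundary; the upper bound is far above plausible macroevolutionary rates
and keeps line searches out of the stiff-ODE regime. Multi-start
(default 5): a character-independent fit anchors the first start, the
rest are multiplicative U(0.5, 2) jitters; the finite-difference step
(1e-6 on log scale) sits above the ODE-integration noise floor. Fits are
deterministic given a seed.

**Model space.** The 16 scenarios cross biome-divergence speciation
(free vs 0) × dispersal (equal vs free) × four λ/μ equality patterns;
the dispersal-constrained half (8 models) is the intended design for
smaller phylogenies, where fitting all seven parameters is not
recommended. Ranking is by AIC (= 2k − 2lnL), ties broken toward fewer
parameters; nested pairs are compared by LRT against χ² with df = Δk.

**MCMC.** Univariate slice sampling (step-out by doubling with Neal's
acceptance test, then shrinkage) over the free parameters, positive
support. Priors are independent exponentials with a shared mean of twice
the character-independent net-diversification estimate (rate = 1/(2r̂);
fallback mean λ̂ when r̂ ≤ 0) — the convention of the R toolchain this
package parallels; since only the prior family and its inputs are fixed
by the study design, the rule is surfaced in output metadata. Step-out
width = prior mean. Defaults: 20,000 steps after a 500-step burnin.
Posterior summaries report per-parameter means and equal-tailed 95%
credibility intervals plus the draw-wise r_trop − r_temp distribution,
flagged significant when the interval excludes 0. Time-varying specs are
not sampled (slopes would need a different prior; the posterior analyses
target time-constant models).

**Dispersal-ratio sweep.** The grid is uniform in u = ρ/(1+ρ) on [0,1]
(default 150 points), symmetric under ρ ↔ 1/ρ, with u = 0 and 1 mapping
to the one-way-dispersal submodels and u = 0.5 (ρ = 1) forced onto the
grid (with an even grid size the exact midpoint is not on the uniform
lattice; the nearest point is replaced). Each grid fit constrains
d_temp = ρ·d_trop with one free dispersal scale, sweeping outward from
ρ = 1 and warm-starting each fit from its neighbor's optimum (the
profile likelihood is continuous in ρ). The reported interval is the
largest contiguous grid range around ρ = 1 where sign(r̂_trop − r̂_temp)
matches the ρ = 1 baseline; failed grid fits are recorded and excluded.

## Synthetic data

The forward simulator draws exact next-event times with per-state
bookkeeping (O(1) per event); time-varying speciation uses thinning
against a per-window rate bound. A run starts from a single stem lineage
at the configured stem age and returns the crown tree of sampled extant
tips: extinct lineages pruned, degree-2 nodes suppressed, per-state
Bernoulli tip thinning for incomplete sampling, ultrametric by
construction. Runs ending in total extinction, or outside a configured
tip-count band, are rejected and redrawn (cap 1,000; the count of
rejected realizations is recorded so conditioning bias can be assessed).
The band rejection is the simple reject-on-size scheme, which slightly
conditions the data on size — a documented bias trade-off accepted for
its simplicity. Stem ages for a target size come from the leading
eigenvalue of the expected-growth generator of the three-state branching
process.

Scenario registry (study conditions; rates in /Myr):

* **out_of_tropics** — tropical cradle + museum + out-of-tropics
  dispersal asymmetry (table above, root TROPICAL). Rates chosen to
  produce a biome balance close to the empirical mammal pattern (roughly
  half tropical, a quarter temperate, a quarter widespread) while
  keeping clear separations (1.5× λ, 2.4× μ, 2.6× d).
* **equal_rates** — biome-independent truth: λ = 0.20, λ_TT = 0,
  μ = 0.08, d = 0.03.
* **temperate_cradle** — high-latitude turnover (Carnivora-like):
  λ_temp = 0.30, λ_trop = 0.15, μ_temp = 0.18, μ_trop = 0.05, root
  TEMPERATE.
* **time_increasing** — speciation increasing toward the present in both
  biomes: λ₀ = (0.18, 0.30), slopes −0.003/Myr in time-before-present
  (negative past-time slope = rates rise through forward time), other
  rates as in out_of_tropics.

What the generator does **not** emulate: rate heterogeneity across
lineages within a biome, non-linear time dependence, fossil sampling,
phylogenetic error (topology/dating noise), and spatial structure within
biomes. Passing recovery tests therefore show the estimators are
correct and calibrated *under the model's own assumptions*, not that the
model is adequate for any particular empirical clade.

## Validation experiments (sizes and thresholds)

Run by the test suite and `scripts/acceptance.py`; sizes are the
experiments' own design, picked for useful precision on one CPU.

* **Birth–death reduction**: 20 random ultrametric trees (10–100 tips,
  pure-birth topologies), single-region GeoSSE vs the closed-form
  constant-rate birth–death likelihood (Nee-style E/Ψ expressions with
  sampling fraction); agreement < 1e-6 in lnL.
* **Pure-death closed form**: E(t) = 1 − e^(−μt) over a (μ, t) grid to
  1e-8.
* **Time-varying degeneracy**: zero slopes reproduce the time-constant
  lnL to 1e-8 on a 100-tip fixture.
* **Simulator moments**: Yule mean tip count vs e^(λT) at 1,000
  replicates; pooled Bernoulli thinning vs its binomial expectation —
  both within 3 Monte-Carlo SE.
* **Parameter recovery**: 50 out_of_tropics replicates at ~500 tips,
  full 7-parameter ML (3 starts). Checks: sign of (λ_trop − λ_temp) and
  of (μ_temp − μ_trop) recovered in ≥ 80% of replicates; per-rate median
  *signed* relative error (a bias measure) within ±30%. The median
  |relative error| of weakly informed rates (λ_TT, d_temp, μ_trop) is
  35–45% at this size — rare events carry little information — which is
  why bias, not spread, is the calibration target.
* **Model selection**: 50 replicates per scenario over the 8-model
  dispersal-constrained space (the design intended for phylogenies of
  this size); equal_rates at ~150 tips (the equal-rates model should
  rank first in most replicates), out_of_tropics at ~300 tips (a model
  with unequal λ or μ should rank first in ≥ 80%). Note the first check
  is intrinsically marginal: the probability that the simplest model
  beats all 7 richer AIC competitors on equal-rates data is ≈ 0.6 per
  replicate for any correct implementation.
* **MCMC sanity**: same-seed chains are identical; posterior mean within
  2 posterior SD of the ML optimum on a ~500-tip fixture (1,000-step
  chain); with a flat likelihood stub the sampler reproduces its
  exponential prior (KS on thinned draws).

## Known limitations

* Two regions only; no ClaSSE/DEC-style separation of cladogenetic and
  anagenetic range evolution; no fossil tips.
* The AIC/LRT machinery uses standard χ² asymptotics; boundary
  parameters (rates at 0) make those conservative.
* Size-band rejection in the simulator and crown-conditioning in the
  likelihood are not an exact conditioning match; the recovery
  experiments bound the practical effect (per-rate bias within a few
  percent at 500 tips).
* The MCMC runs a single chain (stability summarized by the lnL trace);
  no cross-chain convergence diagnostic is computed.
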