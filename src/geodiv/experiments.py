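"""Validation experiments: analytical oracles and simulation studies.

Every function here recomputes a verifiable quantity from scratch by
running the package against an independent reference — a closed-form
birth–death likelihood, an analytical expectation, or the known truth of
the forward simulator.  They back both the acceptance test-suite and
``scripts/acceptance.py``.

Problem sizes (replicate counts, target tip counts, optimizer effort,
chain lengths) are the experiments' own design, chosen to estimate each
check's quantity with useful precision on a single CPU; docs/methods.md
records them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .biomes import SamplingFractions
from .inference import fit_many, fit_ml, run_mcmc
from .likelihood import GeoSSELikelihood
from .model_space import (
    GeoSSEParams,
    ModelSpec,
    TimeVaryingParams,
    character_independent_model,
    enumerate_models,
)
from .simulate import SimConfig, make_dataset, scenario_params, simulate_raw
from .treeio import Biome, BiomeStateTable, Phylogeny, parse_newick

__all__ = [
    "bd_loglik_closed_form",
    "yule_tree_newick",
    "bd_reduction_worst_error",
    "pure_death_worst_error",
    "time_varying_degeneracy_error",
    "yule_moment_check",
    "thinning_check",
    "recovery_experiment",
    "model_selection_experiment",
    "mcmc_checks",
]


# ---------------------------------------------------------------------------
# closed-form constant-rate birth-death oracle
# ---------------------------------------------------------------------------


def bd_loglik_closed_form(
    tree: Phylogeny, lam: float, mu: float, f: float = 1.0
) -> float:
    """Constant-rate birth–death log-likelihood of an ultrametric tree.

    Uses the classical closed forms for a reconstructed tree with
    sampling fraction ``f``:

    ``E(t) = 1 - f r / (f λ + (λ(1-f) - μ) e^{-rt})`` with ``r = λ - μ``,
    and the per-branch density factor
    ``Ψ(t) = e^{-rt} r² / (f λ + (λ(1-f) - μ) e^{-rt})²`` (so the tip
    density is ``f`` and internal nodes contribute a factor ``λ``).

    The root is treated as in the pruning implementation's defaults:
    single-state weighting and conditioning on survival of both root
    lineages, i.e. division by ``λ (1 - E(h))²`` at root height ``h``.
    This is an independent oracle: no ODE integration is involved.
    """
    r = lam - mu

    def E(t):
        ert = np.exp(-r * t)
        return 1.0 - f * r / (f * lam + (lam * (1 - f) - mu) * ert)

    def logPsi(t):
        ert = np.exp(-r * t)
        return -r * t + 2.0 * np.log(r) - 2.0 * np.log(
            f * lam + (lam * (1 - f) - mu) * ert
        )

    n = tree.n_tips
    lnl = n * np.log(f) + (n - 1) * np.log(lam)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            lnl += logPsi(tree.ages[p]) - logPsi(tree.ages[i])
    lnl -= np.log(lam) + 2.0 * np.log(1.0 - E(tree.height))
    return float(lnl)


def yule_tree_newick(n_tips: int, rng: np.random.Generator, rate: float = 1.0) -> str:
    """Random ultrametric tree from a forward pure-birth process, written
    as Newick.  Independent of the package's GeoSSE simulator."""
    # forward simulation: lineage split times
    times = [0.0]
    active = [0]
    children: dict[int, tuple[int, int, float]] = {}
    t = 0.0
    nxt = 1
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = active.pop(int(rng.integers(len(active))))
        children[i] = (nxt, nxt + 1, t)
        active += [nxt, nxt + 1]
        nxt += 2
    t_end = t + rng.exponential(1.0 / (rate * len(active)))
    birth = {0: 0.0}
    for i, (a, b, ts) in children.items():
        birth[a] = birth[b] = ts

    def nwk(i: int) -> str:
        if i in children:
            a, b, ts = children[i]
            bl = ts - birth[i]
            return f"({nwk(a)},{nwk(b)}):{bl:.10f}"
        return f"t{i}:{t_end - birth[i]:.10f}"

    a, b, ts = children[0]
    return f"({nwk(a)},{nwk(b)});"


def bd_reduction_worst_error(
    seed: int, n_trees: int = 20, f: float = 1.0
) -> float:
    """Worst |GeoSSE lnL - closed-form birth-death lnL| over random
    single-region ultrametric trees of 10-100 tips.

    With dispersal and biome-divergence speciation at 0 and all tips in
    one biome, the GeoSSE likelihood must reduce exactly to the
    constant-rate birth-death likelihood.  Evaluated at tightened
    integration tolerances (1e-10 / 1e-12) so truncation error stays well
    below the comparison scale.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(10, 101))
        tree = parse_newick(yule_tree_newick(n, rng), ultrametric_tol=1e-6)
        # rescale to a plausible macroevolutionary height
        lam = rng.uniform(0.1, 0.4)
        mu = rng.uniform(0.0, 0.8) * lam
        states = BiomeStateTable({lab: Biome.TROPICAL for lab in tree.tip_labels})
        params = GeoSSEParams(0.0, lam, 0.0, 0.0, mu, 0.0, 0.0)
        fn = GeoSSELikelihood(
            tree, states, SamplingFractions(1.0, f, 1.0), rtol=1e-10, atol=1e-12
        )
        diff = abs(fn(params) - bd_loglik_closed_form(tree, lam, mu, f))
        worst = max(worst, diff)
    return worst


def pure_death_worst_error() -> float:
    """Worst |E(t) - (1 - e^{-μt})| for the pure-death extinction
    probability over a (μ, t) grid.

    With λ = d = 0 a lineage leaves no descendants iff it dies, so the
    extinction probability has the elementary closed form."""
    from .likelihood import LikelihoodState, propagate_branch

    worst = 0.0
    for mu in (0.05, 0.1, 0.5, 1.0, 2.0):
        for t in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0):
            params = GeoSSEParams(0.0, 0.0, 0.0, mu, mu, 0.0, 0.0)
            state0 = LikelihoodState(E=np.zeros(3), D=np.array([0.0, 1.0, 0.0]))
            out = propagate_branch(params, state0, 0.0, t, rtol=1e-10, atol=1e-12)
            worst = max(worst, abs(out.E[1] - (1.0 - np.exp(-mu * t))))
    return worst


def time_varying_degeneracy_error(seed: int, target_tips: int = 100) -> float:
    """|lnL(time-varying, slopes = 0) - lnL(time-constant)| on a
    simulated fixture; the two parameterizations are the same model."""
    tree, states, _ = make_dataset("out_of_tropics", seed=seed, target_tips=target_tips)
    p = scenario_params("out_of_tropics")
    tv = TimeVaryingParams(
        lambda0_temp=p.lambda_temp, lambda0_trop=p.lambda_trop,
        slope_temp=0.0, slope_trop=0.0, lambda_tt=p.lambda_tt,
        mu_temp=p.mu_temp, mu_trop=p.mu_trop, d_temp=p.d_temp, d_trop=p.d_trop,
    )
    fn = GeoSSELikelihood(tree, states)
    return abs(fn(tv) - fn(p))


def yule_moment_check(seed: int, reps: int = 1000, lam: float = 0.1, T: float = 10.0):
    """Mean extant tip count of the pure-birth simulator vs e^{λT}.

    Returns ``(mean, expected, z)`` where z is the deviation in
    Monte-Carlo standard errors."""
    rng = np.random.default_rng(seed)
    params = GeoSSEParams(0.0, lam, 0.0, 0.0, 0.0, 0.0, 0.0)
    cfg = SimConfig(params=params, max_time=T, root_state=Biome.TROPICAL)
    counts = np.empty(reps)
    for i in range(reps):
        _, extant = simulate_raw(cfg, rng)
        counts[i] = len(extant)
    mean = counts.mean()
    se = counts.std(ddof=1) / np.sqrt(reps)
    expected = float(np.exp(lam * T))
    return float(mean), expected, float((mean - expected) / se)


def thinning_check(seed: int, reps: int = 60, f: float = 0.5):
    """Per-state Bernoulli tip thinning vs the binomial expectation.

    Pools sampled-vs-extant counts over replicate simulations; returns
    ``(p_hat, f, z)`` with z in binomial standard errors."""
    rng = np.random.default_rng(seed)
    params = scenario_params("equal_rates")
    cfg = SimConfig(
        params=params,
        max_time=40.0,
        root_state=Biome.TROPICAL,
        sampling=SamplingFractions(f, f, f),
        min_tips=2,
    )
    tot_extant = 0
    tot_sampled = 0
    for _ in range(reps):
        nodes, extant = simulate_raw(cfg, rng)
        n = len(extant)
        if n == 0:
            continue
        s = int(np.sum(rng.uniform(size=n) < f))
        tot_extant += n
        tot_sampled += s
    p_hat = tot_sampled / tot_extant
    se = np.sqrt(f * (1 - f) / tot_extant)
    return float(p_hat), f, float((p_hat - f) / se)


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------


def recovery_experiment(
    seed: int, n_reps: int = 50, target_tips: int = 500
) -> dict:
    """Parameter recovery under the out-of-the-tropics regime.

    Simulates ``n_reps`` datasets, fits the full seven-parameter model by
    ML, and reports: the fraction of replicates recovering the signs of
    (λ_trop − λ_temp) and (μ_temp − μ_trop), and the per-rate median
    signed relative error (a bias measure; the absolute spread of weakly
    informed rates such as within-widespread parameters is much larger).
    """
    truth = scenario_params("out_of_tropics")
    tv = truth.as_dict()
    names = list(tv)
    rng = np.random.default_rng(seed)
    est = np.empty((n_reps, len(names)))
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        tree, states, _ = make_dataset(
            "out_of_tropics", seed=rep_seed, target_tips=target_tips
        )
        fn = GeoSSELikelihood(tree, states, rtol=1e-7, atol=1e-9)
        fit = fit_ml(
            tree, states, spec=ModelSpec(), starts=3, seed=rep_seed,
            likelihood=fn, maxfun=300,
        )
        d = fit.params.as_dict()
        est[rep] = [d[n] for n in names]
    tvv = np.array([tv[n] for n in names])
    rel = (est - tvv) / tvv
    i = {n: j for j, n in enumerate(names)}
    return {
        "sign_lambda": float(np.mean(est[:, i["lambda_trop"]] > est[:, i["lambda_temp"]])),
        "sign_mu": float(np.mean(est[:, i["mu_temp"]] > est[:, i["mu_trop"]])),
        "median_rel_error": {n: float(np.median(rel[:, i[n]])) for n in names},
        "max_abs_median_rel_error": float(np.max(np.abs(np.median(rel, axis=0)))),
        "n_reps": n_reps,
        "target_tips": target_tips,
    }


def model_selection_experiment(
    scenario: str, seed: int, n_reps: int = 50, target_tips: int = 200
) -> dict:
    """AIC model selection calibration over the dispersal-constrained
    eight-model space (the study's design for phylogenies of this size).

    Returns the fraction of replicates in which the character-independent
    (equal-rates) model ranks first and the fraction in which a model
    with unequal speciation or unequal extinction ranks first.
    """
    specs = enumerate_models(constrain_dispersal=True)
    ci = character_independent_model()
    rng = np.random.default_rng(seed)
    ci_wins = 0
    unequal_wins = 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        tree, states, _ = make_dataset(scenario, seed=rep_seed, target_tips=target_tips)
        fn = GeoSSELikelihood(tree, states, rtol=1e-7, atol=1e-9)
        fits = fit_many(
            tree, states, specs=specs, starts=2, seed=rep_seed,
            likelihood=fn, maxfun=200,
        )
        best = min(fits, key=lambda f: (f.aic, f.k))
        ci_wins += best.model == ci
        unequal_wins += (not best.model.speciation_equal) or (
            not best.model.extinction_equal
        )
    return {
        "scenario": scenario,
        "ci_win_fraction": ci_wins / n_reps,
        "unequal_win_fraction": unequal_wins / n_reps,
        "n_reps": n_reps,
        "target_tips": target_tips,
    }


def mcmc_checks(seed: int, target_tips: int = 500, steps: int = 1000, burnin: int = 200) -> dict:
    """Three MCMC sanity checks.

    * same-seed determinism of a short chain;
    * posterior mean within 2 posterior SD of the ML estimate on a
      simulated fixture (diffuse data-derived priors);
    * prior recovery: with a flat likelihood stub the sampler's marginal
      must reproduce the exponential prior (Kolmogorov–Smirnov distance
      of thinned draws).
    """
    from .inference import PriorSpec, default_priors

    tree, states, _ = make_dataset("out_of_tropics", seed=seed, target_tips=target_tips)
    spec = ModelSpec()
    fn = GeoSSELikelihood(tree, states, rtol=1e-7, atol=1e-9)
    fit = fit_ml(tree, states, spec=spec, starts=3, seed=seed, likelihood=fn, maxfun=300)
    priors = default_priors(tree, states, seed=seed)
    sample = run_mcmc(
        tree, states, spec=spec, priors=priors, steps=steps, burnin=burnin,
        seed=seed, init=spec.pack(fit.params), loglik_fn=lambda p: fn(p),
    )
    ml_vec = spec.pack(fit.params)
    post_mean = sample.draws.mean(axis=0)
    post_sd = sample.draws.std(axis=0, ddof=1)
    z = np.abs(post_mean - ml_vec) / np.maximum(post_sd, 1e-12)
    max_z = float(z.max())

    # determinism: two tiny chains, same seed
    small_tree, small_states, _ = make_dataset("equal_rates", seed=seed, target_tips=60)
    kw = dict(
        spec=character_independent_model(), priors=PriorSpec(rate=10.0),
        steps=60, burnin=10, seed=seed + 1,
    )
    s1 = run_mcmc(small_tree, small_states, **kw)
    s2 = run_mcmc(small_tree, small_states, **kw)
    deterministic = bool(np.array_equal(s1.draws, s2.draws))

    # prior recovery under a flat likelihood
    flat = run_mcmc(
        small_tree, small_states, spec=character_independent_model(),
        priors=PriorSpec(rate=5.0), steps=3000, burnin=200, seed=seed + 2,
        loglik_fn=lambda p: 0.0,
    )
    thinned = flat.draws[::5, 0]
    ks = stats.kstest(thinned, "expon", args=(0.0, 1.0 / 5.0))
    return {
        "max_abs_z_ml_vs_posterior": max_z,
        "deterministic": deterministic,
        "prior_recovery_ks": float(ks.statistic),
        "prior_recovery_ks_pvalue": float(ks.pvalue),
        "n_draws": sample.n_draws,
    }
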