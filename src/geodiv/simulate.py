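"""Forward simulation of the two-biome GeoSSE process.

Generates ultrametric trees plus tip biome states with known parameters —
the synthetic stand-in for a dated supertree and a latitudinal-range
database.  The simulator realizes exactly the events the likelihood
models:

* endemic lineages speciate within their biome (λ), go extinct (μ), or
  expand their range into the other biome (d, becoming widespread);
* widespread lineages speciate within either biome (λ_temp / λ_trop,
  producing one endemic and one widespread daughter), speciate by biome
  divergence (λ_TempTrop, producing the two endemics), or contract their
  range by going locally extinct in one biome (μ of that biome).

Simulation is exact next-event (Gillespie) sampling with per-state
bookkeeping; time-varying speciation rates are handled by thinning
against a per-window rate bound.  Extinct lineages are pruned, degree-2
nodes suppressed, and extant tips are retained by per-state Bernoulli
sampling to mimic incomplete taxon sampling.  Runs that end in total
extinction (or outside the requested tip-count band) are retried up to a
cap — this conditions on survival, matching the likelihood's default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .biomes import SamplingFractions
from .model_space import GeoSSEParams, TimeVaryingParams
from .treeio import Biome, BiomeStateTable, Phylogeny

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate_geosse",
    "simulate_raw",
    "SCENARIOS",
    "scenario_params",
    "scenario_config",
    "make_dataset",
    "make_fixture",
]

# internal state codes (match Biome): 0 temperate endemic, 1 tropical, 2 widespread
_A, _B, _AB = 0, 1, 2


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    ``max_time`` is the stem age in Myr: simulation starts from a single
    lineage at ``max_time`` before present and runs to the present.  If a
    tip-count band is given, realizations whose sampled extant tip count
    falls outside ``[min_tips, max_tips]`` are rejected and redrawn
    (documented size-bias caveat: this is the simple reject-on-size
    scheme, not a generalized sampling approach).
    """

    params: GeoSSEParams | TimeVaryingParams
    max_time: float
    root_state: Biome = Biome.TROPICAL
    sampling: SamplingFractions = field(default_factory=SamplingFractions)
    min_tips: int = 2
    max_tips: int | None = None
    retry_cap: int = 1000

    def __post_init__(self) -> None:
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.min_tips < 1:
            raise ValueError("min_tips must be >= 1")
        if self.max_tips is not None and self.max_tips < self.min_tips:
            raise ValueError("max_tips < min_tips")


def _rate_table(params, t_past: float) -> np.ndarray:
    """Per-lineage event rates at a given time before present.

    Rows = state, columns = (speciate_within_A, speciate_within_B,
    speciate_divergence, extinct/contract_A, extinct/contract_B,
    disperse).  Entries not applicable to a state are 0.
    """
    tv = isinstance(params, TimeVaryingParams)
    lam_t = params.lambda_temp_at(t_past) if tv else params.lambda_temp
    lam_r = params.lambda_trop_at(t_past) if tv else params.lambda_trop
    tbl = np.zeros((3, 6))
    tbl[_A] = (lam_t, 0.0, 0.0, params.mu_temp, 0.0, params.d_temp)
    tbl[_B] = (0.0, lam_r, 0.0, 0.0, params.mu_trop, params.d_trop)
    tbl[_AB] = (lam_t, lam_r, params.lambda_tt, params.mu_temp, params.mu_trop, 0.0)
    return tbl


def simulate_raw(cfg: SimConfig, rng: np.random.Generator):
    """One forward realization, no retries, no tree building.

    Returns ``(nodes, extant)`` where ``nodes`` is a list of
    ``(parent_index, birth_forward_time, end_forward_time)`` records of
    every lineage ever alive and ``extant`` maps lineage index -> final
    state for lineages alive at the present.
    """
    params = cfg.params
    T = cfg.max_time
    tv = isinstance(params, TimeVaryingParams)
    if tv and not params.valid_over(T):
        raise ValueError("time-varying speciation rate negative within max_time")

    parent = [-1]
    birth = [0.0]
    end = [np.nan]
    state_of: dict[int, int] = {}
    # per-state membership lists with O(1) swap-remove
    members: list[list[int]] = [[], [], []]
    pos: dict[int, int] = {}

    def _add(lin: int, s: int) -> None:
        state_of[lin] = s
        pos[lin] = len(members[s])
        members[s].append(lin)

    def _remove(lin: int) -> None:
        s = state_of.pop(lin)
        i = pos.pop(lin)
        last = members[s].pop()
        if last != lin:
            members[s][i] = last
            pos[last] = i

    _add(0, int(cfg.root_state))

    t = 0.0  # forward time, 0 = stem origin, T = present
    while t < T and pos:
        counts = np.array([len(m) for m in members], dtype=float)
        # rate bound over the remaining window (rates linear in past-time)
        tbl_now = _rate_table(params, T - t)
        tbl_end = _rate_table(params, 0.0) if tv else tbl_now
        tbl_bound = np.maximum(tbl_now, tbl_end)
        per_state_bound = tbl_bound.sum(axis=1)
        total_bound = float(counts @ per_state_bound)
        if total_bound <= 0.0:
            break  # no further events possible
        t_next = t + rng.exponential(1.0 / total_bound)
        if t_next >= T:
            break
        t = t_next
        tbl = _rate_table(params, T - t)
        per_state = tbl.sum(axis=1)
        total = float(counts @ per_state)
        if tv and rng.uniform() * total_bound > total:
            continue  # thinning rejection
        # choose state, lineage, event
        probs = counts * per_state / total
        s = int(rng.choice(3, p=probs))
        lin = members[s][int(rng.integers(len(members[s])))]
        ev = int(rng.choice(6, p=tbl[s] / per_state[s]))

        if ev in (0, 1, 2):  # speciation
            if s == _A:
                child_states = (_A, _A)
            elif s == _B:
                child_states = (_B, _B)
            elif ev == 0:
                child_states = (_A, _AB)
            elif ev == 1:
                child_states = (_B, _AB)
            else:
                child_states = (_A, _B)
            end[lin] = t
            _remove(lin)
            for cs in child_states:
                parent.append(lin)
                birth.append(t)
                end.append(np.nan)
                _add(len(parent) - 1, cs)
        elif ev in (3, 4):  # extinction or range contraction
            if s == _AB:
                new_state = _B if ev == 3 else _A
                _remove(lin)
                _add(lin, new_state)
            else:
                end[lin] = t
                _remove(lin)
        else:  # dispersal: endemic -> widespread
            _remove(lin)
            _add(lin, _AB)

    extant = {lin: state_of[lin] for lin in pos}
    for lin in extant:
        end[lin] = T
    nodes = list(zip(parent, birth, end))
    return nodes, extant


def _build_tree(nodes, sampled: dict[int, int]):
    """Assemble the pruned phylogeny of sampled extant tips."""
    taxa = dendropy.TaxonNamespace()
    dnodes = {}
    children: dict[int, list[int]] = {}
    for i, (p, _, _) in enumerate(nodes):
        if p >= 0:
            children.setdefault(p, []).append(i)
    # keep only lineages with sampled descendants
    keep = set()
    for lin in sampled:
        j = lin
        while j >= 0 and j not in keep:
            keep.add(j)
            j = nodes[j][0]
    for i in sorted(keep):
        nd = dendropy.Node()
        p, b, e = nodes[i]
        nd.edge.length = (e - b) if np.isfinite(e) else None
        dnodes[i] = nd
        if p in dnodes:
            dnodes[p].add_child(nd)
    for lin, s in sampled.items():
        dnodes[lin].taxon = taxa.new_taxon(label=f"sp{lin}")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = dnodes[min(keep)]
    tree.suppress_unifurcations()
    # drop the root stem so node depths start at the crown
    tree.seed_node.edge.length = None
    phy = Phylogeny.from_dendropy(tree, ultrametric_tol=1e-6)
    states = BiomeStateTable({f"sp{lin}": Biome(s) for lin, s in sampled.items()})
    return phy, states


def simulate_geosse(
    cfg: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[Phylogeny, BiomeStateTable, dict]:
    """Simulate one dataset: pruned sampled tree, tip states, truth record.

    Retries on total extinction / too-few sampled tips / tip counts
    outside the configured band, up to ``cfg.retry_cap``; the number of
    rejected realizations is reported in the truth record so conditioning
    bias can be assessed.
    """
    rng = np.random.default_rng(seed)
    f = np.array(cfg.sampling.as_tuple())
    attempts = 0
    while attempts <= cfg.retry_cap:
        attempts += 1
        nodes, extant = simulate_raw(cfg, rng)
        if len(extant) < 2:
            continue
        sampled = {
            lin: s for lin, s in extant.items() if rng.uniform() < f[s]
        }
        n = len(sampled)
        if n < max(2, cfg.min_tips):
            continue
        if cfg.max_tips is not None and n > cfg.max_tips:
            continue
        tree, states = _build_tree(nodes, sampled)
        truth = {
            "params": cfg.params.as_dict(),
            "time_varying": isinstance(cfg.params, TimeVaryingParams),
            "root_state": cfg.root_state.name,
            "max_time": cfg.max_time,
            "sampling": dict(
                zip(("f_temp", "f_trop", "f_wide"), cfg.sampling.as_tuple())
            ),
            "n_extant": len(extant),
            "n_sampled": n,
            "rejected_realizations": attempts - 1,
        }
        return tree, states, truth
    raise SimulationError(
        f"no acceptable realization in {cfg.retry_cap} attempts "
        f"(params may imply near-certain extinction or a size band that is "
        f"rarely hit)"
    )


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

#: Named parameter regimes used throughout the test-suite and the
#: acceptance experiments.  Rates in events/lineage/Myr; the values are
#: the generator's study conditions, chosen to be realistic for a
#: mammal-like radiation (net diversification of order 0.05-0.25 /Myr).
SCENARIOS: dict[str, dict] = {
    # tropical cradle + museum + out-of-the-tropics dispersal asymmetry;
    # rates chosen to reproduce a biome balance close to the mammal data
    # (roughly half tropical, a quarter temperate, a quarter widespread)
    "out_of_tropics": {
        "params": GeoSSEParams(
            lambda_temp=0.20, lambda_trop=0.30, lambda_tt=0.05,
            mu_temp=0.12, mu_trop=0.05, d_temp=0.05, d_trop=0.13,
        ),
        "root_state": Biome.TROPICAL,
    },
    # biome-independent diversification (character-independent truth)
    "equal_rates": {
        "params": GeoSSEParams(
            lambda_temp=0.20, lambda_trop=0.20, lambda_tt=0.0,
            mu_temp=0.08, mu_trop=0.08, d_temp=0.03, d_trop=0.03,
        ),
        "root_state": Biome.TROPICAL,
    },
    # high-latitude turnover: both speciation and extinction higher in
    # the temperate biome (Carnivora-like)
    "temperate_cradle": {
        "params": GeoSSEParams(
            lambda_temp=0.30, lambda_trop=0.15, lambda_tt=0.03,
            mu_temp=0.18, mu_trop=0.05, d_temp=0.06, d_trop=0.02,
        ),
        "root_state": Biome.TEMPERATE,
    },
    # speciation rates increasing toward the present in both biomes
    # (negative slope in time-before-present)
    "time_increasing": {
        "params": TimeVaryingParams(
            lambda0_temp=0.18, lambda0_trop=0.30,
            slope_temp=-0.003, slope_trop=-0.003,
            lambda_tt=0.03, mu_temp=0.12, mu_trop=0.04,
            d_temp=0.02, d_trop=0.06,
        ),
        "root_state": Biome.TROPICAL,
    },
}


def scenario_params(name: str) -> GeoSSEParams | TimeVaryingParams:
    try:
        return SCENARIOS[name]["params"]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        ) from None


def _growth_matrix(params, t_past: float) -> np.ndarray:
    """Generator of the expected per-state lineage counts, dn/dt = G n."""
    tv = isinstance(params, TimeVaryingParams)
    lam_t = params.lambda_temp_at(t_past) if tv else params.lambda_temp
    lam_r = params.lambda_trop_at(t_past) if tv else params.lambda_trop
    G = np.zeros((3, 3))
    G[_A, _A] = lam_t - params.mu_temp - params.d_temp
    G[_AB, _A] = params.d_temp
    G[_B, _B] = lam_r - params.mu_trop - params.d_trop
    G[_AB, _B] = params.d_trop
    G[_A, _AB] = lam_t + params.lambda_tt + params.mu_trop
    G[_B, _AB] = lam_r + params.lambda_tt + params.mu_temp
    G[_AB, _AB] = -params.lambda_tt - params.mu_temp - params.mu_trop
    return G.T  # rows = d/dt of state counts


def _time_for_tips(params, target: int) -> float:
    """Stem age at which the expected lineage count reaches ``target``,
    from the leading eigenvalue of the expected-growth generator."""
    need = math.log(max(target, 2))
    t, acc, dt = 0.0, 0.0, 0.5
    while acc < need and t < 2000.0:
        g = float(np.linalg.eigvals(_growth_matrix(params, t)).real.max())
        acc += max(g, 1e-4) * dt
        t += dt
    return t


def scenario_config(
    name: str,
    target_tips: int = 500,
    sampling: SamplingFractions | None = None,
) -> SimConfig:
    """Build the :class:`SimConfig` for a named scenario.

    The stem age is set so the expected extant count matches
    ``target_tips``; accepted realizations must fall within
    [target/2, 2*target] sampled tips.
    """
    sc = SCENARIOS[name]
    params = sc["params"]
    return SimConfig(
        params=params,
        max_time=_time_for_tips(params, target_tips),
        root_state=sc["root_state"],
        sampling=sampling or SamplingFractions(),
        min_tips=max(2, target_tips // 2),
        max_tips=target_tips * 2,
    )


def make_dataset(
    scenario: str,
    seed: int | np.random.Generator | None = None,
    target_tips: int = 500,
    sampling: SamplingFractions | None = None,
):
    """Simulate one named-scenario dataset in memory."""
    cfg = scenario_config(scenario, target_tips, sampling)
    return simulate_geosse(cfg, seed)


def make_fixture(
    scenario: str,
    seed: int,
    out_dir,
    target_tips: int = 500,
    sampling: SamplingFractions | None = None,
) -> dict[str, Path]:
    """Write a named-scenario dataset to disk (Newick + state CSV + truth
    JSON).  Byte-identical for identical arguments."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, states, truth = make_dataset(scenario, seed, target_tips, sampling)
    truth = {"scenario": scenario, "seed": seed, **truth}
    paths = {
        "tree": out / f"{scenario}_{seed}.nwk",
        "states": out / f"{scenario}_{seed}_states.csv",
        "truth": out / f"{scenario}_{seed}_truth.json",
    }
    with open(paths["tree"], "w") as fh:
        fh.write(tree.to_newick() + "\n")
    states.to_csv(paths["states"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
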