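"""GeoSSE log-likelihood of a dated tree plus tip biome states.

Implements the pruning algorithm: per lineage and state the probability
density ``D`` of the observed subtree and the probability ``E`` of leaving
no sampled descendant are propagated down each branch by numerically
integrating six coupled ODEs backward in time (present → past), combined
at nodes by the cladogenetic rules, and assembled at the root.  State-
specific sampling fractions enter the tip initial conditions:
``D = f`` for the observed state and ``E = 1 - f`` for every state.

Root treatment (the literature's convention, configurable): root-state
weights proportional to the relative ``D`` values (FitzJohn weighting),
and conditioning on the survival of both root lineages by dividing by the
state-weighted ``λ_eff (1 - E_root)²`` factor, where the effective
speciation rate of a widespread root is the sum of its three speciation
modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .biomes import SamplingFractions
from .model_space import GeoSSEParams, TimeVaryingParams
from .treeio import Biome, BiomeStateTable, Phylogeny

__all__ = [
    "LikelihoodState",
    "RootOptions",
    "LikelihoodError",
    "tip_init",
    "propagate_branch",
    "combine_at_node",
    "loglik",
    "GeoSSELikelihood",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

_ROOT_MODES = {
    "likelihood-weighted": _core.ROOT_FITZJOHN,
    "equal-weights": _core.ROOT_EQUAL,
    "fixed-state": _core.ROOT_FIXED,
}


class LikelihoodError(RuntimeError):
    """Numerical failure inside the likelihood computation."""


@dataclass
class LikelihoodState:
    """Per-lineage pruning variables at one point in time.

    ``D`` (length 3, state order temperate/tropical/widespread) carries a
    running log-scaling factor ``log_scale`` to prevent underflow:
    the actual density is ``D * exp(log_scale)``.
    """

    E: np.ndarray
    D: np.ndarray
    log_scale: float = 0.0

    def copy(self) -> "LikelihoodState":
        return LikelihoodState(self.E.copy(), self.D.copy(), self.log_scale)


@dataclass(frozen=True)
class RootOptions:
    """How to treat the root: state weighting and survival conditioning."""

    root_mode: str = "likelihood-weighted"
    condition_on_survival: bool = True
    fixed_state: Biome | None = None

    def __post_init__(self) -> None:
        if self.root_mode not in _ROOT_MODES:
            raise ValueError(
                f"root_mode must be one of {sorted(_ROOT_MODES)}, got {self.root_mode!r}"
            )
        if self.root_mode == "fixed-state" and self.fixed_state is None:
            raise ValueError("fixed-state root mode requires fixed_state")


def _core_params(params: GeoSSEParams | TimeVaryingParams) -> np.ndarray:
    return params.to_core()


def tip_init(state: Biome, f: SamplingFractions) -> LikelihoodState:
    """Initial conditions at a sampled tip of the given observed state."""
    fv = np.array(f.as_tuple())
    E = 1.0 - fv
    D = np.zeros(3)
    D[int(state)] = fv[int(state)]
    return LikelihoodState(E=E, D=D)


def propagate_branch(
    params: GeoSSEParams | TimeVaryingParams,
    state0: LikelihoodState,
    t_young: float,
    t_old: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> LikelihoodState:
    """Propagate pruning variables from the young to the old end of a branch."""
    if t_old < t_young or t_young < 0:
        raise ValueError(f"need t_old >= t_young >= 0, got ({t_young}, {t_old})")
    if isinstance(params, TimeVaryingParams) and not params.valid_over(t_old):
        raise ValueError("time-varying speciation rate is negative on the branch")
    y = np.concatenate([state0.E, state0.D]).astype(float)
    status, log_scale = _core.propagate(
        y, float(t_young), float(t_old), _core_params(params), rtol, atol
    )
    if status != _core.OK:
        raise LikelihoodError(f"branch integration failed (status {status})")
    return LikelihoodState(
        E=np.clip(y[:3], 0.0, 1.0), D=y[3:], log_scale=state0.log_scale + log_scale
    )


def combine_at_node(
    params: GeoSSEParams | TimeVaryingParams,
    left: LikelihoodState,
    right: LikelihoodState,
    t_node: float = 0.0,
) -> LikelihoodState:
    """Combine two daughter states at a node of age ``t_node``."""
    y1 = np.concatenate([left.E, left.D])
    y2 = np.concatenate([right.E, right.D])
    out = np.empty(6)
    _core._combine(_core_params(params), float(t_node), y1, y2, out)
    return LikelihoodState(
        E=out[:3], D=out[3:], log_scale=left.log_scale + right.log_scale
    )


class GeoSSELikelihood:
    """Reusable likelihood function bound to one (tree, states, sampling).

    Precomputes the array layout once; calling the object with a parameter
    set returns the log-likelihood.  This is the hot path for ML fitting
    and MCMC.
    """

    def __init__(
        self,
        tree: Phylogeny,
        states: BiomeStateTable,
        sampling: SamplingFractions | None = None,
        root: RootOptions | None = None,
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
    ):
        missing = [lab for lab in tree.tip_labels if lab not in states]
        if missing:
            raise ValueError(
                f"{len(missing)} tips lack state data (e.g. {missing[:3]}); "
                "run match_tree_and_states first"
            )
        self.tree = tree
        self.states = states
        self.sampling = sampling or SamplingFractions()
        self.root = root or RootOptions()
        self.rtol = float(rtol)
        self.atol = float(atol)
        self._children = tree.children
        self._ages = tree.ages
        self._tip_state = np.array(
            [int(states[lab]) for lab in tree.tip_labels], dtype=np.int64
        )
        self._f = np.array(self.sampling.as_tuple())
        self._root_mode = _ROOT_MODES[self.root.root_mode]
        self._fixed = int(self.root.fixed_state) if self.root.fixed_state is not None else 0

    @property
    def height(self) -> float:
        return self.tree.height

    def __call__(
        self, params: GeoSSEParams | TimeVaryingParams, strict: bool = False
    ) -> float:
        """Log-likelihood; invalid parameter regions give ``-inf``.

        With ``strict=True`` a numerical integration failure raises a
        :class:`LikelihoodError` naming the offending node instead of
        returning ``-inf``.
        """
        if isinstance(params, TimeVaryingParams) and not params.valid_over(self.height):
            return -np.inf
        lnl, status, node = _core.tree_loglik(
            self._children,
            self._ages,
            self.tree.n_tips,
            self._tip_state,
            self._f,
            _core_params(params),
            self.rtol,
            self.atol,
            self._root_mode,
            self.root.condition_on_survival,
            self._fixed,
        )
        if status != _core.OK:
            if strict:
                raise LikelihoodError(
                    f"non-finite likelihood at node {node} (status {status})"
                )
            return -np.inf
        return float(lnl)


def loglik(
    tree: Phylogeny,
    states: BiomeStateTable,
    params: GeoSSEParams | TimeVaryingParams,
    sampling: SamplingFractions | None = None,
    root: RootOptions | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    strict: bool = True,
) -> float:
    """One-shot GeoSSE log-likelihood (see :class:`GeoSSELikelihood`)."""
    fn = GeoSSELikelihood(tree, states, sampling, root, rtol, atol)
    return fn(params, strict=strict)
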