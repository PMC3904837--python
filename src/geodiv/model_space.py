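"""GeoSSE parameter vectors and the constrained model space.

The full model has seven rates (events / lineage / Myr):

* ``lambda_temp``, ``lambda_trop`` — within-biome speciation;
* ``lambda_tt`` — speciation by biome divergence (a widespread lineage
  splits into one temperate and one tropical endemic daughter);
* ``mu_temp``, ``mu_trop`` — extinction of endemics, which double as the
  range-contraction rates of widespread lineages;
* ``d_temp``, ``d_trop`` — range expansion.  **Naming convention**
  (source-labelled): ``d_temp`` is the rate at which a *temperate* endemic
  expands into the tropics (becomes widespread), ``d_trop`` the rate at
  which a *tropical* endemic expands into temperate regions.  The ratio
  ``d_temp / d_trop`` therefore measures how much more often range
  expansion proceeds from temperate into tropical regions than the
  reverse; the "out of the tropics" regime has ``d_trop > d_temp``.

Sixteen constrained scenarios are generated by crossing: biome-divergence
speciation allowed vs fixed to 0 (×2), dispersal equal vs free (×2), and
the four λ/μ equality patterns (×4).  A time-varying extension lets
within-biome speciation change linearly with time, λ(t) = λ₀ + r·t with
t measured from the present into the past; extinction and dispersal stay
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeoSSEParams",
    "TimeVaryingParams",
    "ModelSpec",
    "FitResult",
    "enumerate_models",
    "full_model",
    "character_independent_model",
]

_RATE_NAMES = (
    "lambda_temp",
    "lambda_trop",
    "lambda_tt",
    "mu_temp",
    "mu_trop",
    "d_temp",
    "d_trop",
)


@dataclass(frozen=True)
class GeoSSEParams:
    """Time-constant GeoSSE rates, all >= 0, events/lineage/Myr."""

    lambda_temp: float
    lambda_trop: float
    lambda_tt: float
    mu_temp: float
    mu_trop: float
    d_temp: float
    d_trop: float

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def r_temp(self) -> float:
        """Temperate net diversification rate (speciation minus extinction)."""
        return self.lambda_temp - self.mu_temp

    @property
    def r_trop(self) -> float:
        """Tropical net diversification rate."""
        return self.lambda_trop - self.mu_trop

    def to_core(self) -> np.ndarray:
        """Internal 9-vector: 7 rates + two zero speciation slopes."""
        return np.array(
            [
                self.lambda_temp,
                self.lambda_trop,
                self.lambda_tt,
                self.mu_temp,
                self.mu_trop,
                self.d_temp,
                self.d_trop,
                0.0,
                0.0,
            ]
        )

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in _RATE_NAMES}


@dataclass(frozen=True)
class TimeVaryingParams:
    """GeoSSE rates with linearly time-varying within-biome speciation.

    λ_temp(t) = lambda0_temp + slope_temp · t  (t in Myr before present),
    and analogously for the tropics.  λ(t) must stay >= 0 over the tree's
    history; that is validated against a tree height at evaluation time,
    not here.  Extinction, dispersal, and biome-divergence speciation are
    constant.
    """

    lambda0_temp: float
    lambda0_trop: float
    slope_temp: float
    slope_trop: float
    lambda_tt: float
    mu_temp: float
    mu_trop: float
    d_temp: float
    d_trop: float

    def __post_init__(self) -> None:
        for name in ("lambda0_temp", "lambda0_trop", "lambda_tt",
                     "mu_temp", "mu_trop", "d_temp", "d_trop"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("slope_temp", "slope_trop"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def lambda_temp_at(self, t: float) -> float:
        return self.lambda0_temp + self.slope_temp * t

    def lambda_trop_at(self, t: float) -> float:
        return self.lambda0_trop + self.slope_trop * t

    def valid_over(self, height: float) -> bool:
        """True when both λ(t) stay >= 0 on [0, height] (linear ⇒ endpoints)."""
        return (
            min(self.lambda_temp_at(0.0), self.lambda_temp_at(height)) >= 0.0
            and min(self.lambda_trop_at(0.0), self.lambda_trop_at(height)) >= 0.0
        )

    @property
    def r_temp(self) -> float:
        """Net diversification at present."""
        return self.lambda0_temp - self.mu_temp

    @property
    def r_trop(self) -> float:
        return self.lambda0_trop - self.mu_trop

    def to_core(self) -> np.ndarray:
        return np.array(
            [
                self.lambda0_temp,
                self.lambda0_trop,
                self.lambda_tt,
                self.mu_temp,
                self.mu_trop,
                self.d_temp,
                self.d_trop,
                self.slope_temp,
                self.slope_trop,
            ]
        )

    def as_dict(self) -> dict[str, float]:
        return {
            n: getattr(self, n)
            for n in (
                "lambda0_temp", "lambda0_trop", "slope_temp", "slope_trop",
                "lambda_tt", "mu_temp", "mu_trop", "d_temp", "d_trop",
            )
        }


@dataclass(frozen=True)
class ModelSpec:
    """Constraint pattern defining one diversification scenario.

    ``dispersal_ratio`` (used by the robustness sweep) replaces the
    dispersal-equality constraint with a fixed ratio
    ``d_temp = ratio · d_trop`` and a single free dispersal scale; the
    sentinels 0 and ``inf`` denote the one-way-dispersal submodels.
    """

    allow_biome_divergence: bool = True
    speciation_equal: bool = False
    extinction_equal: bool = False
    dispersal_equal: bool = False
    time_varying: bool = False
    dispersal_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.dispersal_ratio is not None:
            if self.dispersal_equal:
                raise ValueError("dispersal_ratio replaces dispersal_equal; set one")
            if self.dispersal_ratio < 0:
                raise ValueError("dispersal_ratio must be >= 0 (inf allowed)")

    # -- free parameter bookkeeping -----------------------------------

    def free_names(self) -> tuple[str, ...]:
        """Ordered names of the free parameters."""
        names: list[str] = []
        if self.speciation_equal:
            names.append("lambda")
        else:
            names += ["lambda_temp", "lambda_trop"]
        if self.allow_biome_divergence:
            names.append("lambda_tt")
        if self.extinction_equal:
            names.append("mu")
        else:
            names += ["mu_temp", "mu_trop"]
        if self.dispersal_ratio is not None:
            names.append("d_scale")
        elif self.dispersal_equal:
            names.append("d")
        else:
            names += ["d_temp", "d_trop"]
        if self.time_varying:
            # a shared slope when speciation rates are tied, else one per biome
            names += ["slope"] if self.speciation_equal else ["slope_temp", "slope_trop"]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names())

    def unpack(self, v: Sequence[float]) -> GeoSSEParams | TimeVaryingParams:
        """Expand a free-parameter vector into a full parameter set."""
        names = self.free_names()
        v = np.asarray(v, dtype=float)
        if v.shape != (len(names),):
            raise ValueError(f"expected {len(names)} free parameters, got {v.shape}")
        d = dict(zip(names, v))
        for name, val in d.items():
            if not name.startswith("slope") and val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")

        lam_t = d["lambda"] if self.speciation_equal else d["lambda_temp"]
        lam_r = d["lambda"] if self.speciation_equal else d["lambda_trop"]
        lam_tt = d.get("lambda_tt", 0.0)
        mu_t = d["mu"] if self.extinction_equal else d["mu_temp"]
        mu_r = d["mu"] if self.extinction_equal else d["mu_trop"]
        if self.dispersal_ratio is not None:
            rho = self.dispersal_ratio
            if np.isinf(rho):
                d_t, d_r = d["d_scale"], 0.0
            else:
                d_t, d_r = rho * d["d_scale"], d["d_scale"]
        elif self.dispersal_equal:
            d_t = d_r = d["d"]
        else:
            d_t, d_r = d["d_temp"], d["d_trop"]

        if not self.time_varying:
            return GeoSSEParams(lam_t, lam_r, lam_tt, mu_t, mu_r, d_t, d_r)
        s_t = d["slope"] if self.speciation_equal else d["slope_temp"]
        s_r = d["slope"] if self.speciation_equal else d["slope_trop"]
        return TimeVaryingParams(lam_t, lam_r, s_t, s_r, lam_tt, mu_t, mu_r, d_t, d_r)

    def pack(self, params: GeoSSEParams | TimeVaryingParams) -> np.ndarray:
        """Project a full parameter set onto the free vector (inverse of unpack
        for parameter sets satisfying the constraints)."""
        tv = isinstance(params, TimeVaryingParams)
        if tv != self.time_varying:
            raise ValueError("parameter type does not match spec's time_varying flag")
        lam_t = params.lambda0_temp if tv else params.lambda_temp
        lam_r = params.lambda0_trop if tv else params.lambda_trop
        out: list[float] = []
        for name in self.free_names():
            if name == "lambda":
                out.append(lam_t)
            elif name == "lambda_temp":
                out.append(lam_t)
            elif name == "lambda_trop":
                out.append(lam_r)
            elif name == "lambda_tt":
                out.append(params.lambda_tt)
            elif name == "mu":
                out.append(params.mu_temp)
            elif name == "mu_temp":
                out.append(params.mu_temp)
            elif name == "mu_trop":
                out.append(params.mu_trop)
            elif name == "d":
                out.append(params.d_temp)
            elif name == "d_scale":
                rho = self.dispersal_ratio
                out.append(params.d_temp if np.isinf(rho) else params.d_trop)
            elif name == "d_temp":
                out.append(params.d_temp)
            elif name == "d_trop":
                out.append(params.d_trop)
            elif name == "slope":
                out.append(params.slope_temp)
            elif name == "slope_temp":
                out.append(params.slope_temp)
            elif name == "slope_trop":
                out.append(params.slope_trop)
        return np.array(out)

    # -- structure ------------------------------------------------------

    def with_time_varying(self) -> "ModelSpec":
        return replace(self, time_varying=True)

    def with_dispersal_ratio(self, rho: float) -> "ModelSpec":
        return replace(self, dispersal_equal=False, dispersal_ratio=rho)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True when this spec's constraints are a superset of ``other``'s
        (every parameter set expressible here is expressible in ``other``)."""
        if self.allow_biome_divergence and not other.allow_biome_divergence:
            return False
        if other.speciation_equal and not self.speciation_equal:
            return False
        if other.extinction_equal and not self.extinction_equal:
            return False
        if self.time_varying and not other.time_varying:
            return False
        # dispersal structure
        if other.dispersal_ratio is not None:
            ok = self.dispersal_ratio == other.dispersal_ratio or (
                other.dispersal_ratio == 1.0 and self.dispersal_equal
            )
            if not ok:
                return False
        elif other.dispersal_equal:
            if not (self.dispersal_equal or self.dispersal_ratio == 1.0):
                return False
        return True

    def describe(self) -> str:
        """Short human-readable constraint string, e.g. ``lTT+ lT≠lTr mEq dEq``."""
        parts = [
            "lTT+" if self.allow_biome_divergence else "lTT0",
            "lEq" if self.speciation_equal else "lT≠lTr",
            "mEq" if self.extinction_equal else "mT≠mTr",
        ]
        if self.dispersal_ratio is not None:
            parts.append(f"dRatio={self.dispersal_ratio:g}")
        else:
            parts.append("dEq" if self.dispersal_equal else "dT≠dTr")
        if self.time_varying:
            parts.append("tvar")
        return " ".join(parts)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: ModelSpec
    params: GeoSSEParams | TimeVaryingParams
    lnL: float
    converged: bool
    n_starts: int = 1
    start_lnLs: tuple[float, ...] = field(default=(), compare=False)

    @property
    def k(self) -> int:
        return self.model.n_free

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL

    @property
    def r_temp(self) -> float:
        return self.params.r_temp

    @property
    def r_trop(self) -> float:
        return self.params.r_trop

    def as_dict(self) -> dict:
        return {
            "model": self.model.describe(),
            "k": self.k,
            "lnL": self.lnL,
            "AIC": self.aic,
            "converged": self.converged,
            "r_temp": self.r_temp,
            "r_trop": self.r_trop,
            **self.params.as_dict(),
        }


def enumerate_models(
    constrain_dispersal: bool = False, time_varying: bool = False
) -> list[ModelSpec]:
    """Enumerate the constrained scenarios in a fixed, deterministic order.

    The full space crosses biome-divergence speciation (with / without) ×
    dispersal (equal / free) × the four λ/μ equality patterns → 16 specs;
    ``constrain_dispersal`` keeps only the 8 dispersal-equal ones.
    Ordering: richest structure first within each block, biome-divergence
    models first.
    """
    specs: list[ModelSpec] = []
    for allow_tt in (True, False):
        for d_equal in ((True,) if constrain_dispersal else (False, True)):
            for lam_equal in (False, True):
                for mu_equal in (False, True):
                    specs.append(
                        ModelSpec(
                            allow_biome_divergence=allow_tt,
                            speciation_equal=lam_equal,
                            extinction_equal=mu_equal,
                            dispersal_equal=d_equal,
                            time_varying=time_varying,
                        )
                    )
    return specs


def full_model() -> ModelSpec:
    """The unconstrained seven-parameter model."""
    return ModelSpec()


def character_independent_model() -> ModelSpec:
    """The biome-independent model: shared λ, μ, d and no biome-divergence
    speciation — the most constrained of the 16 scenarios."""
    return ModelSpec(
        allow_biome_divergence=False,
        speciation_equal=True,
        extinction_equal=True,
        dispersal_equal=True,
    )
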