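"""Dispersal-ratio robustness sweep.

Refits the model across a grid of fixed ratios ρ = d_temp / d_trop
(range expansion from temperate into tropical, over the reverse) and
asks over which contiguous range of ρ around the symmetric point ρ = 1
the sign of the net-diversification difference r_trop − r_temp is
conserved.  The grid is uniform in u = ρ / (1 + ρ) on [0, 1] — symmetric
under ρ ↔ 1/ρ and covering 0 → ∞ without an arbitrary cap; the exact
endpoints map to the one-way-dispersal submodels and u = 0.5 (ρ = 1) is
forced onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomes import SamplingFractions
from .inference import ci_base_params, fit_ml
from .likelihood import GeoSSELikelihood, RootOptions
from .model_space import FitResult, ModelSpec
from .treeio import BiomeStateTable, Phylogeny

__all__ = ["SweepResult", "dispersal_ratio_grid", "sweep_dispersal_ratio", "trend_interval"]


def dispersal_ratio_grid(n_grid: int = 150) -> np.ndarray:
    """Strictly increasing grid of ρ values from 0 to ∞ including 1."""
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    u = np.linspace(0.0, 1.0, n_grid)
    if not np.any(u == 0.5):
        u[np.argmin(np.abs(u - 0.5))] = 0.5
    with np.errstate(divide="ignore"):
        rho = u / (1.0 - u)
    rho[-1] = np.inf
    return rho


@dataclass
class SweepResult:
    """Per-ratio refits and the trend-conservation bookkeeping."""

    ratios: np.ndarray
    fits: list[FitResult | None]
    baseline_sign: int  # sign of r_trop - r_temp at rho = 1
    conserved: np.ndarray  # bool per ratio; False where the fit failed
    failed: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rho, fit, cons in zip(self.ratios, self.fits, self.conserved):
            row = {"ratio": rho, "conserved": bool(cons)}
            if fit is not None:
                row.update(
                    lnL=fit.lnL,
                    r_temp=fit.r_temp,
                    r_trop=fit.r_trop,
                    r_diff=fit.r_trop - fit.r_temp,
                    **fit.params.as_dict(),
                )
            rows.append(row)
        return pd.DataFrame(rows)


def sweep_dispersal_ratio(
    tree: Phylogeny,
    states: BiomeStateTable,
    sampling: SamplingFractions | None = None,
    spec: ModelSpec | None = None,
    n_grid: int = 150,
    starts: int = 2,
    seed: int | np.random.Generator | None = None,
    root: RootOptions | None = None,
    likelihood: GeoSSELikelihood | None = None,
) -> SweepResult:
    """Fit the model at every grid ratio with d_temp = ρ · d_trop enforced.

    ``spec`` must leave dispersal free (the ratio constraint replaces the
    dispersal-equality constraint).  Fits sweep outward from ρ = 1,
    warm-started from the previous grid point's optimum (the profile
    likelihood is continuous in ρ).  Failed grid fits are recorded and
    excluded from the trend interval with a warning flag.
    """
    spec = spec or ModelSpec()
    if spec.dispersal_equal or spec.dispersal_ratio is not None:
        raise ValueError("sweep requires a spec with dispersal free")
    rng = np.random.default_rng(seed)
    ratios = dispersal_ratio_grid(n_grid)
    i_one = int(np.where(ratios == 1.0)[0][0])
    fn = likelihood or GeoSSELikelihood(tree, states, sampling, root)
    base = ci_base_params(fn, rng)

    fits: list[FitResult | None] = [None] * len(ratios)
    failed: list[int] = []

    def fit_at(i: int, warm: FitResult | None) -> FitResult | None:
        sub = spec.with_dispersal_ratio(float(ratios[i]))
        init = None
        if warm is not None:
            # the neighbor's free vector maps directly: ratio specs share
            # free-parameter names and ordering
            init = warm.model.pack(warm.params)
        try:
            return fit_ml(
                tree, states, sampling, sub, starts=starts, seed=rng,
                root=root, init=init, likelihood=fn, base_params=base,
            )
        except RuntimeError:
            failed.append(i)
            return None

    fits[i_one] = fit_at(i_one, None)
    if fits[i_one] is None:
        raise RuntimeError("baseline fit at ratio 1 failed")
    for i in range(i_one + 1, len(ratios)):
        fits[i] = fit_at(i, fits[i - 1])
    for i in range(i_one - 1, -1, -1):
        fits[i] = fit_at(i, fits[i + 1])

    base_diff = fits[i_one].r_trop - fits[i_one].r_temp
    baseline_sign = int(np.sign(base_diff))
    if baseline_sign == 0:
        raise RuntimeError("baseline trend undefined: r_trop - r_temp is exactly 0")
    conserved = np.zeros(len(ratios), dtype=bool)
    for i, fit in enumerate(fits):
        if fit is not None:
            conserved[i] = np.sign(fit.r_trop - fit.r_temp) == baseline_sign
    return SweepResult(ratios, fits, baseline_sign, conserved, failed)


def trend_interval(sweep: SweepResult) -> tuple[float, float]:
    """Largest contiguous grid interval around ρ = 1 conserving the trend.

    Endpoints are reported as grid values, with 0 / ∞ as the open-ended
    sentinels.
    """
    ratios = sweep.ratios
    i_one = int(np.where(ratios == 1.0)[0][0])
    if not sweep.conserved[i_one]:
        return 1.0, 1.0
    lo = i_one
    while lo > 0 and sweep.conserved[lo - 1]:
        lo -= 1
    hi = i_one
    while hi < len(ratios) - 1 and sweep.conserved[hi + 1]:
        hi += 1
    return float(ratios[lo]), float(ratios[hi])
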