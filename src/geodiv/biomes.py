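"""Biome classification from latitudinal ranges and sampling fractions.

A species is TROPICAL if its whole latitudinal range lies within the tropic
lines (±23.4° by default), TEMPERATE if the range lies entirely poleward of
them, and WIDESPREAD if it straddles a tropic line.  Sampling fractions —
the probability that an extant species of each biome state appears in the
phylogeny — enter the likelihood's tip initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .treeio import Biome, BiomeStateTable, LatitudeRange

__all__ = [
    "TROPIC_LATITUDE",
    "SamplingFractions",
    "classify_species",
    "classify_table",
    "estimate_sampling_fractions",
    "described_counts_from_proportions",
]

#: Latitude of the tropic lines in degrees (Tropics of Cancer/Capricorn).
TROPIC_LATITUDE = 23.4


@dataclass(frozen=True)
class SamplingFractions:
    """Per-state probabilities that an extant species was sampled.

    Each fraction lies in (0, 1].  The counts used to compute the
    fractions, when known, are carried along for reporting.
    """

    f_temp: float = 1.0
    f_trop: float = 1.0
    f_wide: float = 1.0
    counts_in_tree: dict | None = field(default=None, compare=False)
    counts_described: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, f in zip(("f_temp", "f_trop", "f_wide"), self.as_tuple()):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {f}")

    def as_tuple(self) -> tuple[float, float, float]:
        """(f_temp, f_trop, f_wide), ordered by ``Biome`` state index."""
        return (self.f_temp, self.f_trop, self.f_wide)

    def __getitem__(self, state: Biome) -> float:
        return self.as_tuple()[int(state)]


def classify_species(lat_range: LatitudeRange, threshold: float = TROPIC_LATITUDE) -> Biome:
    """Assign a biome state from a latitudinal range.

    Closed-boundary convention for ranges touching exactly ±threshold:
    a range otherwise inside the tropics that touches a tropic line counts
    as TROPICAL, and a range with ``min_lat == threshold`` (or
    ``max_lat == -threshold``) counts as TEMPERATE.  These are
    measure-zero ties; any other range straddling a tropic line is
    WIDESPREAD.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    lo, hi = lat_range.min_lat, lat_range.max_lat
    # temperate checked first so a degenerate range sitting exactly on a
    # tropic line follows the min_lat-at-threshold rule
    if lo >= threshold or hi <= -threshold:
        return Biome.TEMPERATE
    if -threshold <= lo and hi <= threshold:
        return Biome.TROPICAL
    return Biome.WIDESPREAD


def classify_table(
    ranges: Iterable[LatitudeRange], threshold: float = TROPIC_LATITUDE
) -> BiomeStateTable:
    """Classify a collection of latitudinal ranges into a state table."""
    out: dict[str, Biome] = {}
    for r in ranges:
        if r.species in out:
            raise ValueError(f"duplicate species: {r.species}")
        out[r.species] = classify_species(r, threshold)
    return BiomeStateTable(out)


def estimate_sampling_fractions(
    states_in_tree: BiomeStateTable,
    total_described: Mapping[Biome, int] | Mapping[str, int],
) -> SamplingFractions:
    """Sampling fraction per state = (# tips in state) / (# described in state).

    ``total_described`` maps each biome state (or its name) to the number
    of described extant species in that state; it must dominate the tree
    counts.  States absent from the tree may have zero described species
    (their fraction defaults to 1 and never enters the likelihood).
    """
    described = {
        (k if isinstance(k, Biome) else Biome.parse(k)): int(v)
        for k, v in total_described.items()
    }
    in_tree = states_in_tree.counts()
    fracs = {}
    for b in Biome:
        n_tree = in_tree[b]
        n_desc = described.get(b, 0)
        if n_desc < n_tree:
            raise ValueError(
                f"{b.name}: described total {n_desc} < tips in tree {n_tree}"
            )
        if n_tree == 0:
            fracs[b] = 1.0
        elif n_desc == 0:
            raise ValueError(f"{b.name}: present in tree but zero described species")
        else:
            fracs[b] = n_tree / n_desc
    return SamplingFractions(
        f_temp=fracs[Biome.TEMPERATE],
        f_trop=fracs[Biome.TROPICAL],
        f_wide=fracs[Biome.WIDESPREAD],
        counts_in_tree={b.name: in_tree[b] for b in Biome},
        counts_described={b.name: described.get(b, 0) for b in Biome},
    )


def described_counts_from_proportions(
    proportions: Mapping[Biome, float] | Mapping[str, float],
    grand_total: int,
) -> dict[Biome, int]:
    """Extrapolate described species counts per state.

    Multiplies the observed state proportions (e.g. from a range database
    covering a subset of described species) by the grand total of
    described species, rounding half-up per state.  This reproduces the
    workflow of estimating per-biome described totals from database
    proportions times a known total species count.
    """
    if grand_total <= 0:
        raise ValueError("grand_total must be positive")
    props = {
        (k if isinstance(k, Biome) else Biome.parse(k)): float(v)
        for k, v in proportions.items()
    }
    total_p = sum(props.values())
    if not (0.99 <= total_p <= 1.01):
        raise ValueError(f"proportions must sum to ~1, got {total_p}")
    import math

    return {b: int(math.floor(props.get(b, 0.0) * grand_total + 0.5)) for b in Biome}
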