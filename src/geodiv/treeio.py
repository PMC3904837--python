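"""Reading, validating, and writing dated phylogenies and tip-state tables.

The likelihood machinery needs a rooted, strictly binary, ultrametric tree
with branch lengths in Myr.  :class:`Phylogeny` stores the tree as flat
arrays indexed in postorder (children always before parents, root last),
which is the layout the pruning algorithm consumes directly.  Newick parsing
and pruning are delegated to :mod:`dendropy`.

Time convention: ``t = 0`` at the present, increasing into the past.  Node
ages are measured on that axis, so every tip sits at age 0 and the root at
``height``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Biome",
    "LatitudeRange",
    "BiomeStateTable",
    "Phylogeny",
    "TreeValidationError",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_state_table",
    "match_tree_and_states",
    "extract_clade",
]

#: Default relative (to tree height) tolerance for ultrametricity checks.
#: Large published supertrees are numerically sloppy at the 1e-3 level.
DEFAULT_ULTRAMETRIC_TOL = 1e-3


class TreeValidationError(ValueError):
    """Raised when a tree violates the structural requirements."""


class Biome(enum.IntEnum):
    """Biome occupancy state of a lineage.

    Integer values are the state indices used throughout the likelihood
    core: 0 = temperate endemic, 1 = tropical endemic, 2 = widespread
    (present in both biomes).
    """

    TEMPERATE = 0
    TROPICAL = 1
    WIDESPREAD = 2

    @classmethod
    def parse(cls, text: str) -> "Biome":
        try:
            return cls[str(text).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown biome state: {text!r}") from None


@dataclass(frozen=True)
class LatitudeRange:
    """Observed latitudinal extent of a species, degrees in [-90, 90]."""

    species: str
    min_lat: float
    max_lat: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.min_lat <= 90.0 and -90.0 <= self.max_lat <= 90.0):
            raise ValueError(
                f"{self.species}: latitudes must lie in [-90, 90], "
                f"got ({self.min_lat}, {self.max_lat})"
            )
        if self.min_lat > self.max_lat:
            raise ValueError(
                f"{self.species}: min_lat {self.min_lat} > max_lat {self.max_lat}"
            )


class BiomeStateTable(Mapping[str, Biome]):
    """Immutable mapping species name -> :class:`Biome`."""

    def __init__(self, states: Mapping[str, Biome] | Iterable[tuple[str, Biome]]):
        self._states = dict(states)
        for k, v in self._states.items():
            if not isinstance(v, Biome):
                self._states[k] = Biome.parse(v)

    def __getitem__(self, species: str) -> Biome:
        return self._states[species]

    def __iter__(self):
        return iter(self._states)

    def __len__(self) -> int:
        return len(self._states)

    def __repr__(self) -> str:
        counts = self.counts()
        return (
            f"BiomeStateTable({len(self)} species: "
            f"{counts[Biome.TEMPERATE]} temperate, {counts[Biome.TROPICAL]} tropical, "
            f"{counts[Biome.WIDESPREAD]} widespread)"
        )

    def counts(self) -> dict[Biome, int]:
        """Number of species per biome state."""
        out = {b: 0 for b in Biome}
        for v in self._states.values():
            out[v] += 1
        return out

    def subset(self, species: Iterable[str]) -> "BiomeStateTable":
        return BiomeStateTable({s: self._states[s] for s in species})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self._states),
                "state": [v.name for v in self._states.values()],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Phylogeny:
    """Rooted, strictly binary, ultrametric, dated phylogeny.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder: the ``n_tips`` tips
    occupy arbitrary positions but every internal node has a larger index
    than both of its children, and the root is the last index.

    Attributes
    ----------
    children : (n_nodes, 2) int array, -1 entries for tips
    parent : (n_nodes,) int array, -1 for the root
    ages : (n_nodes,) float array, node age in Myr before present
        (tips exactly 0, root = tree height)
    tip_labels : tuple of str, ``tip_labels[i]`` labels node ``i``
        for ``i < n_tips``
    """

    def __init__(
        self,
        children: np.ndarray,
        parent: np.ndarray,
        ages: np.ndarray,
        tip_labels: tuple[str, ...],
    ):
        self.children = np.asarray(children, dtype=np.int64)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=np.float64)
        self.tip_labels = tuple(tip_labels)
        self.n_nodes = len(self.ages)
        self.n_tips = len(self.tip_labels)
        self.root = self.n_nodes - 1

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(
        cls,
        tree: dendropy.Tree,
        ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
        on_nonultrametric: str = "error",
    ) -> "Phylogeny":
        """Validate a dendropy tree and convert it to the array layout.

        Parameters
        ----------
        ultrametric_tol : float
            Relative tolerance (fraction of tree height) for root-to-tip
            path-length spread.
        on_nonultrametric : {"error", "warn"}
            Whether a violation beyond tolerance raises or warns.
        """
        root = tree.seed_node
        nodes = []  # postorder
        for nd in tree.postorder_node_iter():
            nodes.append(nd)
        if nodes[-1] is not root:  # pragma: no cover - dendropy guarantees this
            raise TreeValidationError("postorder traversal did not end at the root")

        tips = [nd for nd in nodes if nd.is_leaf()]
        n_tips = len(tips)
        if n_tips < 2:
            raise TreeValidationError("tree must have at least 2 tips")

        labels = []
        for nd in tips:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                raise TreeValidationError("tip without a label")
            labels.append(label)
        if len(set(labels)) != n_tips:
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")

        # strict binarity
        for nd in nodes:
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise TreeValidationError(
                    f"non-binary node with {nch} children "
                    f"(polytomies must be resolved externally)"
                )

        # branch lengths: required and > 0 for every non-root node
        depth = {root: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            bl = nd.edge.length
            if bl is None:
                raise TreeValidationError("missing branch length")
            if not np.isfinite(bl) or bl <= 0.0:
                raise TreeValidationError(f"non-positive branch length: {bl}")
            depth[nd] = depth[nd.parent_node] + bl

        tip_depths = np.array([depth[nd] for nd in tips])
        height = float(tip_depths.max())
        spread = float(tip_depths.max() - tip_depths.min())
        if spread > ultrametric_tol * height:
            msg = (
                f"tree is not ultrametric: root-to-tip depths span "
                f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}] "
                f"(spread {spread:.3g} > tol {ultrametric_tol:.3g} x height {height:.6g})"
            )
            if on_nonultrametric == "warn":
                warnings.warn(msg)
            else:
                raise TreeValidationError(msg)

        # index: tips first (in traversal order), then internals postorder
        index = {}
        i = 0
        for nd in nodes:
            if nd.is_leaf():
                index[nd] = i
                i += 1
        for nd in nodes:
            if not nd.is_leaf():
                index[nd] = i
                i += 1
        n_nodes = i

        children = np.full((n_nodes, 2), -1, dtype=np.int64)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        ages = np.zeros(n_nodes, dtype=np.float64)
        for nd in nodes:
            k = index[nd]
            ages[k] = 0.0 if nd.is_leaf() else height - depth[nd]
            for j, ch in enumerate(nd.child_nodes()):
                children[k, j] = index[ch]
                parent[index[ch]] = k
        return cls(children, parent, ages, tuple(labels))

    # -- basic structure ----------------------------------------------

    @property
    def height(self) -> float:
        """Root age = crown height in Myr."""
        return float(self.ages[self.root])

    @property
    def internal_postorder(self) -> np.ndarray:
        """Internal node indices in postorder (children first, root last)."""
        return np.arange(self.n_tips, self.n_nodes, dtype=np.int64)

    def is_tip(self, i: int) -> bool:
        return i < self.n_tips

    def branch_length(self, i: int) -> float:
        p = self.parent[i]
        if p < 0:
            raise ValueError("root has no branch")
        return float(self.ages[p] - self.ages[i])

    def tip_depths(self) -> np.ndarray:
        return np.full(self.n_tips, self.height)

    # -- conversion ----------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = taxa.new_taxon(label=lab)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                nodes[p].add_child(nodes[i])
                nodes[i].edge.length = float(self.ages[p] - self.ages[i])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[self.root]
        return tree

    def to_newick(self) -> str:
        return (
            self.to_dendropy().as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".12g"
            ).strip()
        )

    def __repr__(self) -> str:
        return f"Phylogeny({self.n_tips} tips, height {self.height:.4g} Myr)"


def parse_newick(
    newick: str,
    ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
    on_nonultrametric: str = "error",
) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeValidationError(f"Newick parse failure: {exc}") from exc
    return Phylogeny.from_dendropy(tree, ultrametric_tol, on_nonultrametric)


def read_newick(
    path,
    ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
    on_nonultrametric: str = "error",
) -> Phylogeny:
    """Read and validate a dated phylogeny from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read(), ultrametric_tol, on_nonultrametric)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_state_table(path, schema: str = "states"):
    """Read a delimited per-species table.

    Parameters
    ----------
    schema : {"states", "latitudes"}
        ``states`` expects columns (species, state); ``latitudes`` expects
        (species, min_lat, max_lat).

    Returns
    -------
    BiomeStateTable or list[LatitudeRange]
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns:
        raise ValueError(f"{path}: missing 'species' column")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate species: {sorted(set(dupes))}")
    if schema == "states":
        if "state" not in df.columns:
            raise ValueError(f"{path}: missing 'state' column")
        return BiomeStateTable(
            {str(r.species): Biome.parse(r.state) for r in df.itertuples()}
        )
    if schema == "latitudes":
        for col in ("min_lat", "max_lat"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing '{col}' column")
        return [
            LatitudeRange(str(r.species), float(r.min_lat), float(r.max_lat))
            for r in df.itertuples()
        ]
    raise ValueError(f"unknown schema {schema!r}")


def match_tree_and_states(
    tree: Phylogeny,
    table: BiomeStateTable,
    policy: str = "drop",
) -> tuple[Phylogeny, BiomeStateTable, list[str]]:
    """Put a tree and a state table in bijection.

    Tips without a state entry are pruned (``policy="drop"``, the paper's
    treatment of species lacking latitudinal data) or raise
    (``policy="error"``).  Pruning keeps the tree strictly binary by
    suppressing the resulting degree-2 nodes and summing their branch
    lengths, so root-to-tip depths of retained tips are preserved exactly.
    """
    unmatched = [lab for lab in tree.tip_labels if lab not in table]
    if unmatched and policy == "error":
        raise ValueError(f"tips without state data: {unmatched}")
    if not unmatched:
        return tree, table.subset(tree.tip_labels), []
    keep = [lab for lab in tree.tip_labels if lab in table]
    if len(keep) < 2:
        raise ValueError("fewer than 2 tips with state data remain after matching")
    dtree = tree.to_dendropy()
    taxa_to_keep = [t for t in dtree.taxon_namespace if t.label in set(keep)]
    dtree.retain_taxa(taxa_to_keep)
    # retain_taxa suppresses unifurcations including a degenerate root
    pruned = Phylogeny.from_dendropy(dtree, ultrametric_tol=np.inf)
    return pruned, table.subset(pruned.tip_labels), unmatched


def extract_clade(tree: Phylogeny, tips: Iterable[str]) -> Phylogeny:
    """Subtree spanned by the MRCA of the listed tips.

    Returns the full clade under that MRCA (which may contain tips not in
    the list), re-rooted at the MRCA — the batch-analysis unit for
    per-order / per-family runs.
    """
    wanted = set(tips)
    missing = wanted - set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    if len(wanted) < 2:
        raise ValueError("need at least 2 tips to define a clade")
    # MRCA on the array layout: intersect root-ward paths
    idx = {lab: i for i, lab in enumerate(tree.tip_labels)}

    def path_to_root(i: int) -> list[int]:
        out = [i]
        while tree.parent[out[-1]] >= 0:
            out.append(int(tree.parent[out[-1]]))
        return out

    common = set(path_to_root(idx[next(iter(wanted))]))
    for lab in wanted:
        common &= set(path_to_root(idx[lab]))
    mrca = min(common, key=lambda i: tree.ages[i])
    # leaves under the MRCA
    in_clade = np.zeros(tree.n_nodes, dtype=bool)
    in_clade[mrca] = True
    for node in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        if in_clade[node]:
            in_clade[tree.children[node]] = True
    clade_tips = [tree.tip_labels[i] for i in range(tree.n_tips) if in_clade[i]]
    dtree = tree.to_dendropy()
    dtree.retain_taxa([t for t in dtree.taxon_namespace if t.label in set(clade_tips)])
    return Phylogeny.from_dendropy(dtree, ultrametric_tol=np.inf)
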