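"""Tree ingestion, reconciliation and model-implied trait covariances.

Trees are parsed with dendropy and reduced to the arrays the likelihood code
needs: tip labels, root-to-tip depths and the matrix of shared root-to-MRCA
path lengths s_ij. Under Brownian motion the trait covariance between tips i
and j is sigma^2 * s_ij; Pagel's lambda multiplies the off-diagonals; the
single-optimum Ornstein-Uhlenbeck process (root state fixed at z0 = theta,
height T) gives sigma^2/(2 alpha) * exp(-2 alpha (T - s_ij)) *
(1 - exp(-2 alpha s_ij)); the early-burst model rescales time as
s' = (exp(r s) - 1)/r with r < 0 (rates decay as exp(r t)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .trait_data import TraitTable

BRLEN_CLAMP = 1e-9


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree with non-negative branch lengths and unique tip labels."""

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)
    _depths: dict[str, float] = field(init=False, repr=False)
    _shared: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            if edge.length < 0:
                if edge.length > -BRLEN_CLAMP:
                    warnings.warn("near-zero negative branch length clamped to 0")
                    edge.length = 0.0
                else:
                    raise TreeError(f"negative branch length {edge.length}")
        self.tip_labels = sorted(labels)
        self._depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                node._ns_depth = float(node.edge.length or 0.0)
            else:
                node._ns_depth = node.parent_node._ns_depth + float(node.edge.length)
            if node.is_leaf():
                self._depths[node.taxon.label] = node._ns_depth

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def height(self) -> float:
        return max(self._depths.values())

    def tip_depths(self) -> np.ndarray:
        return np.array([self._depths[t] for t in self.tip_labels])

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        h = d.max()
        return bool(h == 0 or np.all(np.abs(d - h) <= rtol * h))

    def shared_path_matrix(self) -> np.ndarray:
        """s_ij: root-to-MRCA path length for every tip pair (diag = depth).

        Built by a preorder sweep: each internal node of depth d sets
        s_ij = d for tip pairs whose MRCA it is.
        """
        if self._shared is not None:
            return self._shared
        idx = {t: i for i, t in enumerate(self.tip_labels)}
        n = self.n_tips
        S = np.zeros((n, n))
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                node._ns_tips = [i]
                S[i, i] = node._ns_depth
            else:
                groups = [child._ns_tips for child in node.child_nodes()]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for i in groups[a]:
                            for j in groups[b]:
                                S[i, j] = S[j, i] = node._ns_depth
                node._ns_tips = [i for g in groups for i in g]
        self._shared = S
        return S

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def clone_pruned(self, keep: list[str]) -> "Phylogeny":
        # newick round-trip gives an independent taxon namespace
        t = dendropy.Tree.get(data=self.newick(), schema="newick",
                              rooting="force-rooted", preserve_underscores=True)
        taxa = [tx for tx in t.taxon_namespace if tx.label in set(keep)]
        t.retain_taxa(taxa)
        return Phylogeny(t)


def parse_tree(source: str, schema: str = "newick") -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=source, schema=schema, rooting="force-rooted",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises heterogeneous parse errors
        raise TreeError(f"malformed {schema} tree: {exc}") from exc
    return Phylogeny(tree)


def read_trees(path, schema: str = "newick") -> list[Phylogeny]:
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=schema,
                                      rooting="force-rooted",
                                      preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"cannot parse tree file {path}: {exc}") from exc
    return [Phylogeny(t) for t in trees]


def write_trees(phylos: list[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for p in phylos:
            fh.write(p.newick() + "\n")


def load_tree_set(
    path, n_sample: int, seed: int, schema: str = "newick"
) -> tuple[list[Phylogeny], dict]:
    """Sample ``n_sample`` trees uniformly without replacement, reproducibly."""
    trees = read_trees(path, schema=schema)
    if n_sample > len(trees):
        raise TreeError(
            f"requested {n_sample} trees but only {len(trees)} available"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(trees), size=n_sample, replace=False).tolist())
    manifest = {"file": str(path), "indices": idx, "seed": seed}
    return [trees[i] for i in idx], manifest


def reconcile_and_prune(
    tree: Phylogeny, table: TraitTable, synonyms: dict[str, str] | None = None
) -> tuple[Phylogeny, TraitTable]:
    """Align a tree and a trait table via an optional tip-label synonym map.

    Tips without trait data are pruned; species without tips are dropped;
    the returned table rows follow the pruned tree's (sorted) tip order.
    """
    synonyms = synonyms or {}
    mapping = {}  # original tip label -> species_id
    species = set(table.species)
    for tip in tree.tip_labels:
        target = synonyms.get(tip, tip)
        if target in species:
            mapping[tip] = target
    if not mapping:
        raise TreeError("no overlap between tree tips and trait table")
    pruned_tree = tree.clone_pruned(list(mapping))
    # rename tips to species ids
    for leaf in pruned_tree.tree.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    pruned = Phylogeny(pruned_tree.tree)
    aligned = table.subset(pruned.tip_labels)
    return pruned, aligned


# ---------------------------------------------------------------- covariance

MODELS = ("BM", "LAMBDA", "OU", "EB")


@dataclass
class PhyloCovariance:
    matrix: np.ndarray
    tip_labels: list[str]
    model: str
    params: dict


def correlation_structure(
    S: np.ndarray, T: float, model: str, params: dict
) -> np.ndarray:
    """Unit-rate (sigma^2 = 1) covariance structure for a model tag."""
    if model == "BM":
        return S.copy()
    if model == "LAMBDA":
        lam = params["lambda"]
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        V = lam * S
        np.fill_diagonal(V, np.diag(S))
        return V
    if model == "OU":
        alpha = params["alpha"]
        if alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {alpha}")
        return np.exp(-2 * alpha * (T - S)) * (-np.expm1(-2 * alpha * S)) / (
            2 * alpha
        )
    if model == "EB":
        r = params["r"]
        if r == 0:
            return S.copy()
        return np.expm1(r * S) / r
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def model_covariance(tree: Phylogeny, model: str, params: dict) -> PhyloCovariance:
    """Model-implied tip trait covariance (keyed by sorted tip label)."""
    S = tree.shared_path_matrix()
    T = tree.height
    if model in ("OU", "EB") and not tree.is_ultrametric():
        raise TreeError(f"{model} covariance requires an ultrametric tree")
    sigma2 = params.get("sigma2", 1.0)
    C = sigma2 * correlation_structure(S, T, model, params)
    return PhyloCovariance(
        matrix=C, tip_labels=list(tree.tip_labels), model=model, params=dict(params)
    )
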