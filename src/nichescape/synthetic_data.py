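"""Synthetic trees and trait tables with known evolutionary parameters.

The generator emulates the shape of the study inputs — a 16-trait table for
~191 species and a sample of 100 ultrametric trees — with every generating
parameter recorded in a :class:`TruthRecord`, so recovery of lambda, alpha,
r, PCA structure and regression coefficients can be tested without any
external data. Values are not meant to mimic real primate numbers; only the
schema, the correlation structure of the life-history block, the categorical
level sets and the phylogenetic signal are emulated.

The six life-history variables are built as a shared latent Brownian score
plus independent noise. With latent share s, each pair of variables
correlates at s and the expected first-principal-component share of variance
is (1 + 5 s) / 6, so a target PC1 share (default 0.806) fixes s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo_core import Phylogeny, model_covariance, parse_tree
from .schema import CATEGORICAL_LEVELS, LIFE_HISTORY_VARIABLES, raw_schema
from .trait_data import TraitTable


class SimulationError(ValueError):
    pass


# ------------------------------------------------------------------- trees


def simulate_tree(
    n_tips: int,
    seed: int,
    model: str = "yule",
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    rescale_height: float | None = 1.0,
    label_format: str = "sp{:04d}",
) -> Phylogeny:
    """Forward birth(-death) simulation of a rooted ultrametric tree.

    Stops when ``n_tips`` lineages are extant, then holds for one more
    exponential waiting time; extinct lineages are pruned. With
    ``rescale_height`` set, branch lengths are divided by the tree height.
    """
    if n_tips < 2:
        raise SimulationError("need at least 2 tips")
    if birth_rate <= 0 or death_rate < 0:
        raise SimulationError("rates must satisfy birth > 0, death >= 0")
    if model == "yule":
        death_rate = 0.0
    elif model != "birth-death":
        raise SimulationError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        result = _simulate_bd_once(n_tips, rng, birth_rate, death_rate)
        if result is not None:
            newick = _to_newick(result, rescale_height, label_format)
            return parse_tree(newick)
    raise SimulationError("birth-death simulation went extinct 100 times")


def _simulate_bd_once(n_tips, rng, lam, mu):
    # nodes: list of dicts {parent, time, children, extinct}
    nodes = [{"parent": None, "time": 0.0, "children": [], "tip": False}]
    nodes.append({"parent": 0, "time": None, "children": [], "tip": False})
    nodes.append({"parent": 0, "time": None, "children": [], "tip": False})
    nodes[0]["children"] = [1, 2]
    active = [1, 2]
    start = {1: 0.0, 2: 0.0}
    t = 0.0
    while len(active) < n_tips:
        n = len(active)
        total = n * (lam + mu)
        t += rng.exponential(1.0 / total)
        i = active[rng.integers(n)]
        if rng.random() < lam / (lam + mu):
            nodes[i]["time"] = t
            for _ in range(2):
                nodes.append({"parent": i, "time": None, "children": [],
                              "tip": False})
                nodes[i]["children"].append(len(nodes) - 1)
                active.append(len(nodes) - 1)
                start[len(nodes) - 1] = t
            active.remove(i)
        else:
            nodes[i]["time"] = t
            nodes[i]["tip"] = True
            nodes[i]["extinct"] = True
            active.remove(i)
            if not active:
                return None
    t_end = t + rng.exponential(1.0 / (len(active) * (lam + mu)))
    for i in active:
        nodes[i]["time"] = t_end
        nodes[i]["tip"] = True
        nodes[i]["extinct"] = False
    return nodes


def _to_newick(nodes, rescale_height, label_format):
    height = max(nd["time"] for nd in nodes if nd["tip"])
    scale = 1.0 / height * rescale_height if rescale_height else 1.0
    extant = [i for i, nd in enumerate(nodes) if nd["tip"] and not nd.get("extinct")]
    labels = {i: label_format.format(k + 1) for k, i in enumerate(extant)}

    def keep(i):  # subtree contains an extant tip
        nd = nodes[i]
        if nd["tip"]:
            return not nd.get("extinct")
        return any(keep(c) for c in nd["children"])

    def render(i, parent_time):
        nd = nodes[i]
        brlen = (nd["time"] - parent_time) * scale
        if nd["tip"]:
            return f"{labels[i]}:{brlen:.12f}"
        kids = [c for c in nd["children"] if keep(c)]
        if len(kids) == 1:  # suppress unifurcation left by pruning
            child = nodes[kids[0]]
            sub = render(kids[0], parent_time)
            return sub
        inner = ",".join(render(c, nd["time"]) for c in kids)
        return f"({inner}):{brlen:.12f}"

    root = nodes[0]
    kids = [c for c in root["children"] if keep(c)]
    if len(kids) == 1:
        inner = render(kids[0], 0.0)
        return f"({inner});"
    inner = ",".join(render(c, 0.0) for c in kids)
    return f"({inner});"


def perturb_node_ages(
    tree: Phylogeny, seed: int, age_sd: float = 0.3
) -> Phylogeny:
    """A dating variant of a tree: same topology, deformed node ages.

    Internal-node depths (tree height normalised to 1) are passed through the
    monotone map d -> d^gamma with gamma = exp(N(0, age_sd)), so parent-child
    order, ultrametricity and the topology are preserved while every
    divergence time shifts — emulating draws from a node-dating posterior.
    """
    rng = np.random.default_rng(seed)
    gamma = float(np.exp(rng.normal(0.0, age_sd)))
    t = dendropy.Tree.get(data=tree.newick(), schema="newick",
                          rooting="force-rooted", preserve_underscores=True)
    height = tree.height
    # set depths, then rewrite edge lengths from transformed depths
    for node in t.preorder_node_iter():
        parent = node.parent_node
        pdepth = 0.0 if parent is None else parent._depth
        node._depth = pdepth + float(node.edge.length or 0.0)
    for node in t.preorder_node_iter():
        node._new = height * (node._depth / height) ** gamma
    for node in t.preorder_node_iter():
        parent = node.parent_node
        node.edge.length = node._new - (0.0 if parent is None else parent._new)
    return Phylogeny(t)


def simulate_tree_set(
    n_tips: int,
    n_trees: int,
    seed: int,
    model: str = "yule",
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    age_sd: float = 0.3,
) -> list[Phylogeny]:
    """A reference tree plus dating variants, emulating a posterior sample."""
    ref = simulate_tree(n_tips, seed=seed, model=model, birth_rate=birth_rate,
                        death_rate=death_rate)
    trees = [ref]
    for i in range(1, n_trees):
        trees.append(perturb_node_ages(ref, seed=(seed + 104729 * i) % (2**31),
                                       age_sd=age_sd))
    return trees


# ------------------------------------------------------------------ traits


def simulate_continuous_trait(
    tree: Phylogeny, model: str, params: dict, seed: int
) -> pd.Series:
    """One MVN draw of a continuous trait under a model covariance."""
    cov = model_covariance(tree, model, params)
    z0 = params.get("z0", 0.0)
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    sigma2 = params.get("sigma2", 1.0)
    if sigma2 == 0:
        x = np.full(n, z0)
    else:
        L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(n))
        x = z0 + L @ rng.standard_normal(n)
    return pd.Series(x, index=tree.tip_labels)


def simulate_categorical_trait(
    tree: Phylogeny,
    Q: np.ndarray,
    levels: tuple[str, ...],
    root_state: str,
    seed: int,
) -> pd.Series:
    """Continuous-time Markov (Mk) simulation of a discrete trait."""
    Q = np.asarray(Q, dtype=float)
    k = len(levels)
    if Q.shape != (k, k):
        raise SimulationError(f"Q must be {k}x{k}")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any() or not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise SimulationError("Q rows must sum to 0 with non-negative off-diagonals")
    if root_state not in levels:
        raise SimulationError(f"root state {root_state!r} not in levels")
    rng = np.random.default_rng(seed)
    idx = {lv: i for i, lv in enumerate(levels)}
    states: dict[str, str] = {}

    def walk(node, state):
        for child in node.child_nodes():
            s = state
            remaining = float(child.edge.length or 0.0)
            while True:
                rate = -Q[idx[s], idx[s]]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                probs = off[idx[s]] / rate
                s = levels[rng.choice(k, p=probs)]
            if child.is_leaf():
                states[child.taxon.label] = s
            else:
                walk(child, s)

    walk(tree.tree.seed_node, root_state)
    return pd.Series(states).loc[tree.tip_labels]


def symmetric_rate_matrix(k: int, rate: float) -> np.ndarray:
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return Q


# ------------------------------------------------------------ study config


@dataclass
class StudyConfig:
    """Generating conditions for the synthetic study dataset.

    Defaults match the study shape: 191 species, 100 trees, a life-history
    block whose first principal component carries ~80.6% of the variance,
    strong phylogenetic signal in most continuous elements, one weakly
    phylogenetic categorical element, and known regression coefficients for
    the competition model.
    """

    n_species: int = 191
    n_trees: int = 100
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    lh_pc1_share: float = 0.806
    tree_age_sd: float = 0.3    # node-age deformation across the tree set
    mk_rate_slow: float = 0.3   # phylogenetically conserved categoricals
    mk_rate_fast: float = 8.0   # effectively unconserved guild
    beta: dict = field(default_factory=lambda: {
        "intercept": 0.5,
        "adult_body_mass_g": 0.08,
        "temperature_mean_c": -0.06,
        "trophic_guild[omnivore]": -0.10,
        "trophic_guild[gummivore]": 0.12,
    })
    response_noise_sd: float = 0.05

    def latent_share(self) -> float:
        s = (6.0 * self.lh_pc1_share - 1.0) / 5.0
        if not 0.0 < s <= 1.0:
            raise SimulationError(
                f"lh_pc1_share {self.lh_pc1_share} outside attainable (1/6, 1]"
            )
        return s

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_trees": self.n_trees,
            "tree_model": self.tree_model,
            "birth_rate": self.birth_rate,
            "death_rate": self.death_rate,
            "tree_age_sd": self.tree_age_sd,
            "lh_pc1_share": self.lh_pc1_share,
            "mk_rate_slow": self.mk_rate_slow,
            "mk_rate_fast": self.mk_rate_fast,
            "beta": dict(self.beta),
            "response_noise_sd": self.response_noise_sd,
        }


@dataclass
class TruthRecord:
    config: dict
    seed: int
    child_seeds: dict
    variable_models: dict
    beta: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "child_seeds": self.child_seeds,
                "variable_models": self.variable_models,
                "beta": self.beta,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def _child_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, child in zip(names, children)
    }


# LH variable scales (mean, sd in days) keep values positive and plausible.
_LH_SCALES = {
    "gestation_length_d": (170.0, 40.0),
    "weaning_age_d": (400.0, 120.0),
    "age_first_reproduction_d": (1800.0, 500.0),
    "interbirth_interval_d": (500.0, 150.0),
    "generation_length_d": (3500.0, 900.0),
    "max_longevity_d": (11000.0, 2500.0),
}


def simulate_study(
    config: StudyConfig | None = None, seed: int = 0
) -> tuple[TraitTable, list[Phylogeny], TruthRecord]:
    """Generate the full synthetic study: 16-trait table, tree set, truth.

    Traits are simulated on the first tree of the set (the "reference"
    phylogeny), so the remaining trees play the role of a posterior sample
    over which inference is replicated.
    """
    config = config or StudyConfig()
    names = (
        ["trees", "latent_lh", "lh_noise", "mass", "diet", "habitat",
         "tmean", "trange", "pmean", "prange", "stratum", "activity",
         "guild", "response"]
    )
    seeds = _child_seeds(seed, names)
    trees = simulate_tree_set(
        config.n_species,
        config.n_trees,
        seed=seeds["trees"],
        model=config.tree_model,
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        age_sd=config.tree_age_sd,
    )
    ref = trees[0]
    rng_noise = np.random.default_rng(seeds["lh_noise"])

    variable_models: dict[str, dict] = {}

    # life-history block: shared latent BM score + independent noise
    latent = simulate_continuous_trait(
        ref, "BM", {"sigma2": 1.0, "z0": 0.0}, seeds["latent_lh"]
    )
    z_latent = (latent - latent.mean()) / latent.std(ddof=0)
    s = config.latent_share()
    lh = {}
    for var in LIFE_HISTORY_VARIABLES:
        noise = rng_noise.standard_normal(config.n_species)
        std = np.sqrt(s) * z_latent.to_numpy() + np.sqrt(1 - s) * noise
        mean, sd = _LH_SCALES[var]
        lh[var] = mean + sd * std
        variable_models[var] = {
            "model": "latent_BM_plus_noise", "latent_share": s,
            "mean": mean, "sd": sd,
        }

    def cont(name, model, params, seed_key):
        variable_models[name] = {"model": model, **params}
        return simulate_continuous_trait(ref, model, params, seeds[seed_key])

    log_mass = cont("adult_body_mass_g", "BM",
                    {"sigma2": 1.0, "z0": np.log(3000.0)}, "mass")
    mass = np.exp(log_mass)
    variable_models["adult_body_mass_g"]["transform"] = "exp(BM on log scale)"

    diet_latent = cont("diet_breadth", "OU",
                       {"sigma2": 2.0, "alpha": 2.0, "z0": 0.0}, "diet")
    diet = 1 + np.clip(np.round(2.0 + 1.5 * diet_latent), 0, 12).astype(int)
    habitat_latent = cont("habitat_breadth", "OU",
                          {"sigma2": 2.0, "alpha": 2.0, "z0": 0.0}, "habitat")
    habitat = 1 + np.clip(np.round(1.5 + habitat_latent), 0, 5).astype(int)

    tmean = cont("temperature_mean_c", "BM", {"sigma2": 60.0, "z0": 22.0},
                 "tmean")
    trange = cont("temperature_range_c", "OU",
                  {"sigma2": 40.0, "alpha": 1.0, "z0": 12.0}, "trange").clip(0)
    pmean = cont("precipitation_mean_mm", "BM",
                 {"sigma2": 3e5, "z0": 1500.0}, "pmean").clip(0)
    prange = cont("precipitation_range_mm", "OU",
                  {"sigma2": 2e5, "alpha": 1.0, "z0": 800.0}, "prange").clip(0)

    def mk(name, rate, seed_key):
        levels = CATEGORICAL_LEVELS[name]
        Q = symmetric_rate_matrix(len(levels), rate)
        # deterministic reseeding until every declared level is observed
        for bump in range(50):
            draw = simulate_categorical_trait(
                ref, Q, levels, levels[0], (seeds[seed_key] + bump) % (2**31)
            )
            if set(draw) == set(levels):
                break
        variable_models[name] = {
            "model": "Mk_symmetric", "rate": rate, "levels": list(levels),
        }
        return draw

    stratum = mk("foraging_stratum", config.mk_rate_slow, "stratum")
    activity = mk("activity_cycle", config.mk_rate_slow, "activity")
    guild = mk("trophic_guild", config.mk_rate_fast, "guild")

    data = pd.DataFrame(index=pd.Index(ref.tip_labels, name="species_id"))
    for var in LIFE_HISTORY_VARIABLES:
        data[var] = lh[var]
    data["adult_body_mass_g"] = mass
    data["diet_breadth"] = diet.astype(float)
    data["habitat_breadth"] = habitat.astype(float)
    data["temperature_mean_c"] = tmean
    data["temperature_range_c"] = trange
    data["precipitation_mean_mm"] = pmean
    data["precipitation_range_mm"] = prange
    data["foraging_stratum"] = stratum
    data["activity_cycle"] = activity
    data["trophic_guild"] = guild
    table = TraitTable(data, raw_schema())

    truth = TruthRecord(
        config=config.to_dict(),
        seed=seed,
        child_seeds=seeds,
        variable_models=variable_models,
        beta=dict(config.beta),
    )
    return table, trees, truth


def simulate_pgls_response(
    design_X: pd.DataFrame,
    beta: dict[str, float],
    tree: Phylogeny,
    noise_sd: float,
    seed: int,
) -> pd.Series:
    """y = X beta + Brownian noise on the tree, for regression recovery."""
    b = pd.Series(0.0, index=design_X.columns)
    unknown = sorted(set(beta) - set(design_X.columns))
    if unknown:
        raise SimulationError(f"beta names not in design: {unknown}")
    for k, v in beta.items():
        b[k] = v
    mu = design_X.to_numpy() @ b.to_numpy()
    noise = simulate_continuous_trait(
        tree, "BM", {"sigma2": noise_sd**2 / max(tree.height, 1e-12), "z0": 0.0},
        seed,
    )
    return pd.Series(mu, index=design_X.index) + noise.loc[design_X.index]
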