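"""Per-species niche uniqueness and specialisation in the retained space.

Uniqueness is the mean Euclidean distance from a species' niche location to
its k nearest neighbours (k = 5 by default); low uniqueness proxies intense
interspecific competition. Specialisation is the Euclidean distance to the
centroid of the occupied space. Both use all retained dimensions on the
principal-coordinate scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import pearsonr

from .famd import NicheSpace


class MetricError(ValueError):
    pass


@dataclass
class NicheScores:
    scores: pd.DataFrame  # species x [uniqueness, specialisation, ranks, flags]
    k: int

    @property
    def species(self) -> list[str]:
        return list(self.scores.index)


def _distance_matrix(space: NicheSpace) -> pd.DataFrame:
    X = space.coordinates.to_numpy()
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=space.species, columns=space.species)


def uniqueness_scores(space: NicheSpace, k: int = 5) -> pd.Series:
    """Mean distance to the k nearest neighbours, self excluded.

    Distance ties at the k-th neighbour are broken by species_id order so the
    neighbour set is always exactly k and deterministic.
    """
    n = len(space.species)
    if k < 1:
        raise MetricError("k must be at least 1")
    if k >= n:
        raise MetricError(f"k={k} requires more than k species (have {n})")
    D = _distance_matrix(space)
    out = {}
    for sp in space.species:
        d = D[sp].drop(sp)
        order = sorted(zip(d.to_numpy(), d.index))
        out[sp] = float(np.mean([t[0] for t in order[:k]]))
    return pd.Series(out, name="uniqueness").loc[space.species]


def specialisation_scores(space: NicheSpace) -> pd.Series:
    """Euclidean distance to the arithmetic centroid of the coordinates."""
    if len(space.species) < 2:
        raise MetricError("specialisation needs at least 2 species")
    X = space.coordinates.to_numpy()
    centroid = X.mean(axis=0)
    d = np.linalg.norm(X - centroid, axis=1)
    return pd.Series(d, index=space.species, name="specialisation")


def neighbour_robustness(
    space: NicheSpace, ks: tuple[int, ...] = (1, 3, 5, 10, 100), reference_k: int = 5
) -> pd.Series:
    """Pearson r between uniqueness at each k and at the reference k."""
    n = len(space.species)
    bad = [k for k in ks if k >= n]
    if bad:
        raise MetricError(f"neighbour count(s) {bad} not below n={n}")
    ref = uniqueness_scores(space, reference_k)
    out = {}
    for k in ks:
        if k == reference_k:
            out[k] = 1.0
        else:
            out[k] = float(pearsonr(uniqueness_scores(space, k), ref)[0])
    return pd.Series(out, name=f"r_vs_k{reference_k}")


def _tukey_upper_outliers(x: pd.Series) -> pd.Series:
    q1, q3 = x.quantile(0.25), x.quantile(0.75)
    fence = q3 + 1.5 * (q3 - q1)
    return x > fence


def rank_and_flag(space: NicheSpace, k: int = 5) -> NicheScores:
    """Scores with descending ranks (1 = highest) and Tukey upper-fence flags.

    The outlier rule is the standard boxplot convention, score > Q3 + 1.5 IQR;
    rank ties are broken by species_id.
    """
    uni = uniqueness_scores(space, k)
    spec = specialisation_scores(space)
    df = pd.DataFrame({"uniqueness": uni, "specialisation": spec})
    for col in ("uniqueness", "specialisation"):
        # sort on score then species_id for deterministic tie-breaks
        order = df[[col]].copy()
        order["_sp"] = order.index
        order = order.sort_values([col, "_sp"], ascending=[False, True])
        ranks = pd.Series(range(1, len(order) + 1), index=order.index)
        df[f"rank_{col}"] = ranks.loc[df.index]
        df[f"outlier_{col}"] = _tukey_upper_outliers(df[col])
    return NicheScores(scores=df, k=k)


def top_bottom(scores: NicheScores, which: str, m: int = 10) -> dict:
    rank = scores.scores[f"rank_{which}"]
    top = rank[rank <= m].sort_values().index.tolist()
    n = len(rank)
    bottom = rank[rank > n - m].sort_values(ascending=False).index.tolist()
    return {"top": top, "bottom": bottom}


def subset_rerun(
    space: NicheSpace, subset: list[str], k: int = 5
) -> tuple[NicheScores, dict]:
    """Recompute scores restricting neighbours and centroid to a species subset.

    Coordinates are reused from the full-space fit (the factor analysis is not
    refit); the overlap report compares the subset's bottom-10 uniqueness list
    with the full-sample bottom-10.
    """
    missing = sorted(set(subset) - set(space.species))
    if missing:
        raise MetricError(f"subset species absent from space: {missing}")
    if len(subset) <= k:
        raise MetricError(f"subset of {len(subset)} too small for k={k}")
    sub_space = NicheSpace(
        coordinates=space.coordinates.loc[subset],
        eigenvalues=space.eigenvalues,
        pct_variance=space.pct_variance,
        cumulative_pct=space.cumulative_pct,
        contributions=space.contributions,
    )
    sub_scores = rank_and_flag(sub_space, k)
    full_scores = rank_and_flag(space, k)
    full_bottom = set(top_bottom(full_scores, "uniqueness")["bottom"])
    sub_bottom = set(top_bottom(sub_scores, "uniqueness")["bottom"])
    overlap = sorted(full_bottom & sub_bottom)
    report = {
        "full_bottom10": sorted(full_bottom),
        "subset_bottom10": sorted(sub_bottom),
        "shared": overlap,
        "n_shared": len(overlap),
    }
    return sub_scores, report
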