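"""Factor analysis of mixed data (FAMD) on the niche elements.

Quantitative columns are z-scored (population scaling); each categorical level
is coded as an indicator divided by the square root of its frequency and then
centred. A PCA of the resulting expanded matrix (uniform row weights 1/n)
yields eigenvalues whose total equals q + sum_j (K_j - 1): 17 for the study
schema of 8 quantitative elements and categorical levels 3/3/6.

Species coordinates are principal coordinates: the per-component variance of
the coordinates equals the component's eigenvalue, so Euclidean distances in
the retained space are the distances used by the niche metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import TraitSchema
from .trait_data import TraitTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FamdModel:
    expanded: pd.DataFrame          # species x expanded columns (processed)
    eigenvalues: np.ndarray         # descending, all components
    coordinates: pd.DataFrame       # species x all components (principal coords)
    column_loadings: pd.DataFrame   # expanded column x component (unit vectors)
    column_variable: pd.Series      # expanded column -> parent element name
    schema: TraitSchema

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class NicheSpace:
    """Retained (Kaiser) niche space: coordinates, variances, contributions."""

    coordinates: pd.DataFrame       # species x Dim1..DimD
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    contributions: pd.DataFrame     # element x dimension, percent

    @property
    def n_dimensions(self) -> int:
        return self.coordinates.shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.coordinates.index)


def build_expanded_matrix(
    table: TraitTable,
) -> tuple[pd.DataFrame, pd.Series]:
    """Construct the weighted, centred FAMD expanded matrix.

    Returns the processed matrix and a map from expanded column to parent
    element. Levels observed zero times are dropped with a warning.
    """
    schema = table.schema
    blocks: list[pd.DataFrame] = []
    parents: dict[str, str] = {}

    cont = table.continuous_frame()
    sd = cont.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"constant quantitative column(s): {zero}")
    z = (cont - cont.mean()) / sd
    blocks.append(z)
    parents.update({c: c for c in z.columns})

    n = table.n_species
    for var, levels in schema.categorical.items():
        observed = table.data[var]
        for level in levels:
            indicator = (observed == level).astype(float)
            p = indicator.mean()
            if p == 0:
                warnings.warn(
                    f"level {level!r} of {var!r} unobserved; dropped",
                    stacklevel=2,
                )
                continue
            if indicator.sum() == 1:
                warnings.warn(
                    f"level {level!r} of {var!r} observed once (weight 1/sqrt(1/n))",
                    stacklevel=2,
                )
            col = indicator / np.sqrt(p)
            colname = f"{var}={level}"
            blocks.append((col - col.mean()).rename(colname).to_frame())
            parents[colname] = var
    expanded = pd.concat(blocks, axis=1)
    return expanded, pd.Series(parents)


def famd_fit(table: TraitTable) -> FamdModel:
    """Fit the FAMD by eigendecomposition of the expanded-matrix covariance.

    Deterministic up to sign; each component is oriented so that its
    largest-magnitude column loading is positive.
    """
    expanded, parents = build_expanded_matrix(table)
    X = expanded.to_numpy()
    n = X.shape[0]
    cov = (X.T @ X) / n
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| column positive per component
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    coords = X @ eigvec
    comp_names = [f"Dim{j + 1}" for j in range(eigvec.shape[1])]
    return FamdModel(
        expanded=expanded,
        eigenvalues=eigval,
        coordinates=pd.DataFrame(coords, index=expanded.index, columns=comp_names),
        column_loadings=pd.DataFrame(
            eigvec, index=expanded.columns, columns=comp_names
        ),
        column_variable=parents,
        schema=table.schema,
    )


def variable_contributions(
    model: FamdModel, dim: int, report_threshold: float | None = None
) -> pd.Series:
    """Percent contribution of each element to component ``dim`` (1-based).

    Category-level contributions are summed into their parent categorical
    element; percentages over all elements sum to 100. With
    ``report_threshold`` set, only elements above that percentage are returned
    (the headline figures use 9%).
    """
    if not 1 <= dim <= len(model.eigenvalues):
        raise IndexError(f"dimension {dim} out of range 1..{len(model.eigenvalues)}")
    v = model.column_loadings.iloc[:, dim - 1]
    per_column = 100.0 * v**2
    per_element = per_column.groupby(model.column_variable).sum()
    per_element = per_element.sort_values(ascending=False)
    if report_threshold is not None:
        per_element = per_element[per_element > report_threshold]
    return per_element


def retain_kaiser(model: FamdModel) -> NicheSpace:
    """Retain the components with eigenvalue strictly greater than one."""
    D = int((model.eigenvalues > 1.0).sum())
    if D == 0:
        raise ValidationError(
            "no eigenvalue exceeds 1; niche space undefined under the Kaiser criterion"
        )
    eig = model.eigenvalues[:D]
    total = model.eigenvalues.sum()
    pct = 100.0 * eig / total
    contrib = pd.DataFrame(
        {f"Dim{d}": variable_contributions(model, d) for d in range(1, D + 1)}
    )
    logger.info(
        "retained %d dimensions (%.1f%% of variance)", D, float(pct.sum())
    )
    return NicheSpace(
        coordinates=model.coordinates.iloc[:, :D].copy(),
        eigenvalues=eig.copy(),
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        contributions=contrib,
    )
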