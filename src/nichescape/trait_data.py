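"""Reading, validation and reduction of the raw species x trait table.

The raw table holds 16 traits per species. The six life-history durations are
mutually highly correlated, so they are collapsed to the first principal
component of their z-scored block (the "life history score"), leaving the 11
niche elements consumed by the factor analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    LIFE_HISTORY_VARIABLES,
    OPTIONAL_COLUMNS,
    TraitSchema,
    element_schema,
    raw_schema,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not match the declared schema."""


class ValidationError(ValueError):
    """Typed table violates an invariant."""


@dataclass
class TraitTable:
    """A typed species x variable table.

    ``data`` is indexed by species_id; continuous columns are float64,
    categorical columns hold level strings from the schema's level sets.
    """

    data: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species_id values: {dupes}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def continuous_frame(self) -> pd.DataFrame:
        return self.data[list(self.schema.continuous)].astype(float)

    def categorical_frame(self) -> pd.DataFrame:
        return self.data[list(self.schema.categorical)]

    def subset(self, species: list[str]) -> "TraitTable":
        missing = sorted(set(species) - set(self.data.index))
        if missing:
            raise ValidationError(f"species not in table: {missing}")
        return TraitTable(self.data.loc[species].copy(), self.schema)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species_id")


def _validate_levels(df: pd.DataFrame, schema: TraitSchema) -> None:
    for var, levels in schema.categorical.items():
        observed = df[var].dropna()
        bad = sorted(set(observed) - set(levels))
        if bad:
            raise ValidationError(
                f"variable {var!r} has undeclared level(s) {bad}; "
                f"allowed: {sorted(levels)}"
            )


def read_trait_table(path, schema: TraitSchema | None = None) -> TraitTable:
    """Read a CSV with a ``species_id`` column into a typed :class:`TraitTable`.

    Missing cells are allowed at this stage (see :func:`drop_incomplete`);
    unknown categorical levels, missing columns, duplicate species and
    unparseable numbers are rejected.
    """
    if schema is None:
        schema = raw_schema()
    df = pd.read_csv(path, dtype=str)
    if "species_id" not in df.columns:
        raise SchemaError("missing required column 'species_id'")
    missing_cols = [v for v in schema.variables if v not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s): {missing_cols}")
    df = df.set_index("species_id")
    keep = [c for c in df.columns if c in schema.variables or c in OPTIONAL_COLUMNS]
    df = df[keep]

    for var in schema.continuous:
        col = df[var]
        parsed = pd.to_numeric(col, errors="coerce")
        bad = col.notna() & parsed.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"unparseable numeric value {col[bad].iloc[0]!r} "
                f"at row {row!r}, column {var!r}"
            )
        if np.isinf(parsed.dropna()).any():
            raise ValidationError(f"non-finite value in column {var!r}")
        df[var] = parsed
    _validate_levels(df, schema)
    return TraitTable(df, schema)


def drop_incomplete(table: TraitTable) -> TraitTable:
    """Listwise deletion: keep only species with no missing analysis cells."""
    cols = list(table.schema.variables)
    complete = table.data[cols].notna().all(axis=1)
    n_removed = int((~complete).sum())
    if complete.sum() == 0:
        raise ValidationError("all species have missing data; nothing to analyse")
    if n_removed:
        logger.info("drop_incomplete: removed %d incomplete species", n_removed)
    return TraitTable(table.data[complete].copy(), table.schema)


def correlation_screen(
    table: TraitTable, threshold: float = 0.6
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations over the continuous variables.

    Returns the symmetric correlation matrix and the variable pairs with
    ``|r| > threshold``, sorted by descending ``|r|``.
    """
    cont = table.continuous_frame()
    if len(cont) < 3:
        raise ValidationError("correlation screen needs at least 3 species")
    sd = cont.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance variable(s): {zero}")
    corr = cont.corr(method="pearson")
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                flagged.append((a, b, r))
    flagged.sort(key=lambda t: -abs(t[2]))
    return corr, flagged


@dataclass
class LifeHistoryScore:
    scores: pd.Series
    pct_variance_pc1: float
    loadings: pd.Series


def life_history_score(
    table: TraitTable,
    lh_variables: tuple[str, ...] = LIFE_HISTORY_VARIABLES,
    orient_on: str = "max_longevity_d",
) -> tuple[TraitTable, LifeHistoryScore]:
    """Collapse the life-history block to its first principal component.

    The block is z-scored (population scaling), PC1 coordinates become the
    continuous element ``life_history`` and the six inputs are removed. The
    component is oriented so the loading of ``orient_on`` (maximum longevity
    by default) is positive: "slow" life histories score high.
    """
    if table.n_species < 2:
        raise ValidationError("life-history PCA needs at least 2 species")
    missing = [v for v in lh_variables if v not in table.data.columns]
    if missing:
        raise SchemaError(f"life-history variable(s) absent: {missing}")
    block = table.data[list(lh_variables)].astype(float)
    if block.isna().any().any():
        raise ValidationError("life-history block has missing values")
    sd = block.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance life-history variable(s): {zero}")
    z = (block - block.mean()) / sd
    cov = np.cov(z.to_numpy(), rowvar=False, ddof=0)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pc1 = eigvec[:, 0]
    if orient_on in lh_variables and pc1[list(lh_variables).index(orient_on)] < 0:
        pc1 = -pc1
    scores = pd.Series(z.to_numpy() @ pc1, index=block.index, name="life_history")
    pct = 100.0 * eigval[0] / eigval.sum()

    out = table.data.drop(columns=list(lh_variables)).copy()
    out["life_history"] = scores
    new_schema = element_schema()
    # Ordering follows the element schema so downstream output is stable.
    ordered = [c for c in new_schema.variables if c in out.columns]
    extras = [c for c in out.columns if c not in ordered]
    reduced = TraitTable(out[ordered + extras], new_schema)
    lh = LifeHistoryScore(
        scores=scores,
        pct_variance_pc1=float(pct),
        loadings=pd.Series(pc1, index=list(lh_variables)),
    )
    return reduced, lh
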