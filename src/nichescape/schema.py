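"""Study variable schema: the 16 raw traits and the 11 derived niche elements.

The raw table carries six life-history durations (days), adult body mass (g),
two breadth counts, four climatic variables and three categorical variables.
After the life-history PCA the six durations are replaced by a single
``life_history`` score, leaving 8 continuous + 3 categorical niche elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field


LIFE_HISTORY_VARIABLES: tuple[str, ...] = (
    "gestation_length_d",
    "weaning_age_d",
    "age_first_reproduction_d",
    "interbirth_interval_d",
    "generation_length_d",
    "max_longevity_d",
)

#: Continuous variables other than the life-history block.
CONTINUOUS_ELEMENTS: tuple[str, ...] = (
    "adult_body_mass_g",
    "diet_breadth",
    "habitat_breadth",
    "temperature_mean_c",
    "temperature_range_c",
    "precipitation_mean_mm",
    "precipitation_range_mm",
)

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "foraging_stratum": ("ground", "scansorial", "arboreal"),
    "activity_cycle": ("nocturnal", "diurnal", "cathemeral"),
    "trophic_guild": (
        "folivore",
        "frugivore",
        "folivore_frugivore",
        "omnivore",
        "gummivore",
        "insectivore",
    ),
}

#: Columns tolerated in input files but excluded from the analysis.
OPTIONAL_COLUMNS: tuple[str, ...] = ("elevation_range_m",)

#: Variables that must be strictly positive.
POSITIVE_VARIABLES: tuple[str, ...] = ("adult_body_mass_g",) + LIFE_HISTORY_VARIABLES

#: Variables that must be non-negative (ranges, counts).
NONNEGATIVE_VARIABLES: tuple[str, ...] = (
    "diet_breadth",
    "habitat_breadth",
    "temperature_range_c",
    "precipitation_range_mm",
    "elevation_range_m",
)


@dataclass(frozen=True)
class TraitSchema:
    """Typing of a species x trait table.

    Parameters
    ----------
    continuous
        Names of continuous variables, in column order.
    categorical
        Mapping of categorical variable name -> allowed level set.
    """

    continuous: tuple[str, ...]
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.continuous + tuple(self.categorical)

    def n_indicator_columns(self) -> int:
        """Total expanded-matrix inertia: q + sum_j (K_j - 1)."""
        return len(self.continuous) + sum(
            len(levels) - 1 for levels in self.categorical.values()
        )


def raw_schema() -> TraitSchema:
    """Schema of the 16-trait input table."""
    return TraitSchema(
        continuous=LIFE_HISTORY_VARIABLES + CONTINUOUS_ELEMENTS,
        categorical=dict(CATEGORICAL_LEVELS),
    )


def element_schema() -> TraitSchema:
    """Schema of the 11 niche elements used by the factor analysis."""
    return TraitSchema(
        continuous=CONTINUOUS_ELEMENTS + ("life_history",),
        categorical=dict(CATEGORICAL_LEVELS),
    )
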