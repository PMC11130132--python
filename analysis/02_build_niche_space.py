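"""Reduce the 16 raw traits to 11 niche elements (life-history PCA) and build
the multidimensional niche space by factor analysis of mixed data, retaining
dimensions with eigenvalue > 1.

Reads results/synthetic_study/traits.csv; writes niche_elements.csv,
coordinates.csv, eigenvalues.csv and contributions.csv under results/.
"""

from pathlib import Path

import pandas as pd

from nichescape.famd import famd_fit, retain_kaiser, variable_contributions
from nichescape.trait_data import (
    correlation_screen,
    drop_incomplete,
    life_history_score,
    read_trait_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = drop_incomplete(read_trait_table(ROOT / "synthetic_study" / "traits.csv"))
    corr, flagged = correlation_screen(table, threshold=0.6)
    lh_pairs = [t for t in flagged if t[0].endswith("_d") and t[1].endswith("_d")]
    print(f"{len(flagged)} variable pairs with |r| > 0.6 "
          f"({len(lh_pairs)} within the life-history block)")

    reduced, lh = life_history_score(table)
    print(f"life-history PC1 explains {lh.pct_variance_pc1:.1f}% of the "
          "variance in the six duration variables")

    model = famd_fit(reduced)
    space = retain_kaiser(model)
    print(f"total inertia {model.total_inertia:.1f}; "
          f"{space.n_dimensions} dimensions retained under the Kaiser "
          f"criterion, explaining {space.cumulative_pct[-1]:.1f}% of variance")
    for d in (1, 2, 3):
        top = variable_contributions(model, d, report_threshold=9.0)
        print(f"  Dim{d} ({space.pct_variance[d-1]:.1f}%): "
              + ", ".join(f"{k} {v:.0f}%" for k, v in top.items()))

    reduced.write_csv(ROOT / "niche_elements.csv")
    space.coordinates.to_csv(ROOT / "coordinates.csv",
                             index_label="species_id", float_format="%.12g")
    pd.DataFrame(
        {
            "eigenvalue": space.eigenvalues,
            "pct_variance": space.pct_variance,
            "cumulative_pct": space.cumulative_pct,
        },
        index=space.coordinates.columns,
    ).to_csv(ROOT / "eigenvalues.csv", index_label="dimension",
             float_format="%.12g")
    space.contributions.to_csv(ROOT / "contributions.csv",
                               index_label="element", float_format="%.12g")


if __name__ == "__main__":
    main()
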