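"""End-to-end orchestration: table -> life-history PCA -> FAMD -> metrics ->
signal/evolutionary models -> PGLS, with flat CSV/JSON artifacts.

Every stage writes plain text outputs into the run directory so a rerun with
the same config and inputs is byte-identical and diffable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .famd import famd_fit, retain_kaiser
from .evo_inference import fit_lambda, lambda_lrt, select_model, summarise_across_trees
from .niche_metrics import neighbour_robustness, rank_and_flag, top_bottom
from .pgls import build_design, multi_tree_pgls
from .phylo_core import load_tree_set, read_trees, reconcile_and_prune
from .synthetic_data import StudyConfig, simulate_study
from .trait_data import drop_incomplete, life_history_score, read_trait_table

logger = logging.getLogger(__name__)

STAGES = ("traits", "famd", "metrics", "signal", "evomodel", "pgls", "manifest")


@dataclasses.dataclass
class RunConfig:
    traits_csv: str | None = None
    trees_file: str | None = None
    synonyms_json: str | None = None
    simulate: bool = True          # generate inputs if paths are absent
    n_species: int = 191
    n_trees: int = 100
    k_neighbours: int = 5
    robustness_ks: tuple[int, ...] = (1, 3, 5, 10, 100)
    seed: int = 0
    alpha: float = 0.05
    pgls_correlation: str = "BM"
    out_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        if "robustness_ks" in raw:
            raw["robustness_ks"] = tuple(raw["robustness_ks"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["robustness_ks"] = list(self.robustness_ks)
        return d


def _float_csv(df: pd.DataFrame, path: Path, index_label="species_id") -> None:
    df.to_csv(path, index_label=index_label, float_format="%.12g")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure is re-raised with the stage name attached so partial
    runs are attributable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    artifacts: dict[str, str] = {}
    stage = "traits"
    try:
        # ---- stage: input acquisition -------------------------------
        if config.traits_csv and config.trees_file:
            table = read_trait_table(config.traits_csv)
            if config.n_trees:
                trees, manifest = load_tree_set(
                    config.trees_file, config.n_trees, config.seed
                )
            else:
                trees = read_trees(config.trees_file)
                manifest = {"file": config.trees_file, "all": True}
            synonyms = {}
            if config.synonyms_json:
                with open(config.synonyms_json) as fh:
                    synonyms = json.load(fh)
        elif config.simulate:
            study = StudyConfig(n_species=config.n_species,
                                n_trees=config.n_trees)
            table, trees, truth = simulate_study(study, seed=config.seed)
            truth.write(out / "truth.json")
            manifest = {"simulated": True, "seed": config.seed}
            synonyms = {}
        else:
            missing = [
                name
                for name, val in (
                    ("traits_csv", config.traits_csv),
                    ("trees_file", config.trees_file),
                )
                if not val
            ]
            raise FileNotFoundError(
                f"missing input(s) {missing} and simulate=False"
            )
        table = drop_incomplete(table)
        trees_aligned = []
        for t in trees:
            pt, table_aligned = reconcile_and_prune(t, table, synonyms)
            trees_aligned.append(pt)
        table = table_aligned
        reduced, lh = life_history_score(table)
        reduced.write_csv(out / "niche_elements.csv")
        artifacts["traits"] = "niche_elements.csv"

        # ---- stage: famd --------------------------------------------
        stage = "famd"
        model = famd_fit(reduced)
        space = retain_kaiser(model)
        _float_csv(space.coordinates, out / "coordinates.csv")
        eig = pd.DataFrame(
            {
                "eigenvalue": space.eigenvalues,
                "pct_variance": space.pct_variance,
                "cumulative_pct": space.cumulative_pct,
            },
            index=space.coordinates.columns,
        )
        _float_csv(eig, out / "eigenvalues.csv", index_label="dimension")
        _float_csv(space.contributions, out / "contributions.csv",
                   index_label="element")
        artifacts["famd"] = "coordinates.csv"

        # ---- stage: metrics -----------------------------------------
        stage = "metrics"
        scores = rank_and_flag(space, k=config.k_neighbours)
        _float_csv(scores.scores, out / "niche_scores.csv")
        ks = tuple(k for k in config.robustness_ks if k < table.n_species)
        robust = neighbour_robustness(space, ks, config.k_neighbours)
        robust.to_frame().to_csv(out / "robustness.csv", index_label="k",
                                 float_format="%.12g")
        summary = {
            "life_history_pct_variance_pc1": lh.pct_variance_pc1,
            "n_dimensions": space.n_dimensions,
            "pct_variance_retained": float(space.cumulative_pct[-1]),
            "n_outliers_uniqueness": int(
                scores.scores["outlier_uniqueness"].sum()
            ),
            "n_outliers_specialisation": int(
                scores.scores["outlier_specialisation"].sum()
            ),
            "top_bottom_uniqueness": top_bottom(scores, "uniqueness"),
            "top_bottom_specialisation": top_bottom(scores, "specialisation"),
        }
        with open(out / "metrics_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        artifacts["metrics"] = "niche_scores.csv"

        # ---- stage: signal + evomodel -------------------------------
        stage = "signal"
        dim_cols = list(space.coordinates.columns)
        rows = []
        for ti, tree in enumerate(trees_aligned):
            ests = [
                fit_lambda(space.coordinates[d], tree) for d in dim_cols
            ]
            lambda_lrt(ests)
            for d, e in zip(dim_cols, ests):
                rows.append(
                    {
                        "tree_id": ti,
                        "dimension": d,
                        "lambda_hat": e.lambda_hat,
                        "p_vs_0_adj": e.p_vs_0_adj,
                        "p_vs_1_adj": e.p_vs_1_adj,
                    }
                )
        signal = pd.DataFrame(rows)
        signal.to_csv(out / "signal_per_tree.csv", index=False,
                      float_format="%.12g")
        artifacts["signal"] = "signal_per_tree.csv"

        stage = "evomodel"
        rows = []
        for ti, tree in enumerate(trees_aligned):
            for d in dim_cols:
                selected, fits = select_model(space.coordinates[d], tree)
                for f in fits:
                    rows.append(
                        {
                            "tree_id": ti,
                            "dimension": d,
                            "model": f.model,
                            "logLik": f.logLik,
                            "AICc": f.AICc,
                            "delta_AICc": f.delta_AICc,
                            "akaike_weight": f.akaike_weight,
                            "selected": f.model == selected,
                        }
                    )
        evomodel = pd.DataFrame(rows)
        evomodel.to_csv(out / "evomodel_per_tree.csv", index=False,
                        float_format="%.12g")
        sel = evomodel[evomodel["selected"]].rename(
            columns={"model": "selected_model"}
        )
        merged = sel.merge(signal, on=["tree_id", "dimension"])
        summary_df = summarise_across_trees(merged)
        summary_df.to_csv(out / "evo_summary.csv", float_format="%.12g")
        artifacts["evomodel"] = "evomodel_per_tree.csv"

        # ---- stage: pgls --------------------------------------------
        stage = "pgls"
        for kind in ("uniqueness", "specialisation"):
            design = build_design(reduced, scores.scores[kind], kind)
            tab, _ = multi_tree_pgls(
                design, trees_aligned, alpha=config.alpha,
                correlation=config.pgls_correlation,
            )
            tab.to_csv(out / f"pgls_{kind}.csv", index_label="term")
        artifacts["pgls"] = "pgls_uniqueness.csv"

        stage = "manifest"
        artifacts["manifest"] = "manifest.json"
        manifest_out = {
            "version": __version__,
            "seed": config.seed,
            "tree_source": manifest,
            "n_species": table.n_species,
            "n_trees": len(trees_aligned),
            "artifacts": artifacts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest_out, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
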