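"""End-to-end orchestration: samples → diet tables → slopes → drivers.

Chains the stages in analysis order:

1. community merging and exclusions on the raw isotope samples;
2. local and regional diet estimates from the mixing model;
3. two diet tables — 'local_only' (local estimates, every retained
   community) and 'full' (local + regional/global fill-in, only the
   communities with occurrence data);
4. the joint weighted beta regression of grass fraction on community ×
   log body mass, and per-community slope extraction;
5. Jaccard PCoA of composition plus community summaries (SpN, mean_C4,
   elephant presence) to build the second-stage predictor table;
6. all-subsets AICc selection for the slope and mean-grass-fraction
   responses over the environment / community / combined predictor sets,
   and per-species models for widespread taxa.

Used by the command-line interface and directly importable for scripted
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assembly, betareg, ordination, selection
from .mixing import MixingConfig

__all__ = ["StageOneResult", "PipelineResult", "build_diet_tables", "fit_stage_one",
           "build_predictors", "run_pipeline", "species_responses"]

logger = logging.getLogger(__name__)

MIN_SPECIES_COMMUNITIES = 12  # a species needs local data in this many communities


@dataclass
class StageOneResult:
    table: pd.DataFrame
    fit: betareg.BetaRegFit
    slopes: pd.DataFrame
    n_positive: int
    n_directional: int


@dataclass
class PipelineResult:
    samples: pd.DataFrame
    exclusion_report: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    stage_one: dict[str, StageOneResult]
    predictors: dict[str, pd.DataFrame]
    ordination: ordination.Ordination | None
    second_stage: dict[tuple[str, str], dict]
    species_stage: dict[str, dict]


def build_diet_tables(
    samples: pd.DataFrame,
    occurrences: pd.DataFrame,
    traits: pd.DataFrame,
    config: MixingConfig | None = None,
    grass_consumers_only: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Local-only and full (filled-in) diet tables from filtered samples.

    The 'full' table covers only communities present in the occurrence
    dataset; the 'local_only' table covers every community with samples.
    ``grass_consumers_only`` drops pure browsers (grass fraction exactly 0)
    from both tables. Returns (tables, regional estimates).
    """
    config = config or MixingConfig()
    local = assembly.local_estimates(samples, config)
    regional = assembly.regional_estimates(samples, config)

    tr = traits.set_index("species")
    local_tab = local.copy()
    missing_mass = sorted(set(local_tab["species"]) - set(tr.index))
    if missing_mass:
        raise ValueError(f"species without traits: {missing_mass}")
    local_tab["body_mass_kg"] = tr["body_mass_kg"].reindex(local_tab["species"]).to_numpy()
    local_tab["log_mass"] = np.log(local_tab["body_mass_kg"])
    local_tab = assembly.fill_sd(local_tab, regional)

    overlap = sorted(set(occurrences["community"]) & set(samples["community"]))
    full_tab = assembly.assemble(occurrences, local, regional, traits, communities=overlap)
    full_tab = assembly.fill_sd(full_tab, regional)

    if grass_consumers_only:
        local_tab = local_tab[local_tab["mean_fc4"] > 0].reset_index(drop=True)
        full_tab = full_tab[full_tab["mean_fc4"] > 0].reset_index(drop=True)
    return {"local_only": local_tab, "full": full_tab}, regional


def fit_stage_one(table: pd.DataFrame, weight_transform: str = "inv_var") -> StageOneResult:
    """Joint linear beta regression and per-community slopes for one table."""
    fit = betareg.fit_interaction_model(table, order=1, weight_transform=weight_transform)
    slopes, n_pos, n_dir = betareg.extract_slopes(fit)
    return StageOneResult(table, fit, slopes, n_pos, n_dir)


def build_predictors(
    table: pd.DataFrame, covariates: pd.DataFrame, occurrences: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, ordination.Ordination]:
    """Second-stage predictor table for the communities in a diet table.

    Environmental covariates come from the covariate table; PCoA1/PCoA2
    from a Jaccard ordination of the table's own presence/absence matrix;
    SpN and mean_C4 from the community summaries. Elephant presence is
    external knowledge, so when an occurrence table is given a community
    counts as elephant-occupied if Loxodonta appears either in its diet
    table or in its occurrence list (a sampled-data species list can miss
    an elephant population that is known to be there). Returns
    (predictors indexed by community, coords, ordination).
    """
    presence = (
        table.assign(present=1)
        .pivot_table(index="community", columns="species", values="present", fill_value=0)
    )
    ordi = ordination.pcoa(ordination.jaccard_matrix(presence))
    scores = ordi.scores
    rows = []
    for comm, members in table.groupby("community"):
        sp_n, mean_c4, elephant = assembly.community_summaries(members)
        rows.append((comm, sp_n, mean_c4, float(elephant)))
    summ = pd.DataFrame(rows, columns=["community", "SpN", "mean_C4", "Elephant"]).set_index("community")
    if occurrences is not None:
        occ_eleph = (
            occurrences[occurrences["species"].str.split().str[0] == assembly.ELEPHANT_GENUS]
            ["community"].unique()
        )
        summ.loc[summ.index.isin(occ_eleph), "Elephant"] = 1.0
    cov = covariates.set_index("community").loc[summ.index]
    predictors = pd.concat(
        [cov[["MARain", "RainS", "MATemp", "TempS", "Woody_cover"]],
         scores[["PCoA1", "PCoA2"]].loc[summ.index] if scores.shape[1] >= 2 else scores.loc[summ.index],
         summ],
        axis=1,
    )
    coords = cov[["lat", "lon"]]
    return predictors, coords, ordi


def species_responses(
    table: pd.DataFrame, min_communities: int = MIN_SPECIES_COMMUNITIES
) -> dict[str, pd.DataFrame]:
    """Per-species diet tables for widespread taxa (local data only).

    A species qualifies when it has local diet estimates from at least
    ``min_communities`` communities; others are skipped with a warning.
    """
    local = table[table["provenance"] == "local"]
    out = {}
    for sp, rows in local.groupby("species"):
        if len(rows) < min_communities:
            continue
        out[sp] = rows.set_index("community")
    if not out:
        logger.warning("no species found in >= %d communities", min_communities)
    return out


def run_pipeline(
    samples: pd.DataFrame,
    occurrences: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    mixing: MixingConfig | None = None,
    merge_map: dict[str, str] | None = None,
    exclude: list[str] | tuple[str, ...] | None = (),
    grass_consumers_only: bool = False,
    weight_transform: str = "inv_var",
    candidate_structures: tuple[str, ...] = selection.STRUCTURE_ORDER,
    run_species_models: bool = True,
    r_threshold: float = 0.5,
) -> PipelineResult:
    """Run the complete analysis; see the module docstring for the stages."""
    mixing = mixing or MixingConfig()
    merged = assembly.merge_communities(samples, merge_map or {})
    filtered, report = assembly.apply_exclusions(merged, exclude or (), config=mixing)
    tables, _regional = build_diet_tables(
        filtered, occurrences, traits, mixing, grass_consumers_only=grass_consumers_only
    )

    stage_one = {name: fit_stage_one(tab, weight_transform) for name, tab in tables.items()}

    predictors: dict[str, pd.DataFrame] = {}
    second: dict[tuple[str, str], dict] = {}
    ordi = None
    for name, res in stage_one.items():
        preds, coords, ordi = build_predictors(res.table, covariates, occurrences)
        predictors[name] = preds
        slopes = res.slopes.set_index("community")
        idx = slopes.index.intersection(preds.index)
        slope_resp = slopes.loc[idx, "slope"]
        slope_w = 1.0 / slopes.loc[idx, "se"] ** 2
        second[(name, "slope")] = selection.run_second_stage(
            slope_resp, preds, slope_w, coords, response_kind="slope",
            r_threshold=r_threshold, candidate_structures=candidate_structures,
        )
        mean_resp = preds.loc[idx, "mean_C4"]
        second[(name, "mean_c4")] = selection.run_second_stage(
            mean_resp, preds, None, coords, response_kind="mean_c4",
            r_threshold=r_threshold, candidate_structures=candidate_structures,
        )

    species_stage: dict[str, dict] = {}
    if run_species_models:
        preds, coords, _ = build_predictors(tables["local_only"], covariates, occurrences)
        for sp, rows in species_responses(tables["local_only"]).items():
            idx = rows.index.intersection(preds.index)
            resp = rows.loc[idx, "mean_fc4"]
            w = 1.0 / rows.loc[idx, "sd_fc4"] ** 2
            species_stage[sp] = selection.run_second_stage(
                resp, preds, w, coords, response_kind="species",
                r_threshold=r_threshold, candidate_structures=candidate_structures,
            )

    return PipelineResult(
        samples=filtered,
        exclusion_report=report,
        tables=tables,
        stage_one=stage_one,
        predictors=predictors,
        ordination=ordi,
        second_stage=second,
        species_stage=species_stage,
    )
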