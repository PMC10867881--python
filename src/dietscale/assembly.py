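"""Community diet-table assembly.

Takes raw isotope samples plus occurrence and trait tables and produces, for
each herbivore community, a complete species-level table of dietary grass
fractions with uncertainty and provenance. Diet estimates are filled in with
a strict priority:

local     mean/SD of that species' samples within the community;
regional  mean/SD of the species' samples pooled across all communities,
          used where local data are missing;
global    a literature-derived grass fraction from the traits table, used
          where the species has no isotope samples anywhere.

Community handling mirrors standard practice for these isotope compilations:
contiguous or nested sampling localities are merged, high-elevation
communities where C3 grasses break the mixing model's C4-grass assumption
are excluded, and closed-canopy forest communities with zero diet variation
(every member a pure browser) are dropped because a diet-mass slope is
undefined there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixing import MixingConfig, fraction_c4

__all__ = [
    "EnvCovariates",
    "CommunityTable",
    "DEFAULT_MERGE_MAP",
    "DEFAULT_EXCLUDE",
    "merge_communities",
    "apply_exclusions",
    "local_estimates",
    "regional_estimates",
    "assemble",
    "fill_sd",
    "community_summaries",
    "read_occurrences",
    "read_traits",
    "read_covariates",
]

logger = logging.getLogger(__name__)

#: Merges of contiguous/nested sampling localities (source -> target).
DEFAULT_MERGE_MAP: dict[str, str] = {"NBNP": "ATHI", "TRKG": "TRKX"}

#: High-elevation communities where C3 grasses are prevalent.
DEFAULT_EXCLUDE: tuple[str, ...] = ("ABER", "BALE", "SIME")

ELEPHANT_GENUS = "Loxodonta"


@dataclass(frozen=True)
class EnvCovariates:
    """Per-community environmental covariates.

    lat/lon in decimal degrees; ma_rain in mm/yr; rain_s is the CV (%) of
    monthly precipitation; ma_temp in °C; temp_s the SD of temperature
    across the seasonal cycle; woody_cover an areal fraction in [0, 1].
    """

    lat: float
    lon: float
    ma_rain: float
    rain_s: float
    ma_temp: float
    temp_s: float
    woody_cover: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.woody_cover <= 1.0:
            raise ValueError(f"woody_cover must be in [0,1], got {self.woody_cover}")
        if self.ma_rain < 0 or self.rain_s < 0:
            raise ValueError("ma_rain and rain_s must be non-negative")


@dataclass
class CommunityTable:
    """Assembled diet table for one community."""

    community: str
    members: pd.DataFrame  # species, body_mass_kg, log_mass, mean_fc4, sd_fc4, n_samples, provenance
    covariates: EnvCovariates | None = None
    elephant_present: bool = field(init=False)
    sp_n: int = field(init=False)
    mean_c4: float = field(init=False)

    def __post_init__(self) -> None:
        self.sp_n, self.mean_c4, self.elephant_present = community_summaries(self.members)


def merge_communities(samples: pd.DataFrame, merge_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Relabel samples from source communities to their merge targets.

    Sample count is conserved. A source code absent from the data is a
    logged no-op; a cycle or chain in the map is a configuration error.
    """
    if merge_map is None:
        merge_map = dict(DEFAULT_MERGE_MAP)
    overlap = set(merge_map) & set(merge_map.values())
    if overlap:
        raise ValueError(f"merge_map sources overlap targets (cycle/chain): {sorted(overlap)}")
    out = samples.copy()
    present = set(out["community"])
    for src in merge_map:
        if src not in present:
            logger.warning("merge source %r not present in samples; no-op", src)
    out["community"] = out["community"].replace(merge_map)
    return out


def apply_exclusions(
    samples: pd.DataFrame,
    exclude_c3grass: list[str] | tuple[str, ...] | None = None,
    auto_exclude_zero_variance: bool = True,
    config: MixingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unusable communities; return (filtered samples, exclusion report).

    Communities in ``exclude_c3grass`` are removed outright. When
    ``auto_exclude_zero_variance`` is set, any community whose every local
    species-mean grass fraction is zero (pure-browser forest sites) is also
    removed. The report has one row per removed community with its reason.
    """
    if exclude_c3grass is None:
        exclude_c3grass = DEFAULT_EXCLUDE
    config = config or MixingConfig()
    reasons: list[tuple[str, str]] = []
    out = samples.copy()

    listed = [c for c in exclude_c3grass if c in set(out["community"])]
    reasons += [(c, "c3_grass_prevalent") for c in listed]
    out = out[~out["community"].isin(exclude_c3grass)]

    if auto_exclude_zero_variance and len(out):
        f, _ = fraction_c4(out["d13C_enamel"].to_numpy(), config)
        means = pd.Series(f, index=out.index).groupby(
            [out["community"], out["species"]]
        ).mean()
        all_zero = means.groupby(level=0).max()
        zero_comms = list(all_zero.index[all_zero <= 1e-9])  # tolerate float noise at the endmember
        reasons += [(c, "no_within_community_diet_variation") for c in zero_comms]
        out = out[~out["community"].isin(zero_comms)]

    if not len(out):
        logger.warning("all samples excluded")
    report = pd.DataFrame(reasons, columns=["community", "reason"])
    return out.reset_index(drop=True), report


def _estimates(samples: pd.DataFrame, keys: list[str], config: MixingConfig) -> pd.DataFrame:
    f, _ = fraction_c4(samples["d13C_enamel"].to_numpy(), config)
    df = samples.assign(fc4=f)
    g = df.groupby(keys)["fc4"]
    out = g.agg(mean_fc4="mean", sd_fc4=lambda s: s.std(ddof=1), n_samples="size").reset_index()
    out["n_samples"] = out["n_samples"].astype(int)
    return out


def local_estimates(samples: pd.DataFrame, config: MixingConfig | None = None) -> pd.DataFrame:
    """Per (species, community) mean/SD dietary grass fraction.

    SD uses the n−1 denominator; single-sample cells carry NaN SD, resolved
    later by :func:`fill_sd`.
    """
    out = _estimates(samples, ["community", "species"], config or MixingConfig())
    out["provenance"] = "local"
    return out


def regional_estimates(samples: pd.DataFrame, config: MixingConfig | None = None) -> pd.DataFrame:
    """Per-species mean/SD over all samples pooled across communities."""
    out = _estimates(samples, ["species"], config or MixingConfig())
    out["provenance"] = "regional"
    return out


def assemble(
    occurrences: pd.DataFrame,
    local: pd.DataFrame,
    regional: pd.DataFrame,
    traits: pd.DataFrame,
    communities: list[str] | None = None,
) -> pd.DataFrame:
    """Build the long-format community diet table with provenance.

    For every (community, species) pair from the occurrence table —
    augmented by species that have local isotope data but are missing from
    the occurrence list, which are taken as present — attach the best
    available diet estimate (local > regional > global-from-traits), the
    species body mass and its natural log.

    Raises ``ValueError`` listing any species with no estimate at any scope
    or without a body mass.
    """
    occ = occurrences[["community", "species"]].drop_duplicates()
    if communities is not None:
        occ = occ[occ["community"].isin(communities)]
        extra = local.loc[local["community"].isin(communities), ["community", "species"]]
    else:
        extra = local[["community", "species"]]
    # species sampled locally but absent from the occurrence list count as present
    occ = pd.concat([occ, extra]).drop_duplicates().reset_index(drop=True)

    est = occ.merge(
        local[["community", "species", "mean_fc4", "sd_fc4", "n_samples", "provenance"]],
        on=["community", "species"],
        how="left",
    )

    reg = regional.set_index("species")
    need = est["mean_fc4"].isna()
    have_reg = est["species"].isin(reg.index)
    fill = need & have_reg
    for col in ("mean_fc4", "sd_fc4", "n_samples"):
        est.loc[fill, col] = reg.loc[est.loc[fill, "species"], col].to_numpy()
    est.loc[fill, "provenance"] = "regional"

    tr = traits.set_index("species")
    need = est["mean_fc4"].isna()
    if "global_fc4" in tr.columns:
        glb = tr["global_fc4"].dropna()
        fill = need & est["species"].isin(glb.index)
        est.loc[fill, "mean_fc4"] = glb.loc[est.loc[fill, "species"]].to_numpy()
        if "global_fc4_sd" in tr.columns:
            est.loc[fill, "sd_fc4"] = tr["global_fc4_sd"].reindex(
                est.loc[fill, "species"]
            ).to_numpy()
        est.loc[fill, "n_samples"] = 0
        est.loc[fill, "provenance"] = "global"

    orphans = sorted(est.loc[est["mean_fc4"].isna(), "species"].unique())
    if orphans:
        raise ValueError(f"no diet estimate at any scope for species: {orphans}")

    no_mass = sorted(set(est["species"]) - set(tr.index[tr["body_mass_kg"].notna()]))
    if no_mass:
        raise ValueError(f"missing body mass for species: {no_mass}")
    est["body_mass_kg"] = tr["body_mass_kg"].reindex(est["species"]).to_numpy(dtype=float)
    est["log_mass"] = np.log(est["body_mass_kg"])  # natural log
    est["n_samples"] = est["n_samples"].fillna(0).astype(int)
    return est


def fill_sd(table: pd.DataFrame, regional: pd.DataFrame) -> pd.DataFrame:
    """Resolve undefined or zero SDs so inverse-variance weights are finite.

    Cells with a single sample (SD undefined) or zero spread borrow the
    species' regional SD; if that too is missing or zero, the median of all
    positive SDs in the table is used.
    """
    out = table.copy()
    sd = out["sd_fc4"].to_numpy(dtype=float)
    bad = ~np.isfinite(sd) | (sd <= 0)
    if bad.any():
        reg_sd = regional.set_index("species")["sd_fc4"]
        borrowed = reg_sd.reindex(out.loc[bad, "species"]).to_numpy(dtype=float)
        sd[bad] = borrowed
        bad = ~np.isfinite(sd) | (sd <= 0)
        if bad.any():
            pool = sd[np.isfinite(sd) & (sd > 0)]
            fallback = float(np.median(pool)) if pool.size else 1.0
            sd[bad] = fallback
    out["sd_fc4"] = sd
    return out


def community_summaries(
    members: pd.DataFrame, exclude_pure_browsers: bool = False
) -> tuple[int, float, bool]:
    """(species richness, unweighted mean grass fraction, elephant presence).

    ``exclude_pure_browsers`` drops members with a grass fraction of exactly
    zero before summarising. Elephant presence is any member of genus
    Loxodonta.
    """
    df = members
    if exclude_pure_browsers:
        df = df[df["mean_fc4"] > 0]
    if not len(df):
        raise ValueError("community empty after filtering")
    elephant = bool(df["species"].str.split().str[0].eq(ELEPHANT_GENUS).any())
    return int(len(df)), float(df["mean_fc4"].mean()), elephant


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    if not {"community", "species"} <= set(df.columns):
        raise ValueError(f"occurrences CSV {path} needs columns community, species")
    return df[["community", "species"]].apply(lambda s: s.str.strip())


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=str.strip)
    if not {"species", "body_mass_kg"} <= set(df.columns):
        raise ValueError(f"traits CSV {path} needs columns species, body_mass_kg")
    df["species"] = df["species"].astype(str).str.strip()
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=str.strip)
    required = {"community", "lat", "lon", "MARain", "RainS", "MATemp", "TempS", "Woody_cover"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariates CSV {path} missing column(s): {sorted(missing)}")
    df["community"] = df["community"].astype(str).str.strip()
    return df
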