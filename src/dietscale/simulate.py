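"""Seed-reproducible synthetic savanna-herbivore datasets with known truth.

Emulates the structure of an eastern-African isotope/community compilation:
~23 communities with environmental covariates, a species pool of ~57 large
herbivores with log-uniform body masses, community occurrence lists, and
per-specimen enamel-equivalent δ13C values generated by inverting the
mixing model. The generating model mirrors the community-assembly patterns
the analysis is designed to detect:

* each community's true diet–mass slope (logit grass fraction per ln kg)
  declines with rainfall seasonality and with elephant presence;
* each community's mean grass dependence is a downward parabola in woody
  cover, peaking at intermediate (0.5) cover;
* small herbivores (<10 kg) are forced toward browsing, and elephants are
  very large but eat little grass;
* a configurable fraction of species-community cells is withheld from the
  isotope table so that regional/global fill-in is exercised.

Ground truth (true slopes, intercepts and per-cell grass fractions) is
returned alongside the data so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .mixing import MixingConfig, delta_from_fraction

__all__ = ["SimConfig", "GroundTruth", "simulate_covariates",
           "simulate_community_diets", "simulate_isotopes", "simulate_dataset"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the study-scale conditions."""

    n_communities: int = 23
    species_pool_size: int = 57
    mean_richness: int = 25
    mass_range_kg: tuple[float, float] = (1.0, 4500.0)  # log-uniform
    # community slope model, on standardized predictors (logit per ln kg)
    slope_beta0: float = 0.6
    slope_beta_rains: float = -0.3
    slope_beta_elephant: float = -0.5
    slope_noise_sd: float = 0.1
    # community intercept model: parabola in woody cover, peak at 0.5
    intercept_base: float = 0.5
    intercept_curvature: float = 6.0
    intercept_noise_sd: float = 0.2
    woody_peak: float = 0.5
    isotope_noise_sd: float = 1.5  # per-sample ‰
    samples_per_cell: float = 5.0  # Poisson mean, min 1
    missing_local_fraction: float = 0.25
    elephant_prob: float = 0.78
    browser_mass_kg: float = 10.0  # below this, grass fraction capped low
    browser_fc4_cap: float = 0.15
    elephant_fc4: float = 0.2
    seed: int = 0
    mixing: MixingConfig = field(default_factory=MixingConfig)

    def __post_init__(self) -> None:
        for name in ("slope_noise_sd", "intercept_noise_sd", "isotope_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("missing_local_fraction", "elephant_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class GroundTruth:
    """Generating parameters and per-cell true grass fractions."""

    community_effects: pd.DataFrame  # community, true_slope, true_intercept, elephant
    true_fc4: pd.DataFrame  # community, species, fc4
    coefficients: dict


def _rng(config: SimConfig, seed: int | None, stream: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def simulate_covariates(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-community environmental covariates and coordinates.

    MARain ~ U(200, 1600) mm/yr; woody cover is built from standardized
    MARain plus independent noise (target correlation ≈ 0.6, mimicking the
    rain–tree-cover collinearity of real savannas) and clipped to
    (0.02, 0.95); RainS (CV %, U(30, 120)), MATemp (U(14, 28) °C) and
    TempS (U(0.5, 4) °C) are independent; coordinates scatter over a
    0–15° box.
    """
    if config.n_communities < 2:
        raise ValueError("need at least 2 communities")
    rng = _rng(config, seed, 1)
    n = config.n_communities
    ma_rain = rng.uniform(200.0, 1600.0, n)
    z_rain = (ma_rain - ma_rain.mean()) / ma_rain.std()
    woody_raw = 0.3 * z_rain + 0.4 * rng.standard_normal(n)  # corr 0.3/0.5 = 0.6
    # scale spans the real gradient from semi-desert (~0.05) to closed forest (~0.9)
    woody = np.clip(0.45 + 0.45 * woody_raw, 0.02, 0.95)
    return pd.DataFrame(
        {
            "community": [f"C{i:03d}" for i in range(n)],
            "lat": rng.uniform(0.0, 15.0, n) - 7.5,
            "lon": rng.uniform(0.0, 15.0, n) + 25.0,
            "MARain": ma_rain,
            "RainS": rng.uniform(30.0, 120.0, n),
            "MATemp": rng.uniform(14.0, 28.0, n),
            "TempS": rng.uniform(0.5, 4.0, n),
            "Woody_cover": woody,
        }
    )


def simulate_community_diets(
    config: SimConfig, covariates: pd.DataFrame, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Species pool, occurrence lists and true diets per community.

    True logit grass fraction for species s in community c is
    a_c + b_c · (ln m_s − mean ln m), with b_c linear in standardized
    rainfall seasonality and elephant presence, and a_c a downward parabola
    in woody cover. Sub-10-kg species are capped at a browsing-level
    fraction; the elephant (genus Loxodonta, >3000 kg) gets a fixed low
    grass fraction.
    """
    rng = _rng(config, seed, 2)
    n_sp = config.species_pool_size
    lo, hi = np.log(config.mass_range_kg[0]), np.log(config.mass_range_kg[1])
    masses = np.exp(rng.uniform(lo, hi, n_sp))
    species = np.array([f"Simulatus sp{i:03d}" for i in range(n_sp)], dtype=object)
    # one elephant species, very large
    masses[0] = rng.uniform(3200.0, 4400.0)
    species[0] = "Loxodonta africana"
    log_mass = np.log(masses)
    center = log_mass.mean()

    rain_s = covariates["RainS"].to_numpy(dtype=float)
    z_rains = (rain_s - rain_s.mean()) / rain_s.std()
    woody = covariates["Woody_cover"].to_numpy(dtype=float)
    comms = covariates["community"].tolist()

    elephant_present = rng.random(len(comms)) < config.elephant_prob
    slopes = (
        config.slope_beta0
        + config.slope_beta_rains * z_rains
        + config.slope_beta_elephant * elephant_present
        + rng.normal(0.0, config.slope_noise_sd, len(comms))
    )
    intercepts = (
        config.intercept_base
        - config.intercept_curvature * (woody - config.woody_peak) ** 2
        + rng.normal(0.0, config.intercept_noise_sd, len(comms))
    )

    occ_rows, truth_rows = [], []
    for ci, comm in enumerate(comms):
        richness = int(np.clip(rng.poisson(config.mean_richness), 5, n_sp))
        non_elephant = rng.choice(np.arange(1, n_sp), size=min(richness, n_sp - 1), replace=False)
        if elephant_present[ci]:
            members = np.sort(np.concatenate([[0], non_elephant]))
        else:
            members = np.sort(non_elephant)
        eta = intercepts[ci] + slopes[ci] * (log_mass[members] - center)
        f = expit(eta)
        small = masses[members] < config.browser_mass_kg
        f[small] = np.minimum(f[small], config.browser_fc4_cap)
        f[members == 0] = config.elephant_fc4
        for m, fv in zip(members, f):
            occ_rows.append((comm, species[m]))
            truth_rows.append((comm, species[m], float(fv)))

    occurrences = pd.DataFrame(occ_rows, columns=["community", "species"])
    truth = pd.DataFrame(truth_rows, columns=["community", "species", "fc4"])
    # species-level global diet values (pool-wide truth) back every species
    sp_mean = truth.groupby("species")["fc4"].mean()
    traits = pd.DataFrame(
        {
            "species": species,
            "order": np.where(species == "Loxodonta africana", "Proboscidea", "Artiodactyla"),
            "body_mass_kg": masses,
            "global_fc4": sp_mean.reindex(species).fillna(0.1).to_numpy(),
            "global_fc4_sd": 0.15,
        }
    )
    effects = pd.DataFrame(
        {
            "community": comms,
            "true_slope": slopes,
            "true_intercept": intercepts,
            "elephant": elephant_present,
        }
    )
    coeffs = {
        "slope_beta0": config.slope_beta0,
        "slope_beta_rains": config.slope_beta_rains,
        "slope_beta_elephant": config.slope_beta_elephant,
        "intercept_curvature": config.intercept_curvature,
    }
    return occurrences, traits, GroundTruth(effects, truth, coeffs)


def simulate_isotopes(
    truth: GroundTruth, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-specimen enamel-equivalent δ13C samples from the true diets.

    Each species-community cell yields max(1, Poisson(mean)) samples at the
    cell's true δ plus Gaussian analytical/individual noise, truncated to
    the enamel endmember interval (truncation, not clamping, keeps samples
    physical without piling mass on the endpoints). A random
    ``missing_local_fraction`` of cells is withheld entirely to exercise
    regional/global fill-in downstream.
    """
    rng = _rng(config, seed, 3)
    mix = config.mixing
    e3, e4 = mix.enamel_c3, mix.enamel_c4
    cells = truth.true_fc4.reset_index(drop=True)
    withheld = rng.random(len(cells)) < config.missing_local_fraction
    rows = []
    sid = 0
    for (comm, sp, fc4), hide in zip(cells.itertuples(index=False), withheld):
        if hide:
            continue
        n = max(1, int(rng.poisson(config.samples_per_cell)))
        mu = delta_from_fraction(float(fc4), mix)
        sd = config.isotope_noise_sd
        if sd > 0:
            a, b = (e3 - mu) / sd, (e4 - mu) / sd
            deltas = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        else:
            deltas = np.full(n, mu)
        for d in deltas:
            rows.append((f"S{sid:06d}", sp, comm, float(d)))
            sid += 1
    return pd.DataFrame(rows, columns=["sample_id", "species", "community", "d13C_enamel"])


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> dict:
    """Generate the full bundle: covariates, occurrences, traits, samples, truth."""
    config = config or SimConfig()
    covariates = simulate_covariates(config, seed)
    occurrences, traits, truth = simulate_community_diets(config, covariates, seed)
    samples = simulate_isotopes(truth, config, seed)
    return {
        "config": config,
        "covariates": covariates,
        "occurrences": occurrences,
        "traits": traits,
        "samples": samples,
        "ground_truth": truth,
    }
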