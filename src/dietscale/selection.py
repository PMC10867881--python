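"""Second-stage model selection for the drivers of diet–mass scaling.

Per-community quantities from the first stage — the diet–body-mass slope
and the community-mean grass fraction — and per-species grass fractions
across communities are modelled against environmental predictors (MARain,
RainS, MATemp, TempS, Woody_cover, with second-order terms for MARain and
Woody_cover) and herbivore-community predictors (PCoA1, PCoA2, SpN,
mean_C4, Elephant). Inference is information-theoretic throughout:

* all subsets of each predictor set are fitted, excluding any model that
  contains a significantly correlated pair (|r| > .5 and p < .05) and any
  second-order term without its first-order parent;
* a spatial covariance structure (none / exponential / gaussian /
  spherical on great-circle distance) is chosen once per model set by AICc
  on the global model, then held fixed;
* models within 2 AICc units of the best are the 'equally plausible' set,
  summarised by how often each term appears and whether its sign is
  consistent.

Responses are weighted by their first-stage uncertainty (1/SE² for slopes,
1/SD² for diet fractions), entering GLS as per-observation variance
scalers. Estimation is maximum likelihood so AICc values are comparable
across models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import pearsonr

__all__ = [
    "SpatialStructure",
    "GLSFit",
    "PREDICTOR_SETS",
    "POLY_BASES",
    "haversine_km",
    "standardize_predictors",
    "collinear_pairs",
    "enumerate_models",
    "fit_gls",
    "select_spatial_structure",
    "rank_models",
    "run_second_stage",
    "term_summary",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

ENV_TERMS = ["MARain", "RainS", "MATemp", "TempS", "Woody_cover"]
COMMUNITY_TERMS = ["PCoA1", "PCoA2", "SpN", "mean_C4", "Elephant"]
#: predictors that carry a second-order polynomial term in the env sets
POLY_BASES = ("MARain", "Woody_cover")

PREDICTOR_SETS: dict[str, list[str]] = {
    "environment": ENV_TERMS + [f"{b}^2" for b in POLY_BASES],
    "community": COMMUNITY_TERMS,
    "combined": ENV_TERMS + [f"{b}^2" for b in POLY_BASES] + COMMUNITY_TERMS,
}

#: tie-break preference order for spatial structures
STRUCTURE_ORDER = ("none", "exponential", "gaussian", "spherical")


@dataclass(frozen=True)
class SpatialStructure:
    """Residual spatial correlation as a function of great-circle distance.

    ``kind='none'`` is iid; otherwise correlation decays with distance d
    (km) at the fitted range r: exponential exp(−d/r), gaussian
    exp(−(d/r)²), spherical 1 − 1.5(d/r) + 0.5(d/r)³ truncated at 0 beyond
    the range. Nugget fixed at 0.
    """

    kind: str = "none"
    range_km: float | None = None

    def correlation(self, dist: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.eye(dist.shape[0])
        r = self.range_km
        if r is None or r <= 0:
            raise ValueError("spatial structure needs a positive range")
        h = dist / r
        if self.kind == "exponential":
            C = np.exp(-h)
        elif self.kind == "gaussian":
            C = np.exp(-(h**2))
        elif self.kind == "spherical":
            C = np.where(h < 1.0, 1.0 - 1.5 * h + 0.5 * h**3, 0.0)
        else:
            raise ValueError(f"unknown spatial structure {self.kind!r}")
        np.fill_diagonal(C, 1.0)
        return C

    @property
    def n_extra_params(self) -> int:
        return 0 if self.kind == "none" else 1


@dataclass
class GLSFit:
    coefficients: pd.Series
    se: pd.Series
    sigma2: float
    structure: SpatialStructure
    loglik: float
    k: int
    n: int
    aicc: float
    fitted: np.ndarray


def haversine_km(lat, lon) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) from decimal degrees."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def standardize_predictors(predictors: pd.DataFrame, poly_bases=POLY_BASES) -> pd.DataFrame:
    """Z-score continuous predictors and append raw second-order terms.

    Binary 0/1 columns (e.g. Elephant) are left on their natural scale.
    Polynomial columns are squares of the standardized base so coefficients
    stay comparable across terms.
    """
    out = pd.DataFrame(index=predictors.index)
    for col in predictors.columns:
        v = predictors[col].to_numpy(dtype=float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            out[col] = v
            continue
        sd = v.std(ddof=0)
        out[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    for b in poly_bases:
        if b in out.columns:
            out[f"{b}^2"] = out[b] ** 2
    return out


def _poly_pair(a: str, b: str) -> bool:
    return a == f"{b}^2" or b == f"{a}^2"


def collinear_pairs(
    predictors: pd.DataFrame, r_threshold: float = 0.5, alpha: float = 0.05
) -> set[frozenset]:
    """Pairs of predictors that may not co-occur in one model.

    A pair is forbidden iff its Pearson |r| exceeds ``r_threshold`` AND the
    correlation is significant at ``alpha``. A second-order term is never
    forbidden against its own base. Constant columns are excluded with a
    warning (they cannot enter any model meaningfully).
    """
    cols = []
    for c in predictors.columns:
        if predictors[c].nunique() <= 1:
            logger.warning("constant predictor %r excluded from collinearity screen", c)
            continue
        cols.append(c)
    forbidden: set[frozenset] = set()
    for a, b in combinations(cols, 2):
        if _poly_pair(a, b):
            continue
        r, p = pearsonr(predictors[a], predictors[b])
        if abs(r) > r_threshold and p < alpha:
            forbidden.add(frozenset((a, b)))
    return forbidden


def enumerate_models(
    terms: list[str], forbidden: set[frozenset], max_terms: int | None = None
) -> list[tuple[str, ...]]:
    """All term subsets (incl. the null model) respecting the constraints.

    Constraints: no subset contains a forbidden pair; a second-order term
    appears only together with its first-order parent (hierarchy rule).
    """
    models: list[tuple[str, ...]] = []
    upper = len(terms) if max_terms is None else min(max_terms, len(terms))
    for size in range(upper + 1):
        for combo in combinations(terms, size):
            chosen = set(combo)
            if any(frozenset(p) <= chosen for p in forbidden):
                continue
            if any(t.endswith("^2") and t[:-2] not in chosen for t in chosen):
                continue
            models.append(combo)
    return models


def _gls_profile(y, X, w, Lam):
    """Profile ML for fixed correlation: returns (beta, sigma2, loglik, XtVinvX_inv)."""
    n = y.size
    L = np.linalg.cholesky(Lam)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    return beta, sigma2, loglik, np.linalg.inv(XtX)


def fit_gls(
    y,
    design: pd.DataFrame | np.ndarray,
    weights=None,
    structure: SpatialStructure | None = None,
    coords: pd.DataFrame | None = None,
    range_bounds: tuple[float, float] = (1.0, 20000.0),
) -> GLSFit:
    """Maximum-likelihood (weighted, optionally spatial) linear regression.

    The residual covariance is σ²·Λ with Λ = V^{1/2} C V^{1/2}, where
    V = diag(1/w) scales per-observation variances and C is the spatial
    correlation at the (profiled-out) range. With ``kind='none'`` and unit
    weights this reduces exactly to ordinary least squares. ``k`` counts
    coefficients, σ², and the range when present.
    """
    structure = structure or SpatialStructure()
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    k = X.shape[1] + 1 + structure.n_extra_params
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} parameters (AICc undefined)")

    sqv = 1.0 / np.sqrt(w)

    if structure.kind == "none":
        Lam = np.diag(1.0 / w)
        beta, sigma2, loglik, XtXinv = _gls_profile(y, X, w, Lam)
        fitted_structure = structure
    else:
        if coords is None:
            raise ValueError("spatial structures require community coordinates")
        dist = haversine_km(coords["lat"], coords["lon"])

        def nll_at(log_r):
            C = SpatialStructure(structure.kind, float(np.exp(log_r))).correlation(dist)
            Lam = sqv[:, None] * C * sqv[None, :]
            try:
                return -_gls_profile(y, X, w, Lam)[2]
            except np.linalg.LinAlgError:
                return np.inf

        lo, hi = np.log(range_bounds[0]), np.log(range_bounds[1])
        res = optimize.minimize_scalar(nll_at, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-4})
        r_hat = float(np.exp(res.x))
        fitted_structure = SpatialStructure(structure.kind, r_hat)
        C = fitted_structure.correlation(dist)
        Lam = sqv[:, None] * C * sqv[None, :]
        try:
            beta, sigma2, loglik, XtXinv = _gls_profile(y, X, w, Lam)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular spatial correlation matrix; try a larger range floor"
            ) from exc

    se = np.sqrt(np.clip(np.diag(XtXinv) * sigma2, 0, None))
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return GLSFit(
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma2=sigma2,
        structure=fitted_structure,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc,
        fitted=X @ beta,
    )


def _design(predictors: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"(intercept)": np.ones(len(predictors))}, index=predictors.index)
    for t in terms:
        X[t] = predictors[t].to_numpy(dtype=float)
    return X


def _resolve_global_terms(terms: list[str], forbidden: set[frozenset], predictors) -> list[str]:
    """Greedy forbidden-pair resolution for the global (structure-selection) model.

    While any forbidden pair remains, drop the member with the larger mean
    absolute correlation to all other retained terms.
    """
    kept = list(terms)
    def mean_abs_corr(t):
        others = [o for o in kept if o != t]
        return np.mean([abs(pearsonr(predictors[t], predictors[o])[0]) for o in others])
    while True:
        live = [p for p in forbidden if frozenset(p) <= set(kept)]
        if not live:
            return kept
        pair = sorted(sorted(live, key=lambda p: tuple(sorted(p)))[0])
        drop = max(pair, key=mean_abs_corr)
        kept = [t for t in kept if t != drop and not (t == f"{drop}^2")]


def select_spatial_structure(
    y,
    predictors: pd.DataFrame,
    global_terms: list[str],
    weights,
    coords,
    candidates: tuple[str, ...] = STRUCTURE_ORDER,
) -> tuple[SpatialStructure, pd.DataFrame]:
    """Choose the residual correlation structure by AICc on the global model.

    Ties break toward the simpler structure in the order none, exponential,
    gaussian, spherical. Returns the winning structure (with its fitted
    range) and the per-candidate AICc table.
    """
    n = len(predictors)
    global_terms = list(global_terms)
    # trim the global model (second-order terms first) if the sample is too
    # small to fit every term alongside sigma^2 and a range parameter
    while global_terms and n <= (len(global_terms) + 1) + 2 + 1:
        drop = next((t for t in reversed(global_terms) if t.endswith("^2")), global_terms[-1])
        logger.warning("global model too large for n=%d; dropping %r", n, drop)
        global_terms.remove(drop)
    X = _design(predictors, tuple(global_terms))
    rows, fits = [], {}
    for kind in candidates:
        try:
            fit = fit_gls(y, X, weights, SpatialStructure(kind, 1.0 if kind != "none" else None),
                          coords)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("structure %s failed on global model: %s", kind, exc)
            continue
        fits[kind] = fit
        rows.append((kind, fit.structure.range_km, fit.aicc))
    if not fits:
        raise ValueError("no spatial structure could be fitted to the global model")
    table = pd.DataFrame(rows, columns=["kind", "range_km", "aicc"])
    best_aicc = table["aicc"].min()
    for kind in STRUCTURE_ORDER:  # tie-break order
        if kind in fits and fits[kind].aicc <= best_aicc + 1e-9:
            return fits[kind].structure, table
    raise AssertionError("unreachable")


def rank_models(
    models: list[tuple[str, ...]],
    predictors: pd.DataFrame,
    y,
    weights,
    structure: SpatialStructure,
    coords=None,
) -> pd.DataFrame:
    """Fit every candidate model and rank by AICc.

    Returns one row per model with terms, k, logLik, AICc, ΔAICc from the
    best, plausibility (ΔAICc < 2), and coefficient/SE dictionaries.
    Models too large for the sample (n ≤ k+1) are skipped with a warning.
    """
    rows = []
    for terms in models:
        X = _design(predictors, terms)
        try:
            fit = fit_gls(y, X, weights, structure, coords)
        except ValueError as exc:
            logger.warning("skipping model %s: %s", terms, exc)
            continue
        rows.append(
            {
                "terms": terms,
                "k": fit.k,
                "loglik": fit.loglik,
                "aicc": fit.aicc,
                "coefficients": fit.coefficients.to_dict(),
                "se": fit.se.to_dict(),
                "spatial_structure": fit.structure.kind,
                "range_km": fit.structure.range_km,
            }
        )
    if not rows:
        raise ValueError("no candidate model could be fitted")
    ranked = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    ranked["delta_aicc"] = ranked["aicc"] - ranked["aicc"].iloc[0]
    ranked["plausible"] = ranked["delta_aicc"] < 2.0
    return ranked


def term_summary(ranked: pd.DataFrame) -> pd.DataFrame:
    """Appearance counts and sign consistency of terms in the plausible set."""
    plaus = ranked[ranked["plausible"]]
    terms: dict[str, list[float]] = {}
    for _, row in plaus.iterrows():
        for t in row["terms"]:
            terms.setdefault(t, []).append(row["coefficients"][t])
    rows = []
    for t, coefs in sorted(terms.items()):
        signs = np.sign(coefs)
        rows.append(
            {
                "term": t,
                "n_plausible_models": len(coefs),
                "n_models_total": int(len(plaus)),
                "mean_coefficient": float(np.mean(coefs)),
                "sign_consistent": bool(np.all(signs == signs[0])),
            }
        )
    return pd.DataFrame(rows, columns=["term", "n_plausible_models", "n_models_total",
                                       "mean_coefficient", "sign_consistent"])


def run_second_stage(
    response: pd.Series,
    predictors: pd.DataFrame,
    weights: pd.Series | np.ndarray | None,
    coords: pd.DataFrame,
    response_kind: str = "slope",
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    candidate_structures: tuple[str, ...] = STRUCTURE_ORDER,
    predictor_sets: dict[str, list[str]] | None = None,
) -> dict[str, dict]:
    """All-subsets AICc selection over the three predictor sets.

    ``predictors`` holds the raw per-community values for all ten base
    predictors (plus lat/lon in ``coords``); standardization and polynomial
    expansion happen here. For ``response_kind='mean_c4'`` the community
    mean grass fraction is removed from the community/combined sets (a
    response cannot predict itself). Rows are aligned on
    ``response.index``.

    Returns, per predictor set: the chosen spatial structure, the structure
    AICc table, the full ranking, and the plausible-set term summary.
    """
    predictor_sets = predictor_sets or PREDICTOR_SETS
    idx = response.index
    preds = standardize_predictors(predictors.loc[idx])
    coords = coords.loc[idx]
    w = None if weights is None else np.asarray(pd.Series(weights).loc[idx], dtype=float)
    forbidden = collinear_pairs(preds, r_threshold=r_threshold, alpha=alpha)

    results: dict[str, dict] = {}
    for set_name, terms in predictor_sets.items():
        terms = [t for t in terms if t in preds.columns]
        if response_kind == "mean_c4":
            terms = [t for t in terms if t != "mean_C4"]
        global_terms = _resolve_global_terms(terms, forbidden, preds)
        structure, struct_table = select_spatial_structure(
            response.to_numpy(dtype=float), preds, global_terms, w, coords,
            candidates=candidate_structures,
        )
        models = enumerate_models(terms, forbidden)
        ranked = rank_models(models, preds, response.to_numpy(dtype=float), w, structure, coords)
        results[set_name] = {
            "structure": structure,
            "structure_table": struct_table,
            "ranking": ranked,
            "summary": term_summary(ranked),
        }
    return results
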