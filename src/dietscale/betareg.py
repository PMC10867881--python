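"""Weighted beta regression with a logit mean link and constant precision.

Dietary grass fractions live on (0, 1), so the diet–body-mass relationship
within each community is modelled with the beta distribution: y_i ~
Beta(μ_i φ, (1−μ_i) φ) with logit(μ_i) = x_iᵀβ and a single precision φ > 0
shared across communities. All communities are fitted jointly in one
interaction model — per-community intercepts and per-community log-mass
slopes — so that coefficient errors account for the simultaneous
comparisons. Per-observation weights w_i (inverse variance of the
species-level diet estimate) multiply the log-likelihood contributions:

    ℓ(β, φ) = Σ_i w_i · log Beta(y_i; μ_i φ, (1−μ_i) φ)

Estimation is maximum likelihood: a weighted-least-squares start on
logit(y), quasi-Newton iteration with the analytic gradient, and a Newton
polish to drive the gradient norm below 1e-6. The coefficient covariance is
the inverse observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm, pearsonr

__all__ = [
    "BetaRegSpec",
    "BetaRegFit",
    "ConvergenceError",
    "adjust_boundaries",
    "weights_from_sd",
    "build_interaction_design",
    "beta_loglik",
    "fit_betareg",
    "fit_interaction_model",
    "extract_slopes",
    "compare_orders",
    "refit_excluding",
]

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-6
BOUNDARY_EPS = 1e-3  # 0 -> .001, 1 -> .999


class ConvergenceError(RuntimeError):
    """Raised when the likelihood maximizer fails; carries the last iterate."""

    def __init__(self, msg: str, params: np.ndarray, grad_norm: float):
        super().__init__(f"{msg} (gradient norm {grad_norm:.3g})")
        self.params = params
        self.grad_norm = grad_norm


@dataclass
class BetaRegSpec:
    """A fully materialized fitting problem.

    ``y`` must already be boundary-adjusted (strictly inside (0, 1));
    ``design`` is the observation × coefficient matrix; ``weights`` are
    positive per-observation likelihood multipliers.
    """

    y: np.ndarray
    design: np.ndarray
    weights: np.ndarray
    order: int = 1
    colnames: list[str] = field(default_factory=list)
    communities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.y <= 0) or np.any(self.y >= 1):
            raise ValueError("response must be strictly inside (0,1); adjust boundaries first")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("design matrix is rank deficient")


@dataclass
class BetaRegFit:
    """Joint interaction-model fit."""

    coefficients: pd.Series  # indexed by design column name
    phi: float
    covariance: np.ndarray  # over (β, log φ)
    loglik: float
    k: int
    n: int
    aicc: float
    rmse: float
    pseudo_r2: float
    order: int
    communities: list[str]
    mu: np.ndarray
    eta: np.ndarray
    spec: BetaRegSpec
    grad_norm: float
    n_iter: int

    @property
    def se(self) -> pd.Series:
        p = len(self.coefficients)
        return pd.Series(np.sqrt(np.diag(self.covariance)[:p]), index=self.coefficients.index)


def adjust_boundaries(y, eps: float = BOUNDARY_EPS) -> np.ndarray:
    """Move exact 0s and 1s just inside the unit interval (0→.001, 1→.999)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1) or not np.all(np.isfinite(y)):
        raise ValueError("fractions must lie in [0,1]")
    out = y.copy()
    out[out == 0.0] = eps
    out[out == 1.0] = 1.0 - eps
    return out


def weights_from_sd(sd, transform: str = "inv_var", normalize: bool = True) -> np.ndarray:
    """Likelihood weights from per-estimate standard deviations.

    ``inv_var`` gives w ∝ 1/sd² (the inverse-variance convention);
    ``inv_sd`` gives w ∝ 1/sd as a sensitivity alternative. Weights are
    normalized to mean 1 so the weighted likelihood stays on the same scale
    as the unweighted one and fits are invariant to rescaling all SDs.
    """
    sd = np.asarray(sd, dtype=float)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError("SDs must be finite and positive (use fill_sd upstream)")
    if transform == "inv_var":
        w = 1.0 / sd**2
    elif transform == "inv_sd":
        w = 1.0 / sd
    else:
        raise ValueError(f"unknown weight transform {transform!r}")
    return w / w.mean() if normalize else w


def build_interaction_design(
    table: pd.DataFrame, order: int = 1
) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Community × log-mass interaction design matrix.

    One indicator column per community plus indicator×log_mass (and
    indicator×log_mass² for ``order=2``), i.e. ``(order+1)·C`` columns; with
    the precision φ the model has ``(order+1)·C + 1`` free parameters.
    Communities with fewer than two distinct log-mass values cannot carry a
    slope and are excluded with a warning. Returns (X, column names, kept
    community codes, row mask into ``table``).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 (linear) or 2 (parabolic)")
    n_distinct = table.groupby("community")["log_mass"].nunique()
    dropped = sorted(n_distinct.index[n_distinct < 2])
    if dropped:
        logger.warning("excluding single-species communities from slope estimation: %s", dropped)
    keep = sorted(n_distinct.index[n_distinct >= 2])
    mask = table["community"].isin(keep).to_numpy()
    sub = table[mask]
    cols, names = [], []
    comm = sub["community"].to_numpy()
    lm = sub["log_mass"].to_numpy(dtype=float)
    for c in keep:
        ind = (comm == c).astype(float)
        cols.append(ind)
        names.append(f"intercept[{c}]")
        for d in range(1, order + 1):
            cols.append(ind * lm**d)
            names.append(f"logmass{'^%d' % d if d > 1 else ''}[{c}]")
    X = np.column_stack(cols)
    return X, names, keep, mask


def beta_loglik(params: np.ndarray, y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """Weighted beta log-likelihood at (β, log φ)."""
    beta, logphi = params[:-1], params[-1]
    phi = np.exp(logphi)
    mu = special.expit(X @ beta)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(np.sum(w * ll))


def _grad(params: np.ndarray, y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    beta, logphi = params[:-1], params[-1]
    phi = np.exp(logphi)
    mu = special.expit(X @ beta)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    g_beta = X.T @ (w * phi * (ystar - mustar) * mu * (1.0 - mu))
    g_phi = np.sum(
        w
        * (
            special.digamma(phi)
            - mu * special.digamma(mu * phi)
            - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
            + mu * np.log(y)
            + (1.0 - mu) * np.log1p(-y)
        )
    )
    return np.append(g_beta, g_phi * phi)  # chain rule for log φ


def _num_hessian(params, y, X, w, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = params.size
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = h * max(1.0, abs(params[j]))
        H[:, j] = (_grad(params + step, y, X, w) - _grad(params - step, y, X, w)) / (2 * step[j])
    return (H + H.T) / 2.0


def _start_values(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    z = np.log(y) - np.log1p(-y)
    W = w / w.mean()
    XtW = X.T * W
    beta0 = np.linalg.solve(XtW @ X, XtW @ z)
    mu0 = special.expit(X @ beta0)
    resid = z - X @ beta0
    # method-of-moments precision from link-scale residual variance:
    # Var(y) ≈ μ(1−μ)/(1+φ) and Var(z) ≈ Var(y)/(μ(1−μ))²
    sigma2 = float(np.sum(W * resid**2) / max(y.size - X.shape[1], 1))
    phi0 = max(float(np.mean(1.0 / (sigma2 * mu0 * (1.0 - mu0)))) - 1.0, 1.0)
    return np.append(beta0, np.log(phi0))


def fit_betareg(spec: BetaRegSpec, max_iter: int = 500) -> BetaRegFit:
    """Maximize the weighted beta log-likelihood for a materialized spec.

    BFGS from the weighted-least-squares start, followed by Newton steps
    until the gradient norm falls below 1e-6. Raises
    :class:`ConvergenceError` (carrying the last iterate) on failure.
    """
    y, X, w = spec.y, spec.design, spec.weights
    x0 = _start_values(y, X, w)

    nll = lambda p: -beta_loglik(p, y, X, w)
    njac = lambda p: -_grad(p, y, X, w)
    res = optimize.minimize(nll, x0, jac=njac, method="BFGS",
                            options={"maxiter": max_iter, "gtol": 1e-8})
    params = res.x
    n_iter = int(res.nit)

    # Newton polish: BFGS's own tolerance is on a scaled gradient
    for _ in range(50):
        g = _grad(params, y, X, w)
        if np.linalg.norm(g) < GRAD_TOL:
            break
        H = _num_hessian(params, y, X, w)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        cand = params - step
        if not np.isfinite(beta_loglik(cand, y, X, w)):
            break
        params = cand
        n_iter += 1
    grad_norm = float(np.linalg.norm(_grad(params, y, X, w)))
    if grad_norm >= GRAD_TOL:
        raise ConvergenceError("beta regression did not converge", params, grad_norm)

    H = _num_hessian(params, y, X, w)
    cov = np.linalg.inv(-H)  # inverse observed information
    ll = beta_loglik(params, y, X, w)
    k = X.shape[1] + 1  # coefficients + precision
    n = y.size
    eta = X @ params[:-1]
    mu = special.expit(eta)
    aicc, rmse, pr2 = fit_metrics(ll, k, n, y, mu, eta)
    return BetaRegFit(
        coefficients=pd.Series(params[:-1], index=spec.colnames or None),
        phi=float(np.exp(params[-1])),
        covariance=cov,
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc,
        rmse=rmse,
        pseudo_r2=pr2,
        order=spec.order,
        communities=spec.communities,
        mu=mu,
        eta=eta,
        spec=spec,
        grad_norm=grad_norm,
        n_iter=n_iter,
    )


def fit_metrics(loglik: float, k: int, n: int, y=None, mu=None, eta=None):
    """(AICc, RMSE, pseudo-R²) for a fitted model.

    AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1). RMSE is on the fraction scale;
    pseudo-R² is the squared Pearson correlation between logit(y) and the
    linear predictor (the convention of standard beta-regression software).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    rmse = pr2 = float("nan")
    if y is not None and mu is not None:
        rmse = float(np.sqrt(np.mean((np.asarray(y) - np.asarray(mu)) ** 2)))
    if y is not None and eta is not None:
        z = special.logit(np.asarray(y))
        if np.std(eta) == 0 or np.std(z) == 0:
            pr2 = 1.0 if rmse == 0.0 else 0.0
        else:
            pr2 = float(pearsonr(z, np.asarray(eta))[0] ** 2)
    return aicc, rmse, pr2


def fit_interaction_model(
    table: pd.DataFrame,
    order: int = 1,
    weight_transform: str = "inv_var",
) -> BetaRegFit:
    """Fit the joint community × log-mass model from a long diet table.

    ``table`` needs columns community, log_mass, mean_fc4, sd_fc4 (SDs
    already resolved to positive values). Responses are boundary-adjusted
    and weighted by :func:`weights_from_sd`.
    """
    X, names, comms, mask = build_interaction_design(table, order=order)
    sub = table[mask]
    y = adjust_boundaries(sub["mean_fc4"].to_numpy())
    w = weights_from_sd(sub["sd_fc4"].to_numpy(), transform=weight_transform)
    spec = BetaRegSpec(y=y, design=X, weights=w, order=order, colnames=names, communities=comms)
    return fit_betareg(spec)


def extract_slopes(fit: BetaRegFit) -> tuple[pd.DataFrame, int, int]:
    """Per-community slope records from an order-1 fit.

    Returns (records, number of positive slopes, number with two-sided
    Wald p < .1). Slopes are d logit(f)/d ln(mass).
    """
    if fit.order != 1:
        raise ValueError("slope extraction requires an order-1 (linear) fit")
    se = fit.se
    # column layout is [intercept[c], logmass[c]] per community
    counts = {
        c: int(fit.spec.design[:, 2 * i].sum()) for i, c in enumerate(fit.communities)
    }
    rows = []
    for c in fit.communities:
        name = f"logmass[{c}]"
        slope = float(fit.coefficients[name])
        s = float(se[name])
        z = slope / s if s > 0 else np.inf * np.sign(slope)
        p = float(2.0 * (1.0 - norm.cdf(abs(z)))) if np.isfinite(z) else 0.0
        rows.append((c, slope, s, p, counts[c]))
    records = pd.DataFrame(rows, columns=["community", "slope", "se", "wald_p", "n_species"])
    return records, int((records["slope"] > 0).sum()), int((records["wald_p"] < 0.1).sum())


def compare_orders(
    table: pd.DataFrame, weight_transform: str = "inv_var"
) -> tuple[int, pd.DataFrame, dict[int, BetaRegFit]]:
    """Fit linear and parabolic log-mass models; pick the lower AICc.

    Ties break toward the linear model. Returns (chosen order, metric
    table, fits by order).
    """
    fits = {o: fit_interaction_model(table, order=o, weight_transform=weight_transform) for o in (1, 2)}
    metrics = pd.DataFrame(
        {
            "order": [1, 2],
            "aicc": [fits[1].aicc, fits[2].aicc],
            "rmse": [fits[1].rmse, fits[2].rmse],
            "loglik": [fits[1].loglik, fits[2].loglik],
            "k": [fits[1].k, fits[2].k],
        }
    )
    chosen = 2 if fits[2].aicc < fits[1].aicc else 1
    return chosen, metrics, fits


def refit_excluding(
    table: pd.DataFrame,
    species: list[str] | None = None,
    predicate=None,
    order: int = 1,
    weight_transform: str = "inv_var",
) -> tuple[BetaRegFit, pd.DataFrame]:
    """Refit after dropping members, and compare per-community slopes.

    Members are dropped when their species is in ``species`` or when
    ``predicate(row)`` is truthy (e.g. pure browsers ``mean_fc4 == 0``).
    Communities left with fewer than two species fall out of the design
    with a warning. Returns the new fit and a paired slope table with
    columns slope_full / slope_excluded / delta.
    """
    mask = pd.Series(False, index=table.index)
    if species:
        mask |= table["species"].isin(species)
    if predicate is not None:
        mask |= table.apply(predicate, axis=1)
    filtered = table[~mask]
    full = fit_interaction_model(table, order=order, weight_transform=weight_transform)
    refit = fit_interaction_model(filtered, order=order, weight_transform=weight_transform)
    s_full, _, _ = extract_slopes(full)
    s_ref, _, _ = extract_slopes(refit)
    cmp = s_full.merge(s_ref, on="community", suffixes=("_full", "_excluded"))
    cmp["delta"] = cmp["slope_excluded"] - cmp["slope_full"]
    return refit, cmp[["community", "slope_full", "slope_excluded", "delta"]]
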