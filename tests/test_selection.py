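from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from dietscale import selection
from dietscale.selection import SpatialStructure


def make_predictors(rng, n=23):
    idx = [f"C{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "MARain": rng.uniform(200, 1600, n),
            "RainS": rng.uniform(30, 120, n),
            "MATemp": rng.uniform(14, 28, n),
            "TempS": rng.uniform(0.5, 4, n),
            "Woody_cover": rng.uniform(0.05, 0.9, n),
            "PCoA1": rng.normal(size=n),
            "PCoA2": rng.normal(size=n),
            "SpN": rng.integers(10, 40, n).astype(float),
            "mean_C4": rng.uniform(0.1, 0.8, n),
            "Elephant": (rng.random(n) < 0.7).astype(float),
        },
        index=idx,
    )
    coords = pd.DataFrame({"lat": rng.uniform(-7.5, 7.5, n), "lon": rng.uniform(25, 40, n)}, index=idx)
    return df, coords


class TestHaversine:
    def test_known_distance(self):
        # one degree of latitude is ~111 km
        d = selection.haversine_km([0.0, 1.0], [30.0, 30.0])
        assert d[0, 1] == pytest.approx(111.2, abs=0.5)
        assert d[0, 0] == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        d = selection.haversine_km(rng.uniform(-10, 10, 5), rng.uniform(20, 40, 5))
        assert np.allclose(d, d.T)


class TestCollinearPairs:
    def test_perfect_correlation_forbidden(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0)})
        assert frozenset(("x", "y")) in selection.collinear_pairs(df)

    def test_independent_normals_allowed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        assert selection.collinear_pairs(df) == set()

    def test_high_r_without_significance_allowed(self):
        # |r| = 0.6 on n=4 has p > 0.05 -> the pair stays allowed
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.5, 0.0, 3.0, 1.5]})
        r = df["x"].corr(df["y"])
        assert abs(r) > 0.5
        assert selection.collinear_pairs(df) == set()

    def test_poly_pair_exempt(self):
        z = np.linspace(-1, 3, 30)
        df = pd.DataFrame({"MARain": z, "MARain^2": z**2})
        assert selection.collinear_pairs(df) == set()

    def test_constant_excluded_with_warning(self, caplog):
        df = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        assert selection.collinear_pairs(df) == set()


class TestEnumerateModels:
    def test_three_free_predictors(self):
        models = selection.enumerate_models(["a", "b", "c"], set())
        assert len(models) == 8

    def test_forbidden_pair_prunes(self):
        models = selection.enumerate_models(["a", "b"], {frozenset(("a", "b"))})
        assert sorted(models) == [(), ("a",), ("b",)]

    def test_hierarchy_rule(self):
        models = selection.enumerate_models(["x", "x^2"], set())
        assert ("x^2",) not in models
        assert ("x", "x^2") in models

    def test_matches_power_set_oracle(self):
        """Enumeration equals brute-force filtering of the full power set."""
        terms = ["a", "b", "c", "d", "d^2"]
        forbidden = {frozenset(("a", "b")), frozenset(("c", "d"))}
        full = chain.from_iterable(combinations(terms, k) for k in range(len(terms) + 1))
        oracle = [
            m for m in full
            if not any(set(p) <= set(m) for p in forbidden)
            and all(t[:-2] in m for t in m if t.endswith("^2"))
        ]
        assert selection.enumerate_models(terms, forbidden) == oracle


class TestFitGls:
    def test_none_unit_weights_equals_ols(self):
        rng = np.random.default_rng(2)
        n = 30
        X = pd.DataFrame({"i": np.ones(n), "x": rng.normal(size=n)})
        y = 2.0 + 1.5 * X["x"].to_numpy() + rng.normal(0, 0.5, n)
        fit = selection.fit_gls(y, X)
        beta_ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert fit.coefficients.to_numpy() == pytest.approx(beta_ols, abs=1e-10)

    def test_weighted_matches_closed_form(self):
        """GLS with diagonal weights equals the WLS normal equations."""
        X = pd.DataFrame({"i": np.ones(6), "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = np.array([0.1, 1.2, 1.9, 3.3, 3.8, 5.2])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        fit = selection.fit_gls(y, X, weights=w)
        W = np.diag(w)
        Xm = X.to_numpy()
        beta = np.linalg.solve(Xm.T @ W @ Xm, Xm.T @ W @ y)
        assert fit.coefficients.to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_k_counts_range_parameter(self):
        rng = np.random.default_rng(3)
        preds, coords = make_predictors(rng, n=20)
        X = pd.DataFrame({"i": np.ones(20)}, index=preds.index)
        y = rng.normal(size=20)
        f0 = selection.fit_gls(y, X)
        f1 = selection.fit_gls(y, X, structure=SpatialStructure("exponential", 100.0), coords=coords)
        assert f1.k == f0.k + 1

    def test_exponential_truth_recovered_by_aicc(self):
        """Spatially correlated residuals favour the exponential structure."""
        rng = np.random.default_rng(4)
        wins = 0
        reps = 30
        for _ in range(reps):
            n = 40
            coords = pd.DataFrame({"lat": rng.uniform(-10, 10, n), "lon": rng.uniform(20, 45, n)})
            dist = selection.haversine_km(coords["lat"], coords["lon"])
            C = np.exp(-dist / 400.0)
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
            y = L @ rng.normal(size=n)
            X = pd.DataFrame({"i": np.ones(n)})
            aiccs = {}
            for kind in ("none", "exponential"):
                st = SpatialStructure(kind, 1.0 if kind != "none" else None)
                aiccs[kind] = selection.fit_gls(y, X, structure=st, coords=coords).aicc
            wins += aiccs["exponential"] < aiccs["none"]
        assert wins >= 0.7 * reps

    def test_aicc_null_model_scale_invariant(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=25)
        X = pd.DataFrame({"i": np.ones(25)})
        a1 = selection.fit_gls(y, X).aicc
        a2 = selection.fit_gls(y, X * 3.0).aicc  # rescaled intercept column
        assert a1 == pytest.approx(a2, abs=1e-10)


class TestSelectStructure:
    def test_iid_truth_selects_none(self):
        rng = np.random.default_rng(6)
        n = 200
        coords = pd.DataFrame({"lat": rng.uniform(-10, 10, n), "lon": rng.uniform(20, 45, n)})
        preds = pd.DataFrame({"x": rng.normal(size=n)}, index=coords.index)
        y = 1.0 + 0.5 * preds["x"].to_numpy() + rng.normal(size=n)
        structure, table = selection.select_spatial_structure(y, preds, ["x"], None, coords)
        assert structure.kind == "none"

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(7)
        preds, coords = make_predictors(rng, n=15)
        y = rng.normal(size=15)
        structure, _ = selection.select_spatial_structure(
            y, selection.standardize_predictors(preds), ["RainS"], None, coords,
            candidates=("spherical",),
        )
        assert structure.kind == "spherical"


class TestRankModels:
    def test_single_model(self):
        rng = np.random.default_rng(8)
        preds, coords = make_predictors(rng, n=15)
        z = selection.standardize_predictors(preds)
        y = rng.normal(size=15)
        ranked = selection.rank_models([("RainS",)], z, y, None, SpatialStructure())
        assert len(ranked) == 1
        assert ranked["delta_aicc"].iloc[0] == 0.0
        assert ranked["plausible"].iloc[0]

    def test_strong_negative_rains_always_plausible(self):
        """A dominant predictor appears in every plausible model, sign intact."""
        rng = np.random.default_rng(9)
        hits = 0
        reps = 30
        for _ in range(reps):
            preds, coords = make_predictors(rng, n=23)
            z = selection.standardize_predictors(preds)
            y = 0.5 - 0.8 * z["RainS"].to_numpy() + rng.normal(0, 0.15, 23)
            models = selection.enumerate_models(["RainS", "MATemp", "TempS"], set())
            ranked = selection.rank_models(models, z, y, None, SpatialStructure())
            plaus = ranked[ranked["plausible"]]
            ok = all("RainS" in t for t in plaus["terms"]) and all(
                row["coefficients"]["RainS"] < 0 for _, row in plaus.iterrows()
            )
            hits += ok
        assert hits >= 0.9 * reps

    def test_null_truth_keeps_null_plausible(self):
        rng = np.random.default_rng(10)
        hits = 0
        reps = 30
        for _ in range(reps):
            preds, _ = make_predictors(rng, n=23)
            z = selection.standardize_predictors(preds)
            y = rng.normal(size=23)
            models = selection.enumerate_models(["RainS", "MATemp"], set())
            ranked = selection.rank_models(models, z, y, None, SpatialStructure())
            null_rows = ranked[ranked["terms"].map(len) == 0]
            hits += bool(null_rows["plausible"].iloc[0])
        assert hits >= 0.6 * reps


class TestRunSecondStage:
    def test_mean_c4_never_predicts_itself(self):
        rng = np.random.default_rng(11)
        preds, coords = make_predictors(rng, n=18)
        y = pd.Series(rng.uniform(0.2, 0.7, 18), index=preds.index)
        res = selection.run_second_stage(y, preds, None, coords, response_kind="mean_c4",
                                         candidate_structures=("none",))
        for set_name, r in res.items():
            for terms in r["ranking"]["terms"]:
                assert "mean_C4" not in terms

    def test_slope_drivers_recovered_in_plausible_set(self):
        """Slopes built from RainS and Elephant surface in the combined set."""
        rng = np.random.default_rng(12)
        preds, coords = make_predictors(rng, n=23)
        z = selection.standardize_predictors(preds)
        y = pd.Series(
            0.6 - 0.3 * z["RainS"].to_numpy() - 0.5 * preds["Elephant"].to_numpy()
            + rng.normal(0, 0.1, 23),
            index=preds.index,
        )
        res = selection.run_second_stage(y, preds, None, coords, response_kind="slope",
                                         candidate_structures=("none",))
        summary = res["combined"]["summary"].set_index("term")
        assert summary.loc["RainS", "mean_coefficient"] < 0
        assert summary.loc["Elephant", "mean_coefficient"] < 0
        n_plaus = summary["n_models_total"].iloc[0]
        assert summary.loc["Elephant", "n_plausible_models"] == n_plaus

    def test_unbiased_coefficient_recovery(self):
        """Second-stage estimates are unbiased over repeated simulations."""
        rng = np.random.default_rng(13)
        reps = 200
        est = []
        for _ in range(reps):
            preds, coords = make_predictors(rng, n=23)
            z = selection.standardize_predictors(preds)
            y = 0.2 - 0.4 * z["RainS"].to_numpy() + rng.normal(0, 0.2, 23)
            X = pd.DataFrame({"i": np.ones(23), "RainS": z["RainS"]})
            est.append(selection.fit_gls(y, X).coefficients["RainS"])
        est = np.asarray(est)
        assert abs(est.mean() + 0.4) < 0.1 * est.std()
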