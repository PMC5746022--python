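import numpy as np
import pandas as pd
import pytest

from herdimpute.acc_model import (
    FULL_CANDIDATES,
    backward_select,
    build_features,
    cv_correlation,
    fit_linear,
    fit_reduced_model,
    model_to_dict,
    predict_accuracy,
)
from herdimpute.distances import DistanceSummary
from herdimpute.errors import AssemblyError, ParameterError, PredictionError
from herdimpute.genodata import Pedigree
from herdimpute.ibs_cluster import ClusterAssignment


def synth_features(n, seed, n_breeds=3, n_clusters=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "breed": rng.choice([f"br{i}" for i in range(n_breeds)], n),
            "hap_cluster": rng.choice([str(i) for i in range(n_clusters)], n),
            "geno_cluster": rng.choice([str(i) for i in range(n_clusters)], n),
            "euclid_geno_min": rng.gamma(4, 2, n),
            "euclid_geno_max": rng.gamma(9, 2, n),
            "euclid_geno_mean": rng.gamma(6, 2, n),
            "euclid_hap_min": rng.gamma(4, 1, n),
            "euclid_hap_max": rng.gamma(9, 1, n),
            "euclid_hap_mean": rng.gamma(6, 1, n),
            "n_parents_seq": rng.integers(0, 3, n),
            "n_progeny_seq": rng.integers(0, 5, n),
        },
        index=[f"a{i}" for i in range(n)],
    )
    df.index.name = "sample_id"
    return df


def final_model_response(df, seed, sigma=0.01):
    """Accuracy = breed + hap-cluster effects + 4 regressors + noise."""
    rng = np.random.default_rng(seed)
    breed_eff = {b: e for b, e in zip(sorted(df["breed"].unique()), (0.0, 0.02, -0.015))}
    clust_eff = {c: e for c, e in zip(sorted(df["hap_cluster"].unique()), (0.0, 0.01, -0.01))}
    coefs = {
        "euclid_geno_min": -0.004,
        "euclid_geno_max": 0.0015,
        "euclid_hap_mean": -0.003,
        "n_parents_seq": 0.01,
    }
    y = (
        0.93
        + df["breed"].map(breed_eff)
        + df["hap_cluster"].map(clust_eff)
        + sum(c * df[t] for t, c in coefs.items())
        + rng.normal(0, sigma, len(df))
    )
    return y, breed_eff, clust_eff, coefs


class TestBuildFeatures:
    def dsum(self, sid, v):
        return DistanceSummary(sid, v, v + 1, v + 2)

    def test_parent_and_progeny_counts(self):
        ped = Pedigree({"kid": ("pa", "ma"), "pa": (None, None), "ma": (None, None)})
        geno = [self.dsum(s, 1.0) for s in ("kid", "pa", "ma")]
        hap = [self.dsum(s, 2.0) for s in ("kid", "pa", "ma")]
        clusters = ClusterAssignment({"kid": 1, "pa": 1, "ma": 2}, k=2)
        breeds = {"kid": "x", "pa": "x", "ma": "y"}
        df = build_features(geno, hap, clusters, ped, breeds,
                            sequenced_ids={"kid", "pa", "ma"})
        assert df.loc["kid", "n_parents_seq"] == 2
        assert df.loc["pa", "n_progeny_seq"] == 1
        assert df.loc["kid", "n_progeny_seq"] == 0

    def test_animal_absent_from_pedigree_counts_zero(self):
        ped = Pedigree({})
        geno = [self.dsum("solo", 1.0)]
        hap = [self.dsum("solo", 2.0)]
        clusters = ClusterAssignment({"solo": 1}, k=1)
        df = build_features(geno, hap, clusters, ped, {"solo": "x"}, set())
        assert df.loc["solo", "n_parents_seq"] == 0

    def test_missing_source_raises(self):
        geno = [self.dsum("a", 1.0)]
        hap = []
        clusters = ClusterAssignment({"a": 1}, k=1)
        with pytest.raises(AssemblyError):
            build_features(geno, hap, clusters, Pedigree({}), {"a": "x"}, set())


class TestFitLinear:
    def test_zero_noise_exact_recovery(self):
        df = synth_features(200, seed=5)
        y, breed_eff, clust_eff, coefs = final_model_response(df, seed=5, sigma=0.0)
        terms = ["breed", "hap_cluster", *coefs]
        model = fit_linear(df, y, terms)
        for t, c in coefs.items():
            assert model.params[t] == pytest.approx(c, abs=1e-8)
        preds = model.predict(df)
        assert np.allclose(preds, y, atol=1e-8)

    def test_noisy_recovery_within_3se(self):
        hits = 0
        total = 0
        for rep in range(100):
            df = synth_features(500, seed=10_000 + rep)
            y, _, _, coefs = final_model_response(df, seed=20_000 + rep, sigma=0.01)
            model = fit_linear(df, y, ["breed", "hap_cluster", *coefs])
            for t, c in coefs.items():
                total += 1
                if abs(model.params[t] - c) <= 3 * model.bse[t]:
                    hits += 1
        assert hits / total >= 0.95

    def test_single_level_categorical_dropped(self):
        df = synth_features(100, seed=1)
        df["breed"] = "only"
        y = df["euclid_geno_min"] * 0.01
        with pytest.warns(UserWarning):
            model = fit_linear(df, y, ["breed", "euclid_geno_min"])
        assert "breed" not in model.terms


class TestBackwardSelect:
    def test_pure_noise_regressor_removed(self):
        removed = 0
        for rep in range(10):
            df = synth_features(500, seed=100 + rep)
            rng = np.random.default_rng(rep)
            df["noise_reg"] = rng.normal(size=len(df))
            y, *_ = final_model_response(df, seed=300 + rep, sigma=0.01)
            globals_ = ["breed", "hap_cluster", "euclid_geno_min", "euclid_geno_max",
                        "euclid_hap_mean", "n_parents_seq", "noise_reg"]
            model = backward_select(df, y, globals_, seed=rep)
            if "noise_reg" not in model.terms:
                removed += 1
        assert removed >= 9

    def test_strong_predictors_all_retained(self):
        rng = np.random.default_rng(0)
        n = 400
        df = pd.DataFrame(
            {
                "euclid_geno_min": rng.normal(size=n),
                "euclid_geno_max": rng.normal(size=n),
                "n_parents_seq": rng.normal(size=n),
            },
            index=[f"a{i}" for i in range(n)],
        )
        y = (0.5 * df["euclid_geno_min"] + 0.5 * df["euclid_geno_max"]
             + 0.5 * df["n_parents_seq"] + rng.normal(0, 0.05, n))
        model = backward_select(df, y, list(df.columns), seed=0)
        assert set(model.terms) == set(df.columns)

    def test_infinite_drop_tol_reduces_to_intercept(self):
        df = synth_features(200, seed=2)
        y, *_ = final_model_response(df, seed=2)
        model = backward_select(df, y, ["breed", "euclid_geno_min"],
                                drop_tol=np.inf, seed=0)
        assert model.terms == []
        assert model.params["Intercept"] == pytest.approx(float(np.mean(y)))

    def test_refit_on_all_matches_fit_linear(self):
        df = synth_features(300, seed=3)
        y, *_ = final_model_response(df, seed=3)
        model = backward_select(df, y, ["breed", "hap_cluster", "euclid_geno_min",
                                        "euclid_geno_max", "euclid_hap_mean",
                                        "n_parents_seq"], seed=1)
        refit = fit_linear(df, y, model.terms)
        assert np.allclose(model.params, refit.params[model.params.index])


class TestPredict:
    def test_intercept_only_constant(self):
        df = synth_features(50, seed=4)
        y = pd.Series(0.9, index=df.index)
        model = backward_select(df, y, ["euclid_geno_min"], drop_tol=np.inf, seed=0)
        preds, ranks = predict_accuracy(model, df)
        assert np.allclose(preds, 0.9)

    def test_unseen_level_raises(self):
        df = synth_features(100, seed=6)
        y, *_ = final_model_response(df, seed=6)
        model = fit_linear(df, y, ["breed", "euclid_geno_min"])
        bad = df.copy()
        bad.loc[bad.index[0], "breed"] = "martian"
        with pytest.raises(PredictionError):
            model.predict(bad)

    def test_row_order_invariance(self):
        df = synth_features(150, seed=7)
        y, *_ = final_model_response(df, seed=7)
        model = fit_linear(df, y, ["breed", "euclid_geno_min", "n_parents_seq"])
        shuffled = df.sample(frac=1, random_state=0)
        p1 = model.predict(df).loc[shuffled.index]
        p2 = model.predict(shuffled)
        assert np.allclose(p1, p2)

    def test_bottom_k_overlap_reporting(self):
        df = synth_features(100, seed=8)
        y, *_ = final_model_response(df, seed=8, sigma=0.0)
        model = fit_linear(df, y, ["breed", "hap_cluster", "euclid_geno_min",
                                   "euclid_geno_max", "euclid_hap_mean",
                                   "n_parents_seq"])
        preds, ranks = predict_accuracy(model, df)
        bottom_pred = set(ranks[ranks <= 10].index)
        bottom_true = set(pd.Series(y).rank(method="first")[lambda s: s <= 10].index)
        # zero-noise fit: predictions equal responses, so overlap is total
        assert bottom_pred == bottom_true


class TestReducedModel:
    def test_progeny_noise_removed(self):
        for rep in range(3):
            df = synth_features(400, seed=500 + rep)
            rng = np.random.default_rng(rep)
            y = (0.93 - 0.004 * df["euclid_geno_min"] + 0.01 * df["n_parents_seq"]
                 + rng.normal(0, 0.01, len(df)))
            model = fit_reduced_model(df, y, seed=rep)
            assert "n_progeny_seq" not in model.terms

    def test_signal_only_in_min_distance_retained(self):
        df = synth_features(400, seed=600)
        rng = np.random.default_rng(600)
        y = 0.9 - 0.01 * df["euclid_geno_min"] + rng.normal(0, 0.005, len(df))
        model = fit_reduced_model(df, y, seed=0)
        assert "euclid_geno_min" in model.terms

    def test_reduced_candidates_exclude_haplotype_terms(self):
        df = synth_features(300, seed=700)
        y, *_ = final_model_response(df, seed=700)
        model = fit_reduced_model(df, y, seed=0)
        assert not any(t.startswith("euclid_hap") for t in model.terms)
        assert not any("cluster" in t for t in model.terms)

    def test_serialization_round_trip_fields(self):
        df = synth_features(200, seed=800)
        y, *_ = final_model_response(df, seed=800)
        model = fit_reduced_model(df, y, seed=0)
        d = model_to_dict(model)
        assert set(d) >= {"terms", "params", "cv_r", "cv_r2", "dropped_terms"}


def test_cv_correlation_bounds():
    df = synth_features(200, seed=900)
    y, *_ = final_model_response(df, seed=900, sigma=0.005)
    r, r2 = cv_correlation(df, y, ["breed", "euclid_geno_min", "euclid_geno_max",
                                   "euclid_hap_mean", "n_parents_seq"], seed=1)
    assert -1 <= r <= 1 and r2 == pytest.approx(r * r)
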