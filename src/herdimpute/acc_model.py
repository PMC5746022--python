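"""Linear prediction of per-animal imputation accuracy, with backward selection.

The response is each animal's imputation concordance; candidate predictors
are everything computable from the low-density panel alone: breed,
haplotype- and genotype-based IBS cluster, the six Euclidean-distance
summaries (min/mean/max, on genotypes and on window haplotypes), and the
counts of sequenced parents and progeny. The working final model has the
form

    accuracy = X_breed + X_hap_cluster
               + b1 * euclid_geno_min + b2 * euclid_geno_max
               + b3 * euclid_hap_mean + b4 * n_parents_seq + residual

Backward selection removes, each round, the term with the largest partial-F
p-value (a categorical leaves as a block), re-estimates the 5-fold
cross-validated squared correlation between pooled out-of-fold predictions
and the observed accuracies, and stops — keeping the current model — as soon
as a removal would cost more than ``drop_tol`` (default 0.01) of that CV R².
The retained model is then refit on all animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .errors import (
    AssemblyError,
    ParameterError,
    PredictionError,
    SingularDesignError,
)
from .distances import DistanceSummary
from .genodata import Pedigree
from .ibs_cluster import ClusterAssignment

CATEGORICAL_TERMS = ("breed", "hap_cluster", "geno_cluster", "extra_cluster")

NUMERIC_TERMS = (
    "euclid_geno_min",
    "euclid_geno_max",
    "euclid_geno_mean",
    "euclid_hap_min",
    "euclid_hap_max",
    "euclid_hap_mean",
    "n_parents_seq",
    "n_progeny_seq",
)

FULL_CANDIDATES = (
    "breed",
    "hap_cluster",
    "geno_cluster",
    "euclid_geno_min",
    "euclid_geno_max",
    "euclid_geno_mean",
    "euclid_hap_min",
    "euclid_hap_max",
    "euclid_hap_mean",
    "n_parents_seq",
    "n_progeny_seq",
)

REDUCED_CANDIDATES = (
    "breed",
    "euclid_geno_min",
    "euclid_geno_max",
    "euclid_geno_mean",
    "n_parents_seq",
    "n_progeny_seq",
)


def build_features(
    dist_geno: list[DistanceSummary],
    dist_hap: list[DistanceSummary],
    clusters_hap: ClusterAssignment,
    pedigree: Pedigree,
    breeds: dict[str, str],
    sequenced_ids: set[str],
    clusters_geno: ClusterAssignment | None = None,
    extra_clusters: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the per-animal feature table (index: sample_id).

    ``n_parents_seq`` / ``n_progeny_seq`` count pedigree parents and progeny
    that belong to ``sequenced_ids``; animals absent from the pedigree count
    zero. ``extra_clusters`` is a hook for externally computed cluster labels
    (e.g. from a model-based ancestry program) so the complete candidate set
    remains constructible. Raises :class:`AssemblyError` when an animal is
    missing from any source.
    """
    ids = [s.sample_id for s in dist_geno]
    hap_by_id = {s.sample_id: s for s in dist_hap}
    missing: list[str] = []
    rows = []
    for s in dist_geno:
        sid = s.sample_id
        h = hap_by_id.get(sid)
        if h is None or sid not in breeds or sid not in clusters_hap.assignment:
            missing.append(sid)
            continue
        parents = [p for p in pedigree.parents_of(sid) if p in sequenced_ids]
        progeny = [c for c in pedigree.progeny_of(sid) if c in sequenced_ids]
        row = {
            "breed": breeds[sid],
            "hap_cluster": str(clusters_hap.assignment[sid]),
            "euclid_geno_min": s.d_min,
            "euclid_geno_max": s.d_max,
            "euclid_geno_mean": s.d_mean,
            "euclid_hap_min": h.d_min,
            "euclid_hap_max": h.d_max,
            "euclid_hap_mean": h.d_mean,
            "n_parents_seq": len(parents),
            "n_progeny_seq": len(progeny),
        }
        if clusters_geno is not None:
            if sid not in clusters_geno.assignment:
                missing.append(sid)
                continue
            row["geno_cluster"] = str(clusters_geno.assignment[sid])
        if extra_clusters is not None:
            if sid not in extra_clusters:
                missing.append(sid)
                continue
            row["extra_cluster"] = str(extra_clusters[sid])
        rows.append((sid, row))
    if missing:
        raise AssemblyError(f"animals missing from an input source: {sorted(set(missing))[:10]}")
    df = pd.DataFrame([r for _, r in rows], index=[sid for sid, _ in rows])
    df.index.name = "sample_id"
    return df


@dataclass
class PredictionModel:
    """A fitted linear accuracy predictor.

    ``levels`` maps each retained categorical term to its ordered training
    levels (the first is the reference level absorbed by the intercept);
    ``params`` holds the intercept, level effects, and regression
    coefficients by design-column name.
    """

    terms: list[str]
    levels: dict[str, list[str]]
    params: pd.Series
    bse: pd.Series
    term_pvalues: dict[str, float]
    resid_var: float
    nobs: int
    cv_r2: float | None = None
    cv_r: float | None = None
    dropped_terms: list[str] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        X = _design(features, self.terms, self.levels)
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        return pd.Series(X.to_numpy() @ self.params.to_numpy(), index=features.index)


def _design(
    features: pd.DataFrame,
    terms: list[str],
    levels: dict[str, list[str]] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Intercept + reference-coded dummies + numeric columns, as a DataFrame."""
    cols = {"Intercept": np.ones(len(features))}
    for t in terms:
        if t not in features.columns:
            raise ParameterError(f"feature table has no column {t!r}")
        if t in CATEGORICAL_TERMS:
            vals = features[t].astype(str)
            if levels is not None and t in levels:
                lv = levels[t]
                unseen = sorted(set(vals) - set(lv))
                if unseen and strict:
                    raise PredictionError(f"unseen level(s) {unseen} for term {t!r}")
            else:
                lv = sorted(vals.unique())
            for level in lv[1:]:  # first level is the reference
                cols[f"{t}[{level}]"] = (vals == level).to_numpy(dtype=float)
        else:
            cols[t] = features[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=features.index)


def _term_levels(features: pd.DataFrame, terms: list[str]) -> dict[str, list[str]]:
    return {
        t: sorted(features[t].astype(str).unique())
        for t in terms
        if t in CATEGORICAL_TERMS
    }


def fit_linear(
    features: pd.DataFrame,
    accuracy: pd.Series | np.ndarray,
    terms: list[str],
) -> PredictionModel:
    """OLS fit with reference-level coding; per-term partial-F p-values.

    A categorical with a single observed level carries no information and is
    dropped with a warning-level p-value of 1. Rank deficiency after level
    dropping raises :class:`SingularDesignError`.
    """
    y = np.asarray(accuracy, dtype=float)
    if len(y) != len(features):
        raise ParameterError("accuracy length does not match feature rows")
    terms = list(terms)
    levels = _term_levels(features, terms)
    degenerate = [t for t, lv in levels.items() if len(lv) < 2]
    if degenerate:
        import warnings

        warnings.warn(f"dropping single-level categorical term(s): {degenerate}")
        terms = [t for t in terms if t not in degenerate]
        levels = {t: lv for t, lv in levels.items() if t not in degenerate}

    X = _design(features, terms, levels)
    if len(y) <= X.shape[1]:
        raise ParameterError("more parameters than animals")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix rank-deficient; collinearity among terms {terms}"
        )
    full = sm.OLS(y, X).fit()

    term_p: dict[str, float] = {}
    for t in terms:
        sub_cols = [c for c in X.columns if c == t or c.startswith(f"{t}[")]
        X_red = X.drop(columns=sub_cols)
        red = sm.OLS(y, X_red).fit()
        f, p, _ = full.compare_f_test(red)
        term_p[t] = float(p)

    return PredictionModel(
        terms=terms,
        levels=levels,
        params=full.params,
        bse=full.bse,
        term_pvalues=term_p,
        resid_var=float(full.mse_resid),
        nobs=int(full.nobs),
    )


def _cv_predictions(
    features: pd.DataFrame,
    y: np.ndarray,
    terms: list[str],
    n_folds: int,
    seed: int,
) -> np.ndarray:
    """Pooled out-of-fold predictions from simple random fold splits.

    Fold fits use a pseudoinverse solve so that a level absent from a
    training fold (a zero dummy column) degrades gracefully instead of
    failing.
    """
    levels = _term_levels(features, terms)
    X = _design(features, terms, levels).to_numpy()
    preds = np.empty(len(y))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        beta = np.linalg.pinv(X[train]) @ y[train]
        preds[test] = X[test] @ beta
    return preds


def cv_correlation(
    features: pd.DataFrame,
    accuracy,
    terms: list[str],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """(r, r^2) between pooled cross-validated predictions and observed accuracy."""
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    y = np.asarray(accuracy, dtype=float)
    preds = _cv_predictions(features, y, terms, n_folds, seed)
    if np.std(preds) == 0 or np.std(y) == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(preds, y)[0, 1])
    return r, r * r


def backward_select(
    features: pd.DataFrame,
    accuracy,
    candidate_terms,
    n_folds: int = 5,
    drop_tol: float = 0.01,
    seed: int = 0,
) -> PredictionModel:
    """Backward selection on term p-values, guarded by cross-validated R².

    Each round fits the current model on all animals, nominates the term with
    the largest partial-F p-value, and computes the CV squared correlation
    without it. If that removal costs more than ``drop_tol`` of CV R²
    relative to the current model, selection stops and the current model is
    kept; otherwise the term is dropped and the loop continues. The final
    model is refit on all animals, with the CV correlation of its own term
    set attached.
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    y = np.asarray(accuracy, dtype=float)
    terms = [t for t in candidate_terms]
    # categoricals with one level never enter
    lv = _term_levels(features, terms)
    terms = [t for t in terms if t not in lv or len(lv[t]) >= 2]
    dropped: list[str] = []
    _, cur_r2 = cv_correlation(features, y, terms, n_folds, seed)
    while terms:
        model = fit_linear(features, y, terms)
        worst = max(model.terms, key=lambda t: (model.term_pvalues[t], t))
        reduced = [t for t in model.terms if t != worst]
        _, cand_r2 = cv_correlation(features, y, reduced, n_folds, seed)
        if cur_r2 - cand_r2 > drop_tol:
            break
        dropped.append(worst)
        terms = reduced
        cur_r2 = cand_r2
        if not terms:
            break
    final = fit_linear(features, y, terms) if terms else _intercept_model(y)
    r, r2 = cv_correlation(features, y, terms, n_folds, seed) if terms else (0.0, 0.0)
    final.cv_r = r
    final.cv_r2 = r2
    final.dropped_terms = dropped
    return final


def _intercept_model(y: np.ndarray) -> PredictionModel:
    return PredictionModel(
        terms=[],
        levels={},
        params=pd.Series({"Intercept": float(np.mean(y))}),
        bse=pd.Series({"Intercept": float(np.std(y, ddof=1) / np.sqrt(len(y)))}),
        term_pvalues={},
        resid_var=float(np.var(y, ddof=1)),
        nobs=len(y),
    )


def predict_accuracy(
    model: PredictionModel, features: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Predicted accuracy per animal plus the ascending rank ordering.

    The rank series (1 = worst predicted) supports bottom-k exclusion: the
    animals predicted to impute worst are candidates for removal from
    downstream analyses.
    """
    preds = model.predict(features)
    ranks = preds.rank(method="first").astype(int)
    return preds, ranks


def fit_reduced_model(
    features: pd.DataFrame,
    accuracy,
    n_folds: int = 5,
    drop_tol: float = 0.01,
    seed: int = 0,
) -> PredictionModel:
    """Backward selection over the practical candidate set only.

    Restricts candidates to breed, the genotype-based distance summaries,
    and the pedigree counts — everything computable without phasing or
    clustering — for use as a routine quality-control screen.
    """
    cands = [t for t in REDUCED_CANDIDATES if t in features.columns]
    return backward_select(features, accuracy, cands, n_folds=n_folds,
                           drop_tol=drop_tol, seed=seed)


def model_to_dict(model: PredictionModel) -> dict:
    """JSON-serialisable form of a fitted model."""
    return {
        "terms": model.terms,
        "levels": model.levels,
        "params": {k: float(v) for k, v in model.params.items()},
        "bse": {k: float(v) for k, v in model.bse.items()},
        "term_pvalues": model.term_pvalues,
        "resid_var": model.resid_var,
        "nobs": model.nobs,
        "cv_r": model.cv_r,
        "cv_r2": model.cv_r2,
        "dropped_terms": model.dropped_terms,
    }
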