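"""Staged linear-discriminant risk modelling and biomarker evaluation.

The modelling protocol:

1. three preliminary analyses select, by exhaustively searching feature
   subsets of size 1..3 scored with stratified four-fold cross-validated
   ROC AUC, the best predictors within (i) conventional volumetric and
   clinical measures, (ii) regional RV parcellation measures and
   (iii) the retained shape-mode z-scores;
2. a composite model repeats the selection over the union of the three
   winners;
3. the winning linear-discriminant score is evaluated as a biomarker:
   Mann-Whitney AUC, Youden-optimal cut-off and odds ratio per standard
   deviation with a Wald 95% confidence interval;
4. a surrogate analysis relates pulmonary regurgitation (PRVI) to the risk
   score and to the shape modes by forward-selected linear regression.

Features are z-scored before discriminant fitting; missing values are
handled complete-case per analysis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CONVENTIONAL_POOL = [
    "lvedv_i", "lvesv_i", "rvedv_i", "rvesv_i",
    "lvef", "rvef", "lvm_i", "qrs_ms", "sbp_mmHg", "dbp_mmHg",
]
REGIONAL_POOL = [
    "ipvi_ed", "opvi_ed", "apvi_ed", "ipvi_es", "opvi_es", "apvi_es",
    "ipsvi", "opsvi", "apsvi", "ipef", "opef", "apef",
]


# --------------------------------------------------------------------------
# Fisher discriminant
# --------------------------------------------------------------------------

class FisherLDA(BaseEstimator, ClassifierMixin):
    """Two-class Fisher linear discriminant.

    w is proportional to S_pooled^{-1} (mu_1 - mu_0); the intercept centres
    the score at the pooled-mean midpoint; the sign convention puts the
    positive (higher-risk) class at higher scores.  A singular pooled
    covariance falls back to a ridge-regularized inverse
    (lambda = 1e-6 * trace / d) with a logged warning.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y) -> "FisherLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("FisherLDA needs exactly two classes")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("each class needs at least 2 members")
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        S = np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1)
        S = S + np.cov(X1, rowvar=False, ddof=1) * (len(X1) - 1)
        S = np.atleast_2d(S / (len(X) - 2))
        try:
            w = np.linalg.solve(S, mu1 - mu0)
        except np.linalg.LinAlgError:
            tr = np.trace(S)
            lam = self.ridge * (tr / S.shape[0] if tr > 0 else 1.0)
            logger.warning("singular pooled covariance; ridge-regularizing (lambda=%.3g)", lam)
            w = np.linalg.solve(S + lam * np.eye(S.shape[0]), mu1 - mu0)
        b = -0.5 * float(w @ (mu0 + mu1))
        # sign convention: higher score = class 1 (higher risk)
        if (X1 @ w).mean() < (X0 @ w).mean():
            w, b = -w, -b
        self.classes_ = classes
        self.coef_ = w
        self.intercept_ = b
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def fit_lda(X, y) -> tuple[np.ndarray, np.ndarray]:
    """Weights and training scores of the Fisher discriminant."""
    lda = FisherLDA().fit(X, y)
    return lda.coef_, lda.decision_function(X)


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """z-score each column (ddof=1); constant columns map to 0."""
    sd = df.std(ddof=1).replace(0, 1.0)
    return (df - df.mean()) / sd


# --------------------------------------------------------------------------
# biomarker evaluation
# --------------------------------------------------------------------------

def evaluate_biomarker(scores, labels) -> tuple[float, float, tuple[float, float, float]]:
    """(AUC, Youden cut-off, (OR, ci_low, ci_high)) for a continuous score.

    AUC is the Mann-Whitney statistic (ties count one half).  The cut-off
    maximizes sensitivity + specificity over the observed score values
    (predicted positive when score >= threshold; ties broken toward the
    lower threshold).  The odds ratio is exp(beta) from a univariable
    logistic fit of the outcome on the score as given — pass a z-scored
    score to obtain an OR per standard deviation — with Wald 95% CI.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) != 2:
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(labels, scores))

    thresholds = np.unique(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, cutoff = -np.inf, thresholds[0]
    for thr in thresholds:  # ascending; strict > keeps the lowest argmax
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        if sens + spec > best_j + 1e-12:
            best_j, cutoff = sens + spec, float(thr)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels, sm.add_constant(scores)).fit(disp=0)
            beta, se = fit.params[1], fit.bse[1]
            or_ = float(np.exp(beta))
            ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
        except Exception:  # perfect separation
            or_, ci = float("inf"), (0.0, float("inf"))
    return auc, cutoff, (or_, *ci)


# --------------------------------------------------------------------------
# cross-validated subset selection
# --------------------------------------------------------------------------

def cv_auc(
    X: pd.DataFrame, y: np.ndarray, features: tuple[str, ...], folds: int, seed: int
) -> float:
    """Mean stratified k-fold validation AUC of a Fisher LDA on ``features``."""
    Xs = X[list(features)].values
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(Xs, y):
        if min(np.bincount(y[tr], minlength=2)) < 2 or len(np.unique(y[va])) < 2:
            continue  # fold degenerate: cannot fit or cannot score
        lda = FisherLDA().fit(Xs[tr], y[tr])
        aucs.append(roc_auc_score(y[va], lda.decision_function(Xs[va])))
    if not aucs:
        raise ValueError(
            "no usable CV folds: too few members of one outcome class"
        )
    return float(np.mean(aucs))


@dataclass
class RiskModel:
    """A selected-and-fitted discriminant risk model."""

    selected_features: tuple[str, ...]
    lda_weights: np.ndarray
    cv_auc: float
    full_auc: float
    cutoff: float
    or_per_sd: float
    or_ci: tuple[float, float]
    scores: pd.Series = dc_field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "lda_weights": list(map(float, self.lda_weights)),
            "cv_auc": self.cv_auc,
            "full_auc": self.full_auc,
            "cutoff": self.cutoff,
            "or_per_sd": self.or_per_sd,
            "or_ci": list(self.or_ci),
        }


def select_features(
    pool: pd.DataFrame,
    labels,
    max_k: int = 3,
    folds: int = 4,
    seed: int = 0,
    prestandardized: bool = False,
) -> RiskModel:
    """Exhaustive subset search (sizes 1..max_k) scored by stratified CV AUC.

    Ties go to the smaller subset, then to lexicographic feature order
    (guaranteed by ascending-size, sorted-name enumeration with strict
    improvement).  If the positive class has fewer members than ``folds``
    the fold count is reduced with a warning.
    """
    y = np.asarray(labels).astype(int)
    complete = pool.notna().all(axis=1).values
    df = pool[complete]
    y = y[complete]
    X = df if prestandardized else standardize(df)
    n_pos = int(y.sum())
    if n_pos < folds:
        logger.warning("only %d positives; reducing folds from %d to %d", n_pos, folds, max(2, n_pos))
        folds = max(2, n_pos)
    names = sorted(X.columns)
    best_subset, best_auc = None, -np.inf
    for k in range(1, min(max_k, len(names)) + 1):
        for subset in itertools.combinations(names, k):
            auc = cv_auc(X, y, subset, folds, seed)
            if auc > best_auc + 1e-12:
                best_subset, best_auc = subset, auc
    return finalize_model(X, y, best_subset, best_auc)


def finalize_model(
    X: pd.DataFrame, y: np.ndarray, subset: tuple[str, ...], cv_auc_value: float
) -> RiskModel:
    """Fit the final LDA on all data and evaluate its score as a biomarker."""
    lda = FisherLDA().fit(X[list(subset)].values, y)
    raw = lda.decision_function(X[list(subset)].values)
    z = (raw - raw.mean()) / raw.std(ddof=1)
    auc, cutoff, (or_, lo, hi) = evaluate_biomarker(z, y)
    return RiskModel(
        selected_features=subset,
        lda_weights=lda.coef_,
        cv_auc=cv_auc_value,
        full_auc=auc,
        cutoff=cutoff,
        or_per_sd=or_,
        or_ci=(lo, hi),
        scores=pd.Series(z, index=X.index, name="risk_score"),
    )


# --------------------------------------------------------------------------
# feature table and staged analysis
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Merged per-subject feature matrix with named pools.

    ``data`` holds raw (unstandardized) features plus the outcome column
    ``adverse_outcome`` and optionally ``prvi``; standardization happens
    inside each analysis.
    """

    data: pd.DataFrame
    conventional: list[str]
    regional: list[str]
    shape: list[str]

    @property
    def labels(self) -> np.ndarray:
        return self.data["adverse_outcome"].values.astype(int)

    def pool(self, name: str) -> pd.DataFrame:
        cols = {"conventional": self.conventional, "regional": self.regional,
                "shape": self.shape}[name]
        return self.data[cols]


def build_feature_table(volumetrics_df, parcellation_df, scores, records) -> FeatureTable:
    """Assemble the three feature pools from the pipeline stage outputs."""
    rec = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "qrs_ms": r.qrs_ms,
                "sbp_mmHg": r.sbp_mmHg,
                "dbp_mmHg": r.dbp_mmHg,
                "adverse_outcome": r.adverse_outcome,
                "prvi": r.prvi,
            }
            for r in records
        ]
    ).set_index("subject_id")
    z = pd.DataFrame(
        np.asarray(scores),
        index=volumetrics_df.index,
        columns=[f"z{j + 1}" for j in range(np.asarray(scores).shape[1])],
    )
    conv = volumetrics_df[["lvedv_i", "lvesv_i", "rvedv_i", "rvesv_i", "lvef", "rvef", "lvm_i"]]
    reg = parcellation_df[REGIONAL_POOL]
    data = pd.concat([conv, reg, z, rec], axis=1)
    return FeatureTable(
        data=data,
        conventional=CONVENTIONAL_POOL,
        regional=REGIONAL_POOL,
        shape=list(z.columns),
    )


def staged_analysis(
    table: FeatureTable, max_k: int = 3, folds: int = 4, seed: int = 0
) -> dict[str, RiskModel]:
    """Three preliminary selections plus the composite model.

    Returns models keyed ``conventional``, ``regional``, ``shape`` and
    ``composite`` (selection over the union of the three winners).
    """
    y = table.labels
    out: dict[str, RiskModel] = {}
    winners: list[str] = []
    for pool_name in ("conventional", "regional", "shape"):
        model = select_features(table.pool(pool_name), y, max_k=max_k, folds=folds, seed=seed)
        out[pool_name] = model
        winners.extend(model.selected_features)
    composite_pool = table.data[sorted(dict.fromkeys(winners))]
    out["composite"] = select_features(composite_pool, y, max_k=max_k, folds=folds, seed=seed)
    return out


# --------------------------------------------------------------------------
# group-comparison tables
# --------------------------------------------------------------------------

def group_comparison_tables(
    table: FeatureTable, median_features: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Per-feature group statistics mirroring a clinical baseline table.

    Normal-format rows report mean +/- sd per outcome group with Welch's
    two-sample t-test; rows listed in ``median_features`` report
    median (IQR) with Mood's median test.  Stars mark p <= 0.05.
    """
    y = table.labels
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome groups must be non-empty")
    feats = table.conventional + table.regional + table.shape
    rows = []
    for name in feats:
        x = table.data[name].astype(float)
        g1, g0 = x[y == 1].dropna(), x[y == 0].dropna()
        row: dict[str, object] = {"feature": name}
        if name in median_features:

            def fmt(g):
                return f"{g.median():.2f} ({g.quantile(0.75) - g.quantile(0.25):.2f})"

            row["all"], row["adverse"], row["no_adverse"] = fmt(x.dropna()), fmt(g1), fmt(g0)
            try:
                _, p, *_ = stats.median_test(g1, g0)
            except ValueError:
                p = np.nan
            row["test"] = "mood"
        else:

            def fmt(g):
                return f"{g.mean():.2f} ± {g.std(ddof=1):.2f}"

            row["all"], row["adverse"], row["no_adverse"] = fmt(x.dropna()), fmt(g1), fmt(g0)
            if len(g1) < 2 or len(g0) < 2:
                p = np.nan
            else:
                _, p = stats.ttest_ind(g1, g0, equal_var=False)
            row["test"] = "welch"
        row["p"] = float(p) if np.isfinite(p) else np.nan
        row["sig"] = "*" if np.isfinite(p) and p <= 0.05 else ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


# --------------------------------------------------------------------------
# PRVI surrogate analysis
# --------------------------------------------------------------------------

def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(coefficients, R^2, F-test p) of an OLS fit with intercept."""
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return fit.params[1:], float(fit.rsquared), float(fit.f_pvalue)


def forward_select_regression(
    y: pd.Series, X: pd.DataFrame, max_k: int = 3
) -> tuple[list[str], np.ndarray, float]:
    """Forward stepwise linear regression maximizing R^2, up to max_k terms."""
    if np.asarray(y).std() == 0:
        raise ValueError("response is constant; regression undefined")
    selected: list[str] = []
    best_r2 = 0.0
    for _ in range(min(max_k, X.shape[1])):
        best_cand, best_cand_r2 = None, best_r2
        for name in X.columns:
            if name in selected:
                continue
            _, r2, _ = _ols_r2(y.values, X[selected + [name]].values)
            if r2 > best_cand_r2 + 1e-12:
                best_cand, best_cand_r2 = name, r2
        if best_cand is None:
            break
        selected.append(best_cand)
        best_r2 = best_cand_r2
    coefs, r2, _ = _ols_r2(y.values, X[selected].values)
    return selected, coefs, r2


def prvi_analysis(
    table: FeatureTable,
    composite: RiskModel,
    max_k: int = 3,
    folds: int = 4,
    seed: int = 0,
    atlas=None,
) -> dict:
    """Surrogate analysis of pulmonary regurgitation (PRVI).

    (a) does PRVI add discriminative value to the composite predictors?
    (b) univariable regressions of PRVI on the risk score, RVEF and apical EF;
    (c) forward-selected regression of PRVI on the shape-mode z-scores;
    (d) if an atlas is given, +/-2 sd shapes along the PRVI regression
        direction and along the outcome discriminant direction.
    """
    mask = table.data["prvi"].notna()
    if mask.sum() < 10:
        raise ValueError("fewer than 10 subjects with PRVI")
    sub = table.data[mask]
    if sub["prvi"].std(ddof=1) == 0:
        raise ValueError("PRVI is constant; surrogate regression undefined")
    y = sub["adverse_outcome"].values.astype(int)

    base_cols = list(composite.selected_features)
    base = select_features(sub[base_cols], y, max_k=max_k, folds=folds, seed=seed)
    with_prvi = select_features(
        sub[base_cols + ["prvi"]], y, max_k=max_k + 1, folds=folds, seed=seed
    )
    prvi_auc = cv_auc(standardize(sub[["prvi"]]), y, ("prvi",), folds, seed)

    prvi = sub["prvi"]
    risk = composite.scores[mask] if composite.scores is not None else None
    univariable = {}
    for name, x in (("risk_score", risk), ("rvef", sub["rvef"]), ("apef", sub["apef"])):
        if x is None:
            continue
        _, r2, p = _ols_r2(prvi.values, np.asarray(x, dtype=float).reshape(-1, 1))
        univariable[name] = {"r2": r2, "p": p}

    Zcols = table.shape
    selected, coefs, r2 = forward_select_regression(prvi, standardize(sub[Zcols]), max_k=max_k)

    out = {
        "auc_composite_without_prvi": base.cv_auc,
        "auc_composite_with_prvi": with_prvi.cv_auc,
        "auc_prvi_alone": prvi_auc,
        "univariable": univariable,
        "prvi_modes": {"selected": selected, "coefficients": list(map(float, coefs)), "r2": r2},
    }
    if atlas is not None:
        direction = np.zeros(len(Zcols))
        for name, c in zip(selected, coefs):
            direction[Zcols.index(name)] = c
        out["prvi_shapes"] = {
            s: atlas.synthesize(direction, s) for s in (+2.0, -2.0)
        }
        # outcome direction in z-space from the composite discriminant
        w = np.zeros(len(Zcols))
        any_mode = False
        for fname, wi in zip(composite.selected_features, composite.lda_weights):
            if fname in Zcols:
                w[Zcols.index(fname)] = wi
                any_mode = True
        if any_mode:
            out["outcome_shapes"] = {s: atlas.synthesize(w, s) for s in (+2.0, -2.0)}
    return out
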