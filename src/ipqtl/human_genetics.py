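"""Candidate-SNV association and the bootstrap-LASSO risk-score pipeline.

Single-SNV association supports five genetic models (codominant, dominant,
recessive, overdominant, log-additive) with likelihood-ratio p-values.
Risk scores are built by bootstrap SNV selection (80/20 resampling of the
training set, hit = p < 0.05 in both portions, kept at >= min_hits of
n_iter), an L1-penalized logistic fit with cross-validated penalty, and a
probability cutoff maximizing Youden's J on the training ROC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HumanCohort",
    "AssociationResult",
    "RiskScoreModel",
    "filter_by_imputation",
    "label_cda_cases",
    "encode_genetic_model",
    "associate_snv",
    "choose_best_model",
    "bootstrap_select_snvs",
    "fit_lasso_risk_model",
    "optimize_cutoff_youden",
    "evaluate_on_test",
]

GENETIC_MODELS = ("codominant", "dominant", "recessive", "overdominant", "log-additive")


@dataclass
class HumanCohort:
    """SNV dosages, imputation quality and CDA outcome for one cohort."""

    dosages: pd.DataFrame  # individuals x SNVs, values in {0,1,2} or NaN
    imputation_r2: pd.Series | None = None  # per SNV, in [0,1]
    outcome: np.ndarray | None = None  # binary CDA label
    baseline: np.ndarray | None = None  # cardiac function at baseline (%)
    followup: np.ndarray | None = None  # (n,) or (n, t) follow-up values
    tag: str = ""

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.imputation_r2 is not None:
            r2 = np.asarray(self.imputation_r2, float)
            if np.any((r2 < 0) | (r2 > 1)):
                raise ValueError("imputation R^2 must lie in [0, 1]")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome)

    @property
    def snv_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n(self) -> int:
        return len(self.dosages)

    def subset(self, rows: np.ndarray) -> "HumanCohort":
        return HumanCohort(
            dosages=self.dosages.iloc[rows].reset_index(drop=True),
            imputation_r2=self.imputation_r2,
            outcome=None if self.outcome is None else self.outcome[rows],
            baseline=None if self.baseline is None else np.asarray(self.baseline)[rows],
            followup=None if self.followup is None else np.asarray(self.followup)[rows],
            tag=self.tag,
        )


@dataclass
class AssociationResult:
    snv: str
    model: str
    odds_ratio: float | list[float]
    p_value: float
    aic: float
    chosen: bool = False
    separation_flagged: bool = False


@dataclass
class RiskScoreModel:
    """Penalized logistic risk score over selected SNVs."""

    snv_ids: list[str]
    hit_counts: dict[str, int]
    coefficients: dict[str, float]
    intercept: float
    penalty_lambda: float
    lambda_record: str
    cutoff: float = 0.5
    youden_j: float = 0.0
    training_metrics: dict = field(default_factory=dict)
    seed: int | None = None
    intercept_only: bool = False
    train_means: dict[str, float] = field(default_factory=dict)  # for mean imputation

    def linear_predictor(self, dosages: pd.DataFrame) -> np.ndarray:
        missing = [s for s in self.coefficients if s not in dosages.columns]
        if missing:
            raise ValueError(f"test cohort lacks model SNVs: {missing}")
        eta = np.full(len(dosages), self.intercept)
        for s, b in self.coefficients.items():
            x = dosages[s].to_numpy(float)
            fill = self.train_means.get(s, np.nanmean(x))
            x = np.where(np.isnan(x), fill, x)
            eta += b * x
        return eta

    def predict_proba(self, dosages: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(dosages)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "RiskScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        d["hit_counts"] = {k: int(v) for k, v in d["hit_counts"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# filtering and labeling


def filter_by_imputation(cohort: HumanCohort, r2_min: float = 0.7) -> HumanCohort:
    """Drop SNVs whose imputation R^2 is strictly below ``r2_min``."""
    if cohort.imputation_r2 is None:
        raise ValueError("cohort has no imputation R^2 values")
    r2 = cohort.imputation_r2.reindex(cohort.dosages.columns)
    if r2.isna().any():
        raise ValueError("imputation R^2 missing for some SNVs")
    keep = r2[r2 >= r2_min].index
    n_removed = cohort.dosages.shape[1] - len(keep)
    if n_removed:
        warnings.warn(f"removed {n_removed} SNVs with R^2 < {r2_min}")
    return HumanCohort(
        dosages=cohort.dosages[list(keep)],
        imputation_r2=r2[keep],
        outcome=cohort.outcome,
        baseline=cohort.baseline,
        followup=cohort.followup,
        tag=cohort.tag,
    )


def label_cda_cases(baseline, followup, drop_threshold: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary CDA outcome from cardiac-function measurements.

    Case iff baseline minus any follow-up value is >= ``drop_threshold``
    percentage points (boundary inclusive). Returns (labels, valid mask);
    individuals with no finite follow-up are excluded via the mask.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if followup.ndim == 1:
        followup = followup[:, None]
    if followup.shape[0] != baseline.size:
        raise ValueError("followup must be (n,) or (n, timepoints)")
    drops = baseline[:, None] - followup
    any_follow = np.isfinite(drops).any(axis=1)
    valid = np.isfinite(baseline) & any_follow
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} individuals excluded (missing measurements)")
    case = np.zeros(baseline.size, dtype=int)
    with np.errstate(invalid="ignore"):
        case[valid] = (np.nanmax(drops[valid], axis=1) >= drop_threshold).astype(int)
    return case, valid


def encode_genetic_model(dosages, model: str) -> np.ndarray:
    """Design column(s) for a biallelic SNV under a genetic model.

    codominant returns two indicator columns (het, hom-alt); the other
    models return a single column.
    """
    g = np.asarray(dosages, dtype=float)
    if not np.all(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))):
        raise ValueError("dosages must be coded 0/1/2")
    if model == "codominant":
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    if model == "dominant":
        return (g >= 1).astype(float)[:, None]
    if model == "recessive":
        return (g == 2).astype(float)[:, None]
    if model == "overdominant":
        return (g == 1).astype(float)[:, None]
    if model == "log-additive":
        return g[:, None].copy()
    raise ValueError(f"unknown genetic model {model!r}")


# ---------------------------------------------------------------------------
# logistic machinery


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton-Raphson logistic fit. Returns (beta, loglik, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll_old, False
        beta = beta + step
        ll = float(y @ np.clip(eta, -700, 700) - np.logaddexp(0, eta).sum())
        if abs(ll - ll_old) < tol:
            return beta, ll, True
        ll_old = ll
    return beta, ll_old, False


def _null_loglik(y: np.ndarray) -> float:
    n, k = len(y), y.sum()
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def logistic_lrt_pvalues(G: np.ndarray, y: np.ndarray, max_iter: int = 25) -> np.ndarray:
    """Vectorized per-column log-additive logistic LRT p-values.

    Fits an independent 2-parameter logistic model (intercept + dosage) for
    every column of ``G`` simultaneously by Newton iterations; the p-value
    is a chi-square(1) likelihood-ratio test against intercept-only.
    Constant columns get p = 1.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)

    b0 = np.full(m, _logit_of_mean(y))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + G * b1[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (G * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (G * w).sum(axis=0)
        h11 = (G * G * w).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        db0 = np.clip(db0, -5, 5)
        db1 = np.clip(db1, -5, 5)
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(initial=0), np.abs(db1).max(initial=0)) < 1e-8:
            break

    eta = np.clip(b0[None, :] + G * b1[None, :], -700, 700)
    ll_alt = (y[:, None] * eta).sum(axis=0) - np.logaddexp(0, eta).sum(axis=0)
    ll0 = _null_loglik(y)
    lr = np.maximum(2.0 * (ll_alt - ll0), 0.0)
    pvals = stats.chi2.sf(lr, df=1)
    const = G.std(axis=0) == 0
    pvals[const] = 1.0
    return pvals


def _logit_of_mean(y: np.ndarray) -> float:
    p = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def associate_snv(cohort: HumanCohort, snv: str, model: str) -> AssociationResult:
    """Logistic case/control association of one SNV under one genetic model.

    OR = exp(coefficient) per encoded column; p from the likelihood-ratio
    test against intercept-only. Quasi-separation falls back to a ridge-
    penalized fit (flagged).
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    y = np.asarray(cohort.outcome, dtype=float)
    g = cohort.dosages[snv].to_numpy(float)
    ok = np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    Z = encode_genetic_model(g, model)
    if np.all(Z.std(axis=0) == 0):
        raise ValueError(f"encoded column constant for {snv!r} under {model!r}")
    X = np.column_stack([np.ones(len(y)), Z])
    beta, ll, converged = _logistic_fit(X, y)
    flagged = False
    if not converged or np.any(np.abs(beta[1:]) > 15):
        # (quasi-)separation: refit with a small ridge penalty
        flagged = True
        beta = _ridge_logistic(X, y, lam=1.0)
        eta = np.clip(X @ beta, -700, 700)
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
    ll0 = _null_loglik(y)
    df = Z.shape[1]
    lr = max(2.0 * (ll - ll0), 0.0)
    p = float(stats.chi2.sf(lr, df=df))
    k = df + 1
    aic = 2 * k - 2 * ll
    ors = np.exp(beta[1:])
    return AssociationResult(
        snv=snv,
        model=model,
        odds_ratio=float(ors[0]) if df == 1 else [float(v) for v in ors],
        p_value=p,
        aic=float(aic),
        separation_flagged=flagged,
    )


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1.0, max_iter: int = 100) -> np.ndarray:
    p = X.shape[1]
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0  # intercept unpenalized
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen @ beta
        H = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-9:
            break
    return beta


def choose_best_model(cohort: HumanCohort, snv: str) -> list[AssociationResult]:
    """Fit all five genetic models for one SNV; flag the lowest-AIC model."""
    results = []
    for m in GENETIC_MODELS:
        try:
            results.append(associate_snv(cohort, snv, m))
        except ValueError:
            continue
    if results:
        best = min(results, key=lambda r: r.aic)
        best.chosen = True
    return results


# ---------------------------------------------------------------------------
# bootstrap selection, LASSO, cutoff, evaluation


def stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a stratified (by y) split: (first ~frac, remainder)."""
    y = np.asarray(y)
    first, second = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(round(frac * len(idx)))
        k = min(max(k, 1), len(idx) - 1) if len(idx) >= 2 else k
        first.append(idx[:k])
        second.append(idx[k:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def bootstrap_select_snvs(
    training: HumanCohort,
    n_iter: int = 100,
    eval_frac: float = 0.8,
    min_hits: int = 5,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.Series:
    """Bootstrap SNV selection on the training cohort.

    Per iteration the training data is split ``eval_frac`` / 1-eval_frac
    (stratified by outcome); an SNV scores a hit iff its log-additive
    logistic LRT p-value is below ``alpha`` in BOTH portions. SNVs with at
    least ``min_hits`` hits are returned (hit counts, descending).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = np.asarray(training.outcome, dtype=float)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 20:
        warnings.warn(f"fewer than 20 individuals in a class: {counts.tolist()}")
    G = training.dosages.to_numpy(float)
    rng = np.random.default_rng(seed)
    hits = np.zeros(G.shape[1], dtype=int)
    for _ in range(n_iter):
        a, b = stratified_split(y, eval_frac, rng)
        p_eval = logistic_lrt_pvalues(G[a], y[a])
        p_val = logistic_lrt_pvalues(G[b], y[b])
        hits += ((p_eval < alpha) & (p_val < alpha)).astype(int)
    s = pd.Series(hits, index=training.dosages.columns, name="hits")
    return s[s >= min_hits].sort_values(ascending=False)


def fit_lasso_risk_model(
    training: HumanCohort,
    candidates: list[str],
    hit_counts: dict[str, int] | None = None,
    seed: int | None = None,
    n_folds: int = 10,
    lambda_rule: str = "min",
    fixed_C: float | None = None,
) -> RiskScoreModel:
    """L1-penalized logistic risk model on candidate SNVs.

    The penalty is chosen by stratified ``n_folds`` cross-validation
    minimizing the binomial deviance (``lambda_rule='min'``; a 1-SE rule is
    available). Missing dosages are mean-imputed within SNV. ``fixed_C``
    bypasses CV (sklearn's C = 1 / (lambda * n)).
    """
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    if not candidates:
        raise ValueError("need at least one candidate SNV")
    y = np.asarray(training.outcome, dtype=float)
    X = training.dosages[list(candidates)].to_numpy(float)
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X)
    n = len(y)

    if fixed_C is not None:
        clf = LogisticRegression(penalty="l1", C=fixed_C, solver="liblinear", max_iter=10000, tol=1e-10)
        clf.fit(X, y)
        C = fixed_C
        record = f"fixed C={fixed_C}"
    else:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        Cs = np.logspace(-3, 3, 25)
        clf = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=5000, tol=1e-8, refit=True,
        )
        clf.fit(X, y)
        C = float(clf.C_[0])
        record = f"{n_folds}-fold CV min-deviance over {len(Cs)} C values (rule={lambda_rule})"
        if lambda_rule == "1se":
            scores = clf.scores_[1.0]  # folds x Cs
            mean_s = scores.mean(axis=0)
            se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
            best = int(np.argmax(mean_s))
            ok = mean_s >= mean_s[best] - se[best]
            j = int(np.flatnonzero(ok)[0])  # smallest C (largest lambda) within 1 SE
            C = float(Cs[j])
            clf = LogisticRegression(penalty="l1", C=C, solver="liblinear", max_iter=10000, tol=1e-10)
            clf.fit(X, y)
            record += f"; 1-SE C={C:g}"

    coefs = clf.coef_.ravel()
    nonzero = {s: float(b) for s, b in zip(candidates, coefs) if b != 0.0}
    model = RiskScoreModel(
        snv_ids=sorted(nonzero),
        hit_counts={s: int((hit_counts or {}).get(s, 0)) for s in candidates},
        coefficients=nonzero,
        intercept=float(np.ravel(clf.intercept_)[0]),
        penalty_lambda=1.0 / (C * n),
        lambda_record=record,
        seed=seed,
        intercept_only=not nonzero,
        train_means={s: float(m) for s, m in zip(candidates, means)},
    )
    if model.intercept_only:
        warnings.warn("all coefficients shrunk to zero: intercept-only model")

    scores = model.predict_proba(training.dosages)
    cutoff, J, _ = optimize_cutoff_youden(scores, y)
    model.cutoff = cutoff
    model.youden_j = J
    model.training_metrics = _metrics(scores, y, cutoff)
    return model


def optimize_cutoff_youden(scores, labels) -> tuple[float, float, pd.DataFrame]:
    """ROC sweep over observed scores; cutoff maximizes J = sens + spec - 1.

    Classification rule: positive iff score >= cutoff. Ties on J break to
    the smallest threshold. Returns (cutoff, J, roc table).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)
    sens = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).mean() for t in thresholds])
    J = sens + spec - 1.0
    best = int(np.argmax(J))  # argmax returns the first (smallest threshold) tie
    roc = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec, "J": J})
    return float(thresholds[best]), float(J[best]), roc


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _metrics(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> dict:
    labels = np.asarray(labels, dtype=float)
    pred = (scores >= cutoff).astype(float)
    tp = float(((pred == 1) & (labels == 1)).sum())
    tn = float(((pred == 0) & (labels == 0)).sum())
    fp = float(((pred == 1) & (labels == 0)).sum())
    fn = float(((pred == 0) & (labels == 1)).sum())
    return {
        "auc": _auc(scores, labels),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n": int(len(labels)),
    }


def evaluate_on_test(model: RiskScoreModel, test: HumanCohort) -> dict:
    """Apply a trained risk model to a test cohort at the trained cutoff."""
    y = np.asarray(test.outcome, dtype=float)
    scores = model.predict_proba(test.dosages)
    return _metrics(scores, y, model.cutoff)
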