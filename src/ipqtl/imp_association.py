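"""Associate intermediate molecular phenotype (IMP) levels with pathophenotypes.

Covers qPCR relative quantification (2^-ddCt), the cohort median age split,
normality-gated correlation and two-group tests, multiple-regression IMP
selection, and PCA with a median split of the phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IMPPanel",
    "ddct_fold_change",
    "assign_age_groups",
    "is_normal_ks",
    "correlate_with_phenotype",
    "compare_groups",
    "select_imps",
    "pca_classify",
]


@dataclass
class IMPPanel:
    """Individuals x molecules matrix of myocardial levels.

    ``levels`` is a DataFrame (rows = individuals, columns = molecule names);
    ``molecule_class`` maps each molecule to protein / miRNA / telomere.
    """

    levels: pd.DataFrame
    molecule_class: dict[str, str] = field(default_factory=dict)
    condition: str = ""

    def __post_init__(self) -> None:
        if self.levels.columns.duplicated().any():
            raise ValueError("molecule names must be unique")
        vals = self.levels.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError("IMP levels must be finite or missing (NaN)")
        for m, k in self.molecule_class.items():
            if k not in ("protein", "miRNA", "telomere"):
                raise ValueError(f"unknown molecule class {k!r} for {m!r}")

    @property
    def molecules(self) -> list[str]:
        return list(self.levels.columns)


def ddct_fold_change(ct_target_s: float, ct_ref_s: float, ct_target_c: float, ct_ref_c: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target_sample - Ct_ref_sample) - (Ct_target_calibrator -
    Ct_ref_calibrator); the fold change is 2 to the minus ddCt.
    """
    cts = (ct_target_s, ct_ref_s, ct_target_c, ct_ref_c)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_s - ct_ref_s) - (ct_target_c - ct_ref_c)
    return float(2.0 ** (-ddct))


def assign_age_groups(ages) -> tuple[np.ndarray, float]:
    """Median split of ages into young (< median) and old (>= median).

    Returns (labels array of 'young'/'old', median). All-equal ages yield
    all 'old' (the >= rule) with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least two ages")
    med = float(np.median(ages))
    labels = np.where(ages < med, "young", "old")
    if np.all(labels == "old"):
        warnings.warn("all ages at or above the median: every individual labeled old")
    return labels, med


def is_normal_ks(x: np.ndarray, alpha: float = 0.05, lilliefors: bool = False) -> bool:
    """Kolmogorov-Smirnov normality gate.

    Default: one-sample KS against a normal with the sample mean/SD.
    ``lilliefors=True`` applies the Lilliefors correction instead.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
    else:
        _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return bool(p >= alpha)


def correlate_with_phenotype(
    x, y, alpha: float = 0.05, lilliefors: bool = False
) -> tuple[str, float, float]:
    """KS-gated correlation: Pearson iff both variables pass normality.

    Returns (method, coefficient, p). Pairwise-complete observations are
    used; a constant vector raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need >= 5 paired non-missing values")
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    if is_normal_ks(xv, alpha, lilliefors) and is_normal_ks(yv, alpha, lilliefors):
        r, p = stats.pearsonr(xv, yv)
        return "pearson", float(r), float(p)
    rho, p = stats.spearmanr(xv, yv)
    return "spearman", float(rho), float(p)


def compare_groups(
    values, labels, alpha: float = 0.05, lilliefors: bool = False
) -> tuple[str, float, float]:
    """KS-gated two-group comparison: t-test iff both groups pass normality.

    Returns (test, statistic, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 observations")
    if is_normal_ks(a, alpha, lilliefors) and is_normal_ks(b, alpha, lilliefors):
        t, p = stats.ttest_ind(a, b)
        return "t", float(t), float(p)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann-whitney", float(u), float(p)


def _prune_collinear(X: pd.DataFrame, vif_max: float = 10.0) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns by highest variance-inflation factor until all below cap."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    dropped: list[str] = []
    X = X.copy()
    while X.shape[1] > 1:
        arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        vifs = [variance_inflation_factor(arr, j + 1) for j in range(X.shape[1])]
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        dropped.append(X.columns[worst])
        X = X.drop(columns=X.columns[worst])
    return X, dropped


def select_imps(
    panel: IMPPanel,
    phenotype,
    alpha_entry: float = 0.05,
    vif_max: float = 10.0,
) -> pd.DataFrame:
    """Screen IMPs univariately, then fit a multiple regression on survivors.

    Candidates are molecules whose KS-gated correlation with the phenotype
    has p < ``alpha_entry``; a multiple linear regression on the candidates
    (listwise-complete rows, VIF-pruned) yields coefficients and per-term
    p-values, ordered by p. An empty screen returns an empty table.
    """
    import statsmodels.api as sm

    if not panel.molecules:
        raise ValueError("panel has no candidate molecules")
    y = np.asarray(phenotype, dtype=float)

    screen = []
    for m in panel.molecules:
        x = panel.levels[m].to_numpy(float)
        try:
            method, coef, p = correlate_with_phenotype(x, y)
        except ValueError:
            continue
        if p < alpha_entry:
            screen.append((m, method, coef, p))
    if not screen:
        return pd.DataFrame(
            columns=["molecule", "screen_method", "screen_coef", "screen_p", "coefficient", "p_value"]
        )

    cand = [m for m, *_ in screen]
    df = panel.levels[cand].copy()
    df["__y"] = y
    df = df.dropna()
    X, dropped = _prune_collinear(df[cand], vif_max=vif_max)
    if dropped:
        warnings.warn(f"collinear IMPs pruned by VIF: {dropped}")
    fit = sm.OLS(df["__y"], sm.add_constant(X)).fit()

    rows = []
    for m, method, coef, p in screen:
        rows.append(
            {
                "molecule": m,
                "screen_method": method,
                "screen_coef": coef,
                "screen_p": p,
                "coefficient": float(fit.params[m]) if m in X.columns else np.nan,
                "p_value": float(fit.pvalues[m]) if m in X.columns else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values("p_value", na_position="last").reset_index(drop=True)
    return out


def pca_classify(levels: pd.DataFrame, phenotype) -> dict:
    """PCA of centered/unit-scaled variables plus a phenotype median split.

    Returns a dict with PC ``scores``, variable ``loadings``, explained
    variance ratios and per-individual ``labels`` ('high'/'low' by the
    phenotype median). Zero-variance variables are dropped with a warning.
    """
    from sklearn.decomposition import PCA

    if levels.shape[1] < 2 or levels.shape[0] < 4:
        raise ValueError("need >= 2 variables and >= 4 individuals")
    y = np.asarray(phenotype, dtype=float)
    df = levels.copy()
    keep = df.notna().all(axis=1) & np.isfinite(y)
    df, y = df.loc[keep], y[keep]

    sds = df.std(ddof=1)
    dead = list(sds.index[sds == 0])
    if dead:
        warnings.warn(f"zero-variance variables dropped: {dead}")
        df = df.drop(columns=dead)
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 variables remain after dropping constants")

    Z = (df - df.mean()) / df.std(ddof=1)
    k = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z.to_numpy(float))
    med = float(np.median(y))
    labels = np.where(y >= med, "high", "low")
    return {
        "scores": pd.DataFrame(scores, index=df.index, columns=[f"PC{i+1}" for i in range(k)]),
        "loadings": pd.DataFrame(
            pca.components_.T, index=df.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "labels": labels,
        "phenotype_median": med,
    }
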