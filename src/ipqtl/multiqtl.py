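"""Multi-QTL fixed models fitted by Haley-Knott regression.

A model is a set of loci (chromosome, cM position) and optional pairwise
interactions. The phenotype is regressed on P(het) at each locus (plus
products for interactions); model LOD = (n/2) log10(RSS0/RSS1) and percent
variance explained follows the identity %var = 100 (1 - 10^(-2 LOD / n)).
Term importance is assessed by drop-one refits with an F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics_core import GenotypeProbGrid

__all__ = [
    "QTLModelSpec",
    "ModelFit",
    "fit_qtl_model",
    "drop_one_analysis",
    "compare_models",
    "percent_variance",
]


def percent_variance(lod: float, n: int) -> float:
    """Percent phenotypic variance explained by a model with the given LOD."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


@dataclass(frozen=True)
class QTLModelSpec:
    """Ordered loci and optional pairwise interactions between them."""

    loci: tuple[tuple[str, float], ...] = ()
    interactions: tuple[tuple[int, int], ...] = ()
    model_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("model loci must be distinct")
        for a, b in self.interactions:
            if not (0 <= a < len(self.loci) and 0 <= b < len(self.loci) and a != b):
                raise ValueError("interaction must reference two distinct listed loci")

    @property
    def term_names(self) -> list[str]:
        names = [f"{c}@{p:g}" for c, p in self.loci]
        names += [f"{names[a]}:{names[b]}" for a, b in self.interactions]
        return names


@dataclass
class ModelFit:
    spec: QTLModelSpec
    lod: float
    percent_var: float
    n: int
    rss0: float
    rss1: float
    drop_one: pd.DataFrame | None = None
    phenotype_name: str = ""
    stratum: str = ""
    notes: list[str] = field(default_factory=list)


def _design(probs: GenotypeProbGrid, spec: QTLModelSpec, rows: np.ndarray) -> np.ndarray:
    cols = [np.ones(int(rows.sum()))]
    locus_cols = []
    for chrom, pos in spec.loci:
        x = probs.locus_column(chrom, pos)[rows]
        locus_cols.append(x)
        cols.append(x)
    for a, b in spec.interactions:
        cols.append(locus_cols[a] * locus_cols[b])
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank via least squares."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    r = y - X @ beta
    return float(r @ r), int(rank)


def fit_qtl_model(
    probs: GenotypeProbGrid,
    phenotype,
    spec: QTLModelSpec,
    phenotype_name: str = "",
    stratum: str = "",
) -> ModelFit:
    """Fit a multi-locus Haley-Knott model; see module docstring.

    Raises ``ValueError`` on a rank-deficient design, naming the loci.
    """
    y = np.asarray(phenotype, dtype=float)
    rows = np.isfinite(y)
    n = int(rows.sum())
    n_terms = len(spec.loci) + len(spec.interactions)
    if n < n_terms + 5:
        raise ValueError(f"need n >= terms + 5 (n={n}, terms={n_terms})")
    yv = y[rows]
    yc = yv - yv.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0:
        raise ValueError("phenotype is constant")

    if n_terms == 0:
        return ModelFit(spec, 0.0, 0.0, n, rss0, rss0, phenotype_name=phenotype_name, stratum=stratum)

    X = _design(probs, spec, rows)
    rss1, rank = _rss(X, yv)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design for loci {spec.term_names}")
    notes = []
    if rss1 <= rss0 * 1e-12:
        rss1 = max(rss1, rss0 * 1e-12)
        notes.append("perfect fit: LOD capped")
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    lod = max(lod, 0.0)
    return ModelFit(
        spec=spec,
        lod=float(lod),
        percent_var=percent_variance(float(lod), n),
        n=n,
        rss0=rss0,
        rss1=rss1,
        phenotype_name=phenotype_name,
        stratum=stratum,
        notes=notes,
    )


def drop_one_analysis(fit: ModelFit, probs: GenotypeProbGrid, phenotype) -> pd.DataFrame:
    """Drop-one-term-at-a-time table for a fitted model.

    Dropping a locus also drops the interactions that reference it. For each
    term the reduced model is refitted; the table reports the LOD drop and
    an F-test p-value (df = number of dropped design columns); a term is
    flagged retained iff p < 0.05.
    """
    spec = fit.spec
    n_loci = len(spec.loci)
    if n_loci + len(spec.interactions) == 0:
        raise ValueError("model has no terms to drop")

    y = np.asarray(phenotype, dtype=float)
    rows = np.isfinite(y)
    yv = y[rows]
    n = fit.n
    X_full = _design(probs, spec, rows)
    rss_full, _ = _rss(X_full, yv)
    p_full = X_full.shape[1]

    records = []
    terms = spec.term_names
    for t in range(n_loci + len(spec.interactions)):
        if t < n_loci:
            keep_loci = tuple(l for i, l in enumerate(spec.loci) if i != t)
            remap = {i: (i if i < t else i - 1) for i in range(n_loci) if i != t}
            keep_inter = tuple(
                (remap[a], remap[b]) for a, b in spec.interactions if a != t and b != t
            )
        else:
            keep_loci = spec.loci
            keep_inter = tuple(
                x for i, x in enumerate(spec.interactions) if i != t - n_loci
            )
        reduced = QTLModelSpec(loci=keep_loci, interactions=keep_inter)
        if len(reduced.loci) + len(reduced.interactions) == 0:
            rc = yv - yv.mean()
            rss_red = float(rc @ rc)
        else:
            X_red = _design(probs, reduced, rows)
            rss_red, _ = _rss(X_red, yv)
        df_drop = p_full - (1 + len(reduced.loci) + len(reduced.interactions))
        d_lod = (n / 2.0) * np.log10(max(rss_red, 1e-300) / max(rss_full, 1e-300))
        d_lod = max(float(d_lod), 0.0)
        df_resid = n - p_full
        if rss_red <= rss_full * (1 + 1e-12):
            pval = 1.0
            fstat = 0.0
        else:
            fstat = ((rss_red - rss_full) / df_drop) / (rss_full / df_resid)
            pval = float(stats.f.sf(fstat, df_drop, df_resid))
        records.append(
            {
                "term": terms[t],
                "df": df_drop,
                "delta_lod": d_lod,
                "F": fstat,
                "p_value": pval,
                "retained": pval < 0.05,
            }
        )
    table = pd.DataFrame(records)
    fit.drop_one = table
    return table


def compare_models(basal: ModelFit, extended: list[ModelFit]) -> pd.DataFrame:
    """Comparison table of a basal fit against extended fits (same stratum).

    An extended model counts as an improvement only if every term added
    beyond the basal loci passes the drop-one p < 0.05 rule (drop-one tables
    must have been computed on the extended fits).
    """
    for f in extended:
        if f.n != basal.n:
            raise ValueError("all fits must use the same individuals (n mismatch)")
    basal_terms = set(basal.spec.term_names)
    rows = [
        {
            "model_id": basal.spec.model_id or "basal",
            "components": "; ".join(basal.spec.term_names) or "(null)",
            "lod": basal.lod,
            "percent_var": basal.percent_var,
            "delta_percent_var": 0.0,
            "improvement": False,
            "worst_added_term_p": np.nan,
        }
    ]
    for f in extended:
        added = [t for t in f.spec.term_names if t not in basal_terms]
        if f.drop_one is not None and added:
            sub = f.drop_one[f.drop_one["term"].isin(added)]
            all_pass = bool(sub["retained"].all()) and len(sub) == len(added)
            worst_p = float(sub["p_value"].max()) if len(sub) else np.nan
        else:
            all_pass = False
            worst_p = np.nan
        rows.append(
            {
                "model_id": f.spec.model_id or "; ".join(f.spec.term_names),
                "components": "; ".join(f.spec.term_names),
                "lod": f.lod,
                "percent_var": f.percent_var,
                "delta_percent_var": f.percent_var - basal.percent_var,
                "improvement": all_pass and f.percent_var > basal.percent_var,
                "worst_added_term_p": worst_p,
            }
        )
    return pd.DataFrame(rows)
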