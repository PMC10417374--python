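"""Genome scans and LOD-peak handling for a backcross.

Two scan engines are provided: interval mapping by EM (normal mixture with
genotype-class means and common variance, genotype weights from the HMM
posterior) and Haley-Knott regression (phenotype regressed on P(het)).
Peaks are classified as significant (LOD > 3) or suggestive (1.5 <= LOD < 3)
and condition-specific peaks are consolidated by support-interval overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics_core import GenotypeProbGrid

__all__ = [
    "ScanResult",
    "QTLPeak",
    "scan_em",
    "scan_hk",
    "classify_peaks",
    "consolidate_qtls",
]

#: LOD value reported when the alternative fits perfectly (RSS1 == 0)
LOD_CAP = 1e6

SIGNIFICANT_LOD = 3.0
SUGGESTIVE_LOD = 1.5


@dataclass
class ScanResult:
    """LOD curve from a genome scan."""

    trait: str
    method: str  # "em" or "hk"
    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    lod: dict[str, np.ndarray]
    n_used: int
    stratum: str = ""
    converged: bool = True

    def max_lod(self) -> float:
        return max(float(np.max(self.lod[c])) for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chromosomes:
            for p, l in zip(self.positions[c], self.lod[c]):
                rows.append((c, p, l))
        df = pd.DataFrame(rows, columns=["chromosome", "position_cM", "lod"])
        df["trait"] = self.trait
        df["method"] = self.method
        df["stratum"] = self.stratum
        return df


@dataclass
class QTLPeak:
    chromosome: str
    position: float
    lod: float
    klass: str  # "significant" | "suggestive"
    support_lo: float
    support_hi: float
    condition: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not (self.support_lo <= self.position <= self.support_hi):
            raise ValueError("support interval must contain the peak")


def _check_phenotype(y: np.ndarray, min_n: int = 10) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < min_n:
        raise ValueError(f"need >= {min_n} non-missing phenotype values")
    if np.var(y[ok]) == 0:
        raise ValueError("phenotype is constant")
    return ok


def _hk_lod_columns(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized single-predictor regression LOD for each column of p."""
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    xc = p - p.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0 - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = np.maximum(rss1, 0.0)
    lod = np.where(
        rss1 > rss0 * 1e-12,
        (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / np.where(rss1 > 0, rss1, 1.0)),
        LOD_CAP,
    )
    lod = np.where(sxx > 0, lod, 0.0)  # monomorphic column: no predictor
    return np.maximum(lod, 0.0)


def scan_hk(
    probs: GenotypeProbGrid,
    phenotype,
    trait: str = "trait",
    stratum: str = "",
    min_n: int = 10,
) -> ScanResult:
    """Haley-Knott genome scan: regress phenotype on P(het) at each position.

    LOD = (n/2) log10(RSS0 / RSS1) with RSS0 the intercept-only residual sum
    of squares. A perfect fit (RSS1 = 0) is capped at ``LOD_CAP``.
    """
    y = np.asarray(phenotype, dtype=float)
    ok = _check_phenotype(y, min_n)
    yv = y[ok]
    lod: dict[str, np.ndarray] = {}
    for c in probs.chromosomes:
        lod[c] = _hk_lod_columns(probs.p_het[c][ok], yv)
    return ScanResult(
        trait=trait,
        method="hk",
        chromosomes=list(probs.chromosomes),
        positions={c: probs.grid_positions[c].copy() for c in probs.chromosomes},
        lod=lod,
        n_used=int(ok.sum()),
        stratum=stratum,
    )


def _em_mixture_lod(
    w: np.ndarray, y: np.ndarray, tol: float = 1e-4, max_iter: int = 4000
) -> tuple[float, bool]:
    """LOD at one position: 2-component normal mixture vs single normal.

    w is the prior P(het) per individual from the HMM; EM updates genotype
    posteriors using the phenotype. Means differ by class, sigma is common.
    """
    n = len(y)
    var0 = np.var(y)
    ll_null = -0.5 * n * (math.log(2 * math.pi * var0) + 1.0)

    pi = w.copy()
    # initialize from the prior weights
    mu0 = np.average(y, weights=np.maximum(1 - pi, 1e-9))
    mu1 = np.average(y, weights=np.maximum(pi, 1e-9))
    sig2 = var0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        inv2s = 0.5 / sig2
        d0 = -inv2s * (y - mu0) ** 2
        d1 = -inv2s * (y - mu1) ** 2
        m = np.maximum(d0, d1)
        num1 = w * np.exp(d1 - m)
        num0 = (1 - w) * np.exp(d0 - m)
        tot = num0 + num1
        pi = num1 / tot
        ll = float(np.sum(np.log(tot) + m)) - 0.5 * n * math.log(2 * math.pi * sig2)
        if abs(ll - ll_old) < tol:
            ll_old = ll
            converged = True
            break
        ll_old = ll
        s1 = pi.sum()
        s0 = n - s1
        if s1 < 1e-12 or s0 < 1e-12:
            # one class empty: mixture degenerates to the null
            return 0.0, True
        mu1 = float(pi @ y) / s1
        mu0 = float((1 - pi) @ y) / s0
        sig2 = float(pi @ (y - mu1) ** 2 + (1 - pi) @ (y - mu0) ** 2) / n
        if sig2 < 1e-12 * var0:
            return LOD_CAP, True
    lod = (ll_old - ll_null) / math.log(10)
    return max(lod, 0.0), converged


def scan_em(
    probs: GenotypeProbGrid,
    phenotype,
    trait: str = "trait",
    stratum: str = "",
    tol: float = 1e-4,
    max_iter: int = 4000,
    min_n: int = 10,
) -> ScanResult:
    """Interval-mapping genome scan with the EM algorithm.

    At each grid position a two-component normal mixture (class means, common
    sigma) is fitted by EM with the HMM heterozygote probabilities as mixing
    weights; LOD compares it against a single normal.
    """
    y = np.asarray(phenotype, dtype=float)
    ok = _check_phenotype(y, min_n)
    yv = y[ok]
    lod: dict[str, np.ndarray] = {}
    all_converged = True
    for c in probs.chromosomes:
        p = probs.p_het[c][ok]
        out = np.empty(p.shape[1])
        for j in range(p.shape[1]):
            out[j], conv = _em_mixture_lod(p[:, j], yv, tol=tol, max_iter=max_iter)
            all_converged &= conv
        lod[c] = out
    return ScanResult(
        trait=trait,
        method="em",
        chromosomes=list(probs.chromosomes),
        positions={c: probs.grid_positions[c].copy() for c in probs.chromosomes},
        lod=lod,
        n_used=int(ok.sum()),
        stratum=stratum,
        converged=all_converged,
    )


def _support_interval(pos: np.ndarray, lod: np.ndarray, peak_idx: int, drop: float) -> tuple[float, float]:
    """1.5-LOD (by default) drop support interval around a peak index."""
    thr = lod[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def _local_maxima(lod: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus contribute their leftmost index."""
    out = []
    n = len(lod)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and lod[k + 1] == lod[j]:
            k += 1
        left_ok = j == 0 or lod[j - 1] < lod[j]
        right_ok = k == n - 1 or lod[k + 1] < lod[j]
        if left_ok and right_ok:
            out.append(j)
        j = k + 1
    return out


def classify_peaks(
    scan: ScanResult,
    significant: float = SIGNIFICANT_LOD,
    suggestive: float = SUGGESTIVE_LOD,
    valley_drop: float = 1.5,
    support_drop: float = 1.5,
    condition: str = "",
) -> list[QTLPeak]:
    """Extract classified peaks from a scan.

    One peak per chromosome-local maximum above the suggestive threshold;
    secondary maxima on the same chromosome are kept only when separated
    from every retained peak by a valley at least ``valley_drop`` LOD below
    the lower of the two peaks. Ties break to the leftmost position.
    """
    peaks: list[QTLPeak] = []
    for c in scan.chromosomes:
        lod = scan.lod[c]
        pos = scan.positions[c]
        cands = [j for j in _local_maxima(lod) if lod[j] >= suggestive]
        cands.sort(key=lambda j: (-lod[j], pos[j]))
        kept: list[int] = []
        for j in cands:
            separated = True
            for k in kept:
                lo, hi = min(j, k), max(j, k)
                valley = float(np.min(lod[lo : hi + 1]))
                if valley > min(lod[j], lod[k]) - valley_drop:
                    separated = False
                    break
            if separated:
                kept.append(j)
        for j in sorted(kept, key=lambda j: pos[j]):
            klass = "significant" if lod[j] > significant else "suggestive"
            s_lo, s_hi = _support_interval(pos, lod, j, support_drop)
            peaks.append(
                QTLPeak(
                    chromosome=c,
                    position=float(pos[j]),
                    lod=float(lod[j]),
                    klass=klass,
                    support_lo=s_lo,
                    support_hi=s_hi,
                    condition=condition or scan.stratum,
                    trait=scan.trait,
                )
            )
    return peaks


@dataclass
class ConsolidatedQTL:
    """One registry entry: overlapping condition-specific peaks merged."""

    qtl_id: int
    chromosome: str
    position: float  # position of the strongest member peak
    max_lod: float
    support_lo: float
    support_hi: float
    members: list[QTLPeak] = field(default_factory=list)

    @property
    def conditions(self) -> list[str]:
        return [f"{p.trait}|{p.condition}" for p in self.members]


def consolidate_qtls(peaks: list[QTLPeak]) -> list[ConsolidatedQTL]:
    """Merge same-chromosome peaks whose support intervals overlap.

    Transitive overlap merges into a single registry entry (connected
    components of the interval-overlap graph); entries are numbered
    sequentially in (chromosome, position) order.
    """
    by_chrom: dict[str, list[QTLPeak]] = {}
    chrom_order: list[str] = []
    for p in peaks:
        if p.chromosome not in by_chrom:
            by_chrom[p.chromosome] = []
            chrom_order.append(p.chromosome)
        by_chrom[p.chromosome].append(p)

    entries: list[ConsolidatedQTL] = []
    for c in chrom_order:
        ps = sorted(by_chrom[c], key=lambda p: (p.support_lo, p.support_hi))
        cluster: list[QTLPeak] = []
        hi = -np.inf
        for p in ps:
            if cluster and p.support_lo > hi:
                entries.append(_make_entry(c, cluster))
                cluster = []
                hi = -np.inf
            cluster.append(p)
            hi = max(hi, p.support_hi)
        if cluster:
            entries.append(_make_entry(c, cluster))

    entries.sort(key=lambda e: (chrom_order.index(e.chromosome), e.position))
    for i, e in enumerate(entries, start=1):
        e.qtl_id = i
    return entries


def _make_entry(chrom: str, cluster: list[QTLPeak]) -> ConsolidatedQTL:
    best = max(cluster, key=lambda p: p.lod)
    return ConsolidatedQTL(
        qtl_id=0,
        chromosome=chrom,
        position=best.position,
        max_lod=best.lod,
        support_lo=min(p.support_lo for p in cluster),
        support_hi=max(p.support_hi for p in cluster),
        members=list(cluster),
    )


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": p.chromosome,
                "position_cM": p.position,
                "lod": p.lod,
                "class": p.klass,
                "support_lo": p.support_lo,
                "support_hi": p.support_hi,
                "trait": p.trait,
                "condition": p.condition,
            }
            for p in peaks
        ]
    )
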