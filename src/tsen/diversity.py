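"""Alpha diversity, rarefaction, Bray-Curtis, and Welch differential tests.

Shannon entropy is reported in nats so that Pielou evenness J = H / ln(S)
is consistent; Chao1 uses the classic estimator S + F1^2/(2*F2) with the
standard bias-corrected fallback S + F1*(F1-1)/2 when no doubletons exist.
Rarefaction is the exact hypergeometric expectation, not a subsampling
average.  Differential proportion testing between two sample groups is the
two-sided Welch t-test with the Welch-inverted confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

__all__ = [
    "DiversityReport",
    "DifferentialResult",
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis",
    "welch_differential",
]


@dataclass
class DiversityReport:
    """Alpha-diversity descriptors for one sample."""

    s_obs: int
    shannon: float  # nats
    pielou: float | None  # None when S_obs <= 1 (undefined)
    chao1: float
    rarefaction: list[tuple[int, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "s_obs": self.s_obs,
            "shannon": self.shannon,
            "pielou": self.pielou,
            "chao1": self.chao1,
        }


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("counts must contain at least one positive value")
    return c


def alpha_diversity(counts, base: float = math.e) -> DiversityReport:
    """Observed richness, Shannon H, Pielou J and Chao1 for a count vector."""
    c = _check_counts(counts)
    pos = c[c > 0]
    s_obs = int(pos.size)
    h = float(_skbio_shannon(c, base=base))
    pielou = h / (math.log(s_obs, base)) if s_obs > 1 else None
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if f2 > 0:
        ch = float(_skbio_chao1(c.astype(int), bias_corrected=False))
    else:
        ch = s_obs + f1 * (f1 - 1) / 2.0
    return DiversityReport(s_obs, h, pielou, ch)


def rarefaction_curve(counts, depths) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth (exact hypergeometric).

    E[S_d] = sum_i ( 1 - C(N - N_i, d) / C(N, d) ) for a sample of total
    count N rarefied to depth d without replacement.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    n_total = c.sum()
    curve: list[tuple[int, float]] = []
    for d in np.atleast_1d(depths):
        d = int(d)
        if d < 0 or d > n_total:
            raise ValueError(f"depth {d} exceeds total count {int(n_total)}")
        # log-space binomial ratio, stable for large counts
        log_ratio = (
            special.gammaln(n_total - c + 1)
            - special.gammaln(n_total - c - d + 1)
            - special.gammaln(n_total + 1)
            + special.gammaln(n_total - d + 1)
        )
        with np.errstate(invalid="ignore"):
            p_absent = np.where(n_total - c >= d, np.exp(log_ratio), 0.0)
        curve.append((d, float(np.sum(1.0 - p_absent))))
    return curve


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("x and y cannot both be all-zero")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DifferentialResult:
    """Welch differential-proportion result for one taxon."""

    taxon: object
    delta: float  # mean(A) - mean(B)
    ci_low: float | None
    ci_high: float | None
    t: float | None
    df: float | None
    p: float | None  # None when a group has < 2 samples
    q: float | None  # Benjamini-Hochberg adjusted p
    significant: bool


def _welch_one(a: np.ndarray, b: np.ndarray, ci_level: float):
    na, nb = a.size, b.size
    delta = float(a.mean() - b.mean())
    if na < 2 or nb < 2:
        return delta, None, None, None, None, None
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if delta == 0:
            return delta, delta, delta, 0.0, float(na + nb - 2), 1.0
        return delta, delta, delta, math.inf, float(na + nb - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(ci_level)
    return (
        delta,
        float(ci.low),
        float(ci.high),
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
    )


def welch_differential(
    props_a: pd.DataFrame,
    props_b: pd.DataFrame,
    ci_level: float = 0.95,
    p_cut: float = 0.005,
) -> list[DifferentialResult]:
    """Per-taxon Welch t-test of mean proportions between two sample groups.

    ``props_a`` / ``props_b`` are taxa x samples proportion frames sharing a
    taxon index.  With fewer than 2 samples in a group only the difference in
    mean proportions is reported (no CI, no p, never flagged significant),
    mirroring designs with a single sample per condition.  Raw p is compared
    to ``p_cut`` for the significance flag; Benjamini-Hochberg q-values are
    reported alongside.
    """
    if not props_a.index.equals(props_b.index):
        raise ValueError("both groups must share the same taxon index")
    out: list[DifferentialResult] = []
    raw: list[float | None] = []
    parts = []
    for taxon in props_a.index:
        a = props_a.loc[taxon].to_numpy(dtype=float)
        b = props_b.loc[taxon].to_numpy(dtype=float)
        delta, lo, hi, t, df, p = _welch_one(a, b, ci_level)
        raw.append(p)
        parts.append((taxon, delta, lo, hi, t, df, p))
    defined = [p for p in raw if p is not None]
    qmap: dict[int, float] = {}
    if defined:
        idx = [i for i, p in enumerate(raw) if p is not None]
        q = _benjamini_hochberg(np.asarray(defined))
        qmap = dict(zip(idx, q))
    for i, (taxon, delta, lo, hi, t, df, p) in enumerate(parts):
        out.append(
            DifferentialResult(
                taxon, delta, lo, hi, t, df, p,
                q=float(qmap[i]) if i in qmap else None,
                significant=(p is not None and p < p_cut),
            )
        )
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(ranked, 0, 1)
    return q


def differential_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabular TSV-ready view of Welch differential results."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon, "delta": r.delta, "ci_lo": r.ci_low,
                "ci_hi": r.ci_high, "t": r.t, "df": r.df, "p": r.p,
                "q": r.q, "significant": r.significant,
            }
            for r in results
        ]
    )
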