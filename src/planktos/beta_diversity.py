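"""Bray–Curtis beta diversity, its Baselga partition, and temporal trends.

The Bray–Curtis dissimilarity between two count vectors x, y is

    BC = 1 − 2·Σᵢ min(xᵢ, yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ)

and decomposes additively (Baselga) into a balanced-variation component
(abundance replacement between taxa) and an abundance-gradient component
(uniform abundance loss from one sample to the other):

    A = Σ min(x, y),  B = Σ(x − min),  C = Σ(y − min)
    total    = (B + C) / (2A + B + C)
    balanced = min(B, C) / (A + min(B, C))
    gradient = total − balanced

Time-lag analysis regresses pairwise dissimilarity on elapsed time
between the two samples; a positive slope indicates directional
community change. Distance matrices are scikit-bio DistanceMatrix
objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .data_model import OtuTable

__all__ = ["BetaPartition", "TimeLagFit", "bray_curtis_matrix",
           "partition_bray_curtis", "pairwise_partition",
           "time_lag_regression", "nmds", "niche_breadth",
           "abundance_occupancy"]


@dataclass(frozen=True)
class BetaPartition:
    total: float
    balanced: float
    gradient: float


@dataclass(frozen=True)
class TimeLagFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


def bray_curtis_matrix(table: OtuTable) -> DistanceMatrix:
    """All-pairs Bray–Curtis dissimilarity over samples."""
    if (table.sample_totals == 0).any():
        raise ValueError("zero-total sample")
    mat = table.counts.to_numpy().T.astype(float)
    return DistanceMatrix(squareform(pdist(mat, metric="braycurtis")),
                          ids=[str(s) for s in table.sample_ids])


def partition_bray_curtis(x, y) -> BetaPartition:
    """Baselga partition of Bray–Curtis into balanced + gradient parts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the OTU axis")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("zero-total sample")
    a = np.minimum(x, y).sum()
    b = (x - np.minimum(x, y)).sum()
    c = (y - np.minimum(x, y)).sum()
    if b + c == 0:
        return BetaPartition(0.0, 0.0, 0.0)
    total = (b + c) / (2 * a + b + c)
    balanced = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else total
    return BetaPartition(float(total), float(balanced),
                         float(total - balanced))


def pairwise_partition(table: OtuTable) -> pd.DataFrame:
    """Long-format Baselga partition for every unordered sample pair."""
    cols = table.sample_ids
    arr = table.counts.to_numpy().astype(float)
    rows = []
    for i, j in combinations(range(len(cols)), 2):
        p = partition_bray_curtis(arr[:, i], arr[:, j])
        rows.append({"sample_i": cols[i], "sample_j": cols[j],
                     "bc": p.total, "balanced": p.balanced,
                     "gradient": p.gradient})
    return pd.DataFrame(rows)


def time_lag_regression(dist: DistanceMatrix, dates: pd.Series,
                        sqrt_lag: bool = False) -> TimeLagFit:
    """OLS of pairwise dissimilarity on pairwise time lag.

    ``dates`` maps sample id to its sampling-event ordinal. All unordered
    pairs enter the regression; lags are |date_i − date_j| (optionally
    square-rooted for the classic time-lag-analysis variant). Slope
    significance comes from the regression t test.
    """
    ids = list(dist.ids)
    d = dates.reindex(ids).to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("dates missing for some samples")
    lags, diss = [], []
    for i, j in combinations(range(len(ids)), 2):
        lags.append(abs(d[i] - d[j]))
        diss.append(dist[i, j])
    lags = np.asarray(lags)
    if len(np.unique(lags)) < 3:
        raise ValueError("need at least 3 distinct time lags")
    if sqrt_lag:
        lags = np.sqrt(lags)
    res = stats.linregress(lags, np.asarray(diss))
    return TimeLagFit(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=float(res.rvalue ** 2),
                      p_value=float(res.pvalue), n_pairs=len(diss))


def nmds(dist: DistanceMatrix, k: int = 2, seed: int = 0,
         n_restarts: int = 4) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling of a distance matrix.

    Kruskal stress-1 is minimized by SMACOF with random restarts
    (sklearn); coordinates are centered. Returns (coordinates, stress).
    """
    import inspect

    from sklearn.manifold import MDS

    kw = {"n_components": k, "n_init": n_restarts, "random_state": seed,
          "normalized_stress": True}
    params = inspect.signature(MDS).parameters
    if "metric_mds" in params:
        # post-1.9 naming: `metric` is the dissimilarity spec,
        # `metric_mds` toggles metric vs non-metric scaling
        kw.update(metric="precomputed", metric_mds=False)
    else:
        kw.update(dissimilarity="precomputed", metric=False)
    if "init" in params:
        kw["init"] = "random"
    mds = MDS(**kw)
    coords = mds.fit_transform(dist.data)
    coords = coords - coords.mean(axis=0)
    df = pd.DataFrame(coords, index=list(dist.ids),
                      columns=[f"NMDS{i + 1}" for i in range(k)])
    return df, float(mds.stress_)


def niche_breadth(table: OtuTable, otu_ids=None) -> pd.Series:
    """Levins' niche breadth B = 1/ΣPᵢ² per OTU.

    Pᵢⱼ is the proportion of OTU j's reads found in sample i (the OTU's
    profile row-normalized over samples), so B ranges from 1 (restricted
    to one sample) to the number of samples (perfectly even). OTUs absent
    everywhere get NaN.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    if otu_ids is not None:
        counts = counts.loc[list(otu_ids)]
    totals = counts.sum(axis=1)
    p = counts.div(totals.replace(0, np.nan), axis=0)
    return (1.0 / (p ** 2).sum(axis=1, min_count=1)).rename("levins_b")


def abundance_occupancy(table: OtuTable) -> dict:
    """Abundance–occupancy relationship across OTUs.

    Occupancy (fraction of samples with a positive count) is regressed
    on log10 mean relative abundance; Spearman correlation is reported
    alongside the OLS fit.
    """
    counts = table.counts.to_numpy().astype(float)
    rel = counts / counts.sum(axis=0)
    mean_rel = rel.mean(axis=1)
    occ = (counts > 0).mean(axis=1)
    keep = mean_rel > 0
    mean_rel, occ = mean_rel[keep], occ[keep]
    if np.unique(occ).size < 2 or np.unique(mean_rel).size < 3:
        raise ValueError("degenerate occupancy or abundance variance")
    res = stats.linregress(np.log10(mean_rel), occ)
    rho, p_rho = stats.spearmanr(mean_rel, occ)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue),
            "spearman_rho": float(rho), "spearman_p": float(p_rho),
            "n_otus": int(keep.sum())}
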