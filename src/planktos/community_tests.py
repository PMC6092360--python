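"""Permutation-based multivariate community tests.

ANOSIM tests whether between-group dissimilarities exceed within-group
ones on ranks (statistic R in [−1, 1]); SIMPER decomposes the average
between-group Bray–Curtis into per-OTU contributions; the Mantel test
correlates two distance matrices over their upper triangles; IndVal
scores each OTU's specificity (A) and fidelity (B) for a sample group
and reports sqrt(A·B), tested by permuting sample labels.

All permutation p-values use the add-one estimator

    p = (1 + #{perm stat ≥ observed}) / (1 + n_permutations)

with ties counted as ≥, so p is never 0 and the floor for 999
permutations is 1/1000. ANOSIM additionally supports exhaustive
enumeration of all label permutations for small n, where the exact tail
probability is returned instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _all_perms

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .data_model import OtuTable, SampleFrame

logger = logging.getLogger(__name__)

__all__ = ["PermTestResult", "anosim", "simper", "mantel", "env_distance",
           "indval", "indicator_records", "indicator_counts"]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def _condensed_pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = 0, exact: bool = False) -> PermTestResult:
    """Analysis of similarities.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 pairwise distances ranked with midranks. R near 1 means
    groups are well separated; R < 0 indicates more similarity between
    than within groups.

    With ``exact=True`` every permutation of the label vector is
    enumerated (practical for n ≲ 8) and the exact tail probability
    #{R_perm ≥ R_obs}/n! is reported.
    """
    groups = pd.Series(groups, index=list(dist.ids)) \
        if not isinstance(groups, pd.Series) else groups.reindex(list(dist.ids))
    labels = pd.factorize(groups)[0]
    sizes = np.bincount(labels)
    if (sizes < 2).any() or len(sizes) < 2:
        raise ValueError("every group needs at least 2 samples")
    n = len(labels)
    ii, jj = _condensed_pair_index(n)
    ranks = rankdata(squareform(dist.data, checks=False))
    within = labels[ii] == labels[jj]
    r_obs = _anosim_r(ranks, within)

    if exact:
        total = 0
        hits = 0
        for perm in _all_perms(labels):
            perm = np.asarray(perm)
            total += 1
            if _anosim_r(ranks, perm[ii] == perm[jj]) >= r_obs - 1e-12:
                hits += 1
        return PermTestResult(float(r_obs), hits / total, total, None)

    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _anosim_r(ranks, lab[ii] == lab[jj]) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(float(r_obs), float(p), n_perm, seed)


def simper(table: OtuTable, groups, group_pair: tuple | None = None
           ) -> pd.DataFrame:
    """Similarity-percentage decomposition of between-group Bray–Curtis.

    For every between-group sample pair (x, y) the contribution of OTU i
    is |xᵢ − yᵢ| / Σₖ(xₖ + yₖ); these reassemble the pair's Bray–Curtis
    exactly. Contributions are averaged over pairs and expressed as
    percent of the mean between-group dissimilarity, sorted descending
    with cumulative percentages. With more than two groups pass
    ``group_pair`` to choose which two to contrast.
    """
    groups = pd.Series(groups, index=table.sample_ids) \
        if not isinstance(groups, pd.Series) else groups.reindex(table.sample_ids)
    uniq = list(pd.unique(groups.dropna()))
    if group_pair is None:
        if len(uniq) != 2:
            raise ValueError("more than 2 groups: specify group_pair")
        group_pair = (uniq[0], uniq[1])
    g1 = groups.index[groups == group_pair[0]]
    g2 = groups.index[groups == group_pair[1]]
    arr = table.counts.astype(float)
    contrib = np.zeros(table.n_otus)
    n_pairs = 0
    for s1 in g1:
        x = arr[s1].to_numpy()
        for s2 in g2:
            y = arr[s2].to_numpy()
            contrib += np.abs(x - y) / (x.sum() + y.sum())
            n_pairs += 1
    contrib /= n_pairs
    mean_bc = contrib.sum()
    out = pd.DataFrame({
        "mean_contribution": contrib,
        "pct": 100.0 * contrib / mean_bc,
    }, index=table.counts.index).sort_values("pct", ascending=False)
    out["cum_pct"] = out["pct"].cumsum()
    out.attrs["mean_between_bc"] = float(mean_bc)
    return out


def mantel(dist_a: DistanceMatrix, dist_b: DistanceMatrix,
           method: str = "spearman", n_perm: int = 999,
           seed: int | None = 0) -> PermTestResult:
    """Mantel correlation between two distance matrices.

    The correlation is computed over the n(n−1)/2 upper-triangle entries;
    significance comes from simultaneously permuting the rows and columns
    of one matrix. For Spearman, entries are rank-transformed once (the
    permutation only rearranges them), so permuted statistics are exact.
    """
    if list(dist_a.ids) != list(dist_b.ids):
        if set(dist_a.ids) != set(dist_b.ids):
            raise ValueError("distance matrices cover different samples")
        dist_b = dist_b.filter(dist_a.ids)
    n = len(dist_a.ids)
    a = dist_a.data.copy()
    b = dist_b.data.copy()
    if method == "spearman":
        a = squareform(rankdata(squareform(a, checks=False)))
        b = squareform(rankdata(squareform(b, checks=False)))
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    iu = np.triu_indices(n, k=1)

    def corr(mat_b):
        va, vb = a[iu], mat_b[iu]
        va = va - va.mean()
        vb = vb - vb.mean()
        return float((va * vb).sum() / np.sqrt((va ** 2).sum() * (vb ** 2).sum()))

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(b[np.ix_(p, p)]) >= r_obs - 1e-12:
            hits += 1
    pval = (1 + hits) / (1 + n_perm)
    return PermTestResult(float(r_obs), float(pval), n_perm, seed)


def env_distance(meta: SampleFrame, variable: str,
                 log_base: str = "natural") -> DistanceMatrix:
    """Pairwise distance on one (transformed) environmental variable.

    Numeric variables are log(x+1)-transformed (natural log by default,
    ``log_base='log10'`` for the decadic variant) with the exception of
    pH, which is used untransformed. The design factors ``period`` and
    ``depth`` are coded ordinally (1, 2, 3) before differencing. Samples
    with missing values are dropped pairwise (count logged).
    """
    if variable in ("period", "time", "Time"):
        vals = meta.period.cat.codes.astype(float) + 1
    elif variable in ("depth", "Depth"):
        order = {d: i + 1 for i, d in enumerate(
            [d for d in ("surface", "middle", "bottom")
             if d in set(meta.depth)] or sorted(set(meta.depth)))}
        vals = meta.depth.map(order).astype(float)
    else:
        if variable not in meta.env.columns:
            raise KeyError(f"unknown environmental variable {variable!r}")
        vals = meta.env[variable].astype(float)
        if variable.lower() != "ph":
            vals = np.log1p(vals) if log_base == "natural" else np.log10(vals + 1)
    vals = pd.Series(vals, index=meta.sample_ids)
    missing = vals.isna()
    if missing.any():
        logger.info("env_distance(%s): dropping %d samples with missing "
                    "values", variable, int(missing.sum()))
        vals = vals[~missing]
    v = vals.to_numpy()
    return DistanceMatrix(np.abs(v[:, None] - v[None, :]),
                          ids=[str(s) for s in vals.index])


def _indval_components(rel: np.ndarray, presence: np.ndarray,
                       membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean specificity A and fidelity B matrices (groups × OTUs)."""
    sizes = membership.sum(axis=1, keepdims=True)
    means = membership @ rel.T / sizes
    denom = means.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    b = membership @ presence.T / sizes
    return a, b


def indval(table: OtuTable, groups, n_perm: int = 999, seed: int | None = 0
           ) -> pd.DataFrame:
    """Indicator-value analysis of OTUs against sample groups.

    Per OTU and group g: A (specificity) is the group's mean relative
    abundance divided by the sum of all groups' means (group means, so
    unequal group sizes do not bias A); B (fidelity) is the fraction of
    g's samples where the OTU occurs. The indicator statistic is
    sqrt(A·B) for the best group (argmax), with a permutation p-value
    from reshuffling sample labels (add-one estimator, ties as ≥).

    OTUs absent everywhere are skipped with a log entry.
    """
    groups = pd.Series(groups, index=table.sample_ids) \
        if not isinstance(groups, pd.Series) else groups.reindex(table.sample_ids)
    labels, uniq = pd.factorize(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = table.counts.to_numpy().astype(float)
    observed = counts.sum(axis=1) > 0
    if not observed.all():
        logger.info("indval: skipping %d OTUs absent everywhere",
                    int((~observed).sum()))
    rel = counts / counts.sum(axis=0)
    presence = (counts > 0).astype(float)
    n = table.n_samples
    member = np.zeros((len(uniq), n))
    member[labels, np.arange(n)] = 1.0

    a, b = _indval_components(rel, presence, member)
    stat = np.sqrt(a * b)
    best = stat.argmax(axis=0)
    cols = np.arange(stat.shape[1])
    obs = stat[best, cols]

    rng = np.random.default_rng(seed)
    hits = np.zeros(stat.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap, bp = _indval_components(rel[:, perm], presence[:, perm], member)
        hits += (np.sqrt(ap * bp).max(axis=0) >= obs - 1e-12)
    pvals = (1 + hits) / (1 + n_perm)

    out = pd.DataFrame({
        "best_group": np.asarray(uniq)[best],
        "A": a[best, cols],
        "B": b[best, cols],
        "stat": obs,
        "p_value": pvals,
    }, index=table.counts.index)
    return out[observed]


def indicator_records(indval_table: pd.DataFrame, stat_threshold: float = 0.7,
                      p_threshold: float = 0.05) -> pd.DataFrame:
    """Strict indicators: stat > threshold and permutation p < threshold."""
    keep = (indval_table["stat"] > stat_threshold) & \
           (indval_table["p_value"] < p_threshold)
    return indval_table[keep]


def indicator_counts(records: pd.DataFrame) -> pd.Series:
    """Per-group indicator counts plus their total."""
    counts = records["best_group"].value_counts()
    counts.loc["total"] = counts.sum()
    return counts
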