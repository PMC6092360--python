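"""Sloan neutral community model for occupancy–abundance data.

The model predicts the frequency with which an OTU of metacommunity mean
relative abundance p is detected (above the detection limit d) across
local communities assembled purely by random drift and immigration:

    freq(p) = 1 − BetaCDF(d; Nm·p, Nm·(1 − p))

where Nm is the metacommunity size times the immigration rate — the one
free parameter — and d is the detection limit, taken as one read out of
the rarefied depth N (d = 1/N) by default. Nm is estimated by bounded
nonlinear least squares of predicted against observed occurrence
frequencies, and the goodness of fit R² = 1 − SSE/SStot measures how
much of the occupancy–abundance relationship neutral assembly explains.
A 95% binomial (Wilson) envelope around the fitted curve partitions
OTUs into those occurring more often (above), as often (within) or less
often (below) than the neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .data_model import OtuTable

__all__ = ["NcmFit", "ncm_predict", "ncm_fit", "ncm_fit_frequencies"]

_LOG_NM_BOUNDS = (0.0, np.log(1e7))
_MULTISTARTS = (np.log(10.0), np.log(1e3), np.log(1e5))


@dataclass
class NcmFit:
    nm: float
    r_squared: float
    n: int                  # local community size (reads per sample)
    d: float                # detection limit (proportion)
    per_otu: pd.DataFrame = field(repr=False)

    @property
    def partition_fractions(self) -> pd.Series:
        frac = self.per_otu["partition"].value_counts(normalize=True)
        return frac.reindex(["above", "within", "below"], fill_value=0.0)

    def r_squared_for(self, otu_ids) -> float:
        """Goodness of fit restricted to a subset of OTUs.

        Uses the Nm fitted on the full table (post-hoc restriction), so
        e.g. the rare subcommunity's R² measures how well the community-
        wide neutral curve explains rare-taxon occupancy.
        """
        sub = self.per_otu.loc[self.per_otu.index.intersection(list(otu_ids))]
        if len(sub) < 3:
            raise ValueError("too few OTUs in subset")
        sse = ((sub["obs_freq"] - sub["pred_freq"]) ** 2).sum()
        sstot = ((sub["obs_freq"] - sub["obs_freq"].mean()) ** 2).sum()
        return float(1.0 - sse / sstot) if sstot > 0 else float("nan")


def ncm_predict(p, nm: float, d: float):
    """Predicted occurrence frequency for mean relative abundance ``p``.

    Boundary inputs p = 0 / p = 1 return 0 / 1 exactly.
    """
    if nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 < d < 1):
        raise ValueError("detection limit must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.empty_like(p)
    inner = (p > 0) & (p < 1)
    out[p <= 0] = 0.0
    out[p >= 1] = 1.0
    out[inner] = beta_dist.sf(d, nm * p[inner], nm * (1.0 - p[inner]))
    return float(out[0]) if scalar else out


def ncm_fit_frequencies(p: np.ndarray, freq: np.ndarray, d: float,
                        n_samples: int) -> tuple[float, float, pd.DataFrame]:
    """Fit Nm to (mean relative abundance, occurrence frequency) pairs.

    Returns (Nm, R², per-OTU frame with predictions, Wilson 95% bounds
    and the above/within/below partition). This is the core estimator;
    :func:`ncm_fit` derives p and freq from an OTU table and delegates
    here.
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)

    def sse(log_nm: float) -> float:
        resid = ncm_predict(p, np.exp(log_nm), d) - freq
        return float((resid ** 2).sum())

    candidates = []
    scalar = optimize.minimize_scalar(sse, bounds=_LOG_NM_BOUNDS,
                                      method="bounded",
                                      options={"xatol": 1e-10})
    candidates.append((float(scalar.x), float(scalar.fun)))
    for start in _MULTISTARTS:
        local = optimize.minimize(lambda v: sse(v[0]), x0=[start],
                                  bounds=[_LOG_NM_BOUNDS], method="L-BFGS-B")
        candidates.append((float(local.x[0]), float(local.fun)))
    best = min(candidates, key=lambda c: c[1])
    if not np.isfinite(best[1]):
        raise RuntimeError(
            f"Nm optimization failed within bounds {np.exp(_LOG_NM_BOUNDS)}")
    nm = float(np.exp(best[0]))
    sstot = float(((freq - freq.mean()) ** 2).sum())
    r_squared = 1.0 - best[1] / sstot if sstot > 0 else np.nan

    pred = ncm_predict(p, nm, d)
    lo, hi = proportion_confint(np.round(pred * n_samples), n_samples,
                                alpha=0.05, method="wilson")
    partition = np.where(freq > hi, "above",
                         np.where(freq < lo, "below", "within"))
    per_otu = pd.DataFrame({"p": p, "obs_freq": freq, "pred_freq": pred,
                            "ci_lo": lo, "ci_hi": hi,
                            "partition": partition})
    return nm, float(r_squared), per_otu


def ncm_fit(table: OtuTable, d: float | None = None,
            otu_ids=None) -> NcmFit:
    """Fit the neutral model to an OTU table's occupancy–abundance data.

    p is each OTU's mean relative abundance across samples (zeros
    included in the mean); observed frequency is its occupancy. N is the
    per-sample read depth (the table should be rarefied; the minimum
    column total is used otherwise) and d defaults to 1/N. Nm is
    optimized over log(Nm) in [1, 1e7] from three deterministic
    multistarts. ``otu_ids`` restricts the per-OTU records (e.g. to the
    rare subcommunity) after computing p on the full table.
    """
    counts = table.counts.to_numpy().astype(float)
    n_reads = int(table.sample_totals.min())
    if d is None:
        d = 1.0 / n_reads
    rel = counts / counts.sum(axis=0)
    p = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    keep = (p > 0) & (p < 1)
    if keep.sum() < 10:
        raise ValueError("too few OTUs with informative abundance to fit")
    nm, r_squared, per_otu = ncm_fit_frequencies(p[keep], freq[keep], d,
                                                 table.n_samples)
    per_otu.index = table.counts.index[keep]
    if otu_ids is not None:
        per_otu = per_otu.loc[per_otu.index.intersection(list(otu_ids))]
    return NcmFit(nm=nm, r_squared=float(r_squared), n=n_reads, d=float(d),
                  per_otu=per_otu)
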