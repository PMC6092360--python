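"""Alpha diversity, Preston log-normal coverage, and two-way ANOVA.

Shannon entropy uses natural logarithms (nats); Simpson is reported in
the Gini–Simpson form 1 − Σp². Chao1 (classic form S + F1²/2F2) and ACE
delegate to scikit-bio. The Preston fit bins the pooled species-abundance
distribution into doubling octaves, fits a Gaussian to the visible
octaves by least squares and extrapolates the area beyond the veil line
to estimate the fraction of total richness the sampling recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .data_model import OtuTable

__all__ = ["AlphaIndices", "PrestonFit", "alpha_indices", "alpha_table",
           "preston_fit", "two_way_anova", "rarefaction_curve"]


@dataclass(frozen=True)
class AlphaIndices:
    richness: int
    shannon: float        # nats
    simpson: float        # 1 - sum p^2
    pielou: float
    chao1: float
    ace: float


@dataclass(frozen=True)
class PrestonFit:
    mode: float           # octave of the fitted Gaussian peak
    width: float          # Gaussian sd in octaves
    s0: float             # modal octave height (species)
    s_est: float          # extrapolated total richness
    s_obs: int
    sampled_fraction: float


def alpha_indices(counts, chao1_bias_corrected: bool = False) -> AlphaIndices:
    """Alpha-diversity indices for one sample's count vector."""
    x = np.asarray(counts)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    p = x / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p ** 2).sum())
    richness = int(x.size)
    # Pielou undefined at richness 1; by convention a single-species
    # community is perfectly even.
    pielou = 1.0 if richness == 1 else shannon / np.log(richness)
    chao = float(_skbio_chao1(x.astype(int), bias_corrected=chao1_bias_corrected))
    try:
        ace_val = float(_skbio_ace(x.astype(int)))
    except ValueError:
        # undefined when every rare taxon is a singleton; flag as NaN
        ace_val = float("nan")
    return AlphaIndices(richness=richness, shannon=shannon, simpson=simpson,
                        pielou=pielou, chao1=chao, ace=ace_val)


def alpha_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha indices as a DataFrame (samples × indices)."""
    rows = {s: alpha_indices(table.counts[s].to_numpy())
            for s in table.sample_ids}
    return pd.DataFrame({s: vars(v) for s, v in rows.items()}).T


def _octave_histogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Preston octaves with the standard half-split of boundary counts.

    Octave k covers abundances in (2^(k-1), 2^k); a species whose
    abundance is exactly 2^k contributes one half to octave k and one
    half to octave k+1.
    """
    octs = np.ceil(np.log2(x)).astype(int)
    octs[x <= 1] = 0
    n_oct = octs.max() + 2
    freq = np.zeros(n_oct)
    exact = (np.log2(x) % 1 == 0)
    for o, e in zip(octs, exact):
        if e:
            freq[o] += 0.5
            freq[o + 1] += 0.5
        else:
            freq[o] += 1.0
    return np.arange(n_oct), freq


def preston_fit(pooled_counts) -> PrestonFit:
    """Fit a truncated Preston log-normal to pooled OTU abundances.

    A Gaussian S(o) = S0·exp(−(o−mode)²/2·width²) is fitted by least
    squares to the occupied octaves only, which makes the fit truncated
    at the veil line: octaves hidden left of the detection limit simply
    contribute no points. The extrapolated richness is the area under
    the untruncated Gaussian, S0·width·√(2π).
    """
    x = np.asarray(pooled_counts, dtype=float)
    x = x[x > 0]
    octaves, freq = _octave_histogram(x)
    occupied = freq > 0
    if occupied.sum() < 3:
        raise ValueError("need at least 3 occupied octaves for a Preston fit")
    o, f = octaves[occupied], freq[occupied]

    def model(params):
        mode, width, s0 = params
        return s0 * np.exp(-((o - mode) ** 2) / (2.0 * width ** 2)) - f

    start = np.array([o[np.argmax(f)], max(1.0, np.ptp(o) / 4), f.max()])
    res = optimize.least_squares(
        model, start, bounds=([-20, 0.1, 0.0], [o.max() + 20, 50, np.inf]))
    mode, width, s0 = res.x
    s_est = float(s0 * width * np.sqrt(2 * np.pi))
    s_obs = int(x.size)
    frac = min(1.0, s_obs / s_est) if s_est > 0 else 1.0
    return PrestonFit(mode=float(mode), width=float(width), s0=float(s0),
                      s_est=max(s_est, float(s_obs)), s_obs=s_obs,
                      sampled_fraction=frac)


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction.

    Uses type-II sums of squares (equivalent to the classical balanced
    decomposition when the design is balanced). Returns a DataFrame with
    rows for each main effect, the interaction and the residual, and
    columns sum_sq, df, F, p.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "a": np.asarray(factor_a, dtype=object),
                       "b": np.asarray(factor_b, dtype=object)})
    cells = df.groupby(["a", "b"], observed=True).size()
    full = pd.MultiIndex.from_product([df["a"].unique(), df["b"].unique()])
    empty = [c for c in full if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    tab = tab.rename(index={"C(a)": names[0], "C(b)": names[1],
                            "C(a):C(b)": f"{names[0]}x{names[1]}",
                            "Residual": "residual"})
    return tab.rename(columns={"PR(>F)": "p"})


def rarefaction_curve(table: OtuTable, depths=None, n_seeds: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean observed richness per sample over a grid of rarefaction depths.

    Plotting export: each grid point averages ``n_seeds`` independent
    without-replacement subsamples.
    """
    from .data_model import rarefy

    min_total = int(table.sample_totals.min())
    if depths is None:
        depths = np.unique(np.linspace(1, min_total, 12).astype(int))
    records = []
    for d in depths:
        rich = np.zeros(table.n_samples)
        for k in range(n_seeds):
            sub = rarefy(table, int(d), seed=seed * n_seeds + k)
            rich += (sub.counts.to_numpy() > 0).sum(axis=0)
        for s, r in zip(table.sample_ids, rich / n_seeds):
            records.append({"sample_id": s, "depth": int(d), "richness": r})
    return pd.DataFrame(records)
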