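"""Synthetic OTU tables with known ground truth.

Three generators provide the statistical structure the analysis
pipeline assumes, each returning its ground truth alongside the data:

- :func:`simulate_neutral_table` draws a long-tailed (log-normal)
  metacommunity and assembles every sample by a Dirichlet-multinomial
  kernel with concentration Nm·p — the diffusion-limit sampling model
  behind the Sloan neutral prediction — so occupancy–abundance structure
  follows the neutral expectation.
- :func:`simulate_succession` adds three-period directional succession:
  period metacommunities drift apart by a log-abundance random walk, and
  designated indicator OTUs are boosted only within their own period.
- :func:`simulate_modular_counts` plants correlated OTU blocks: module
  members load on a per-module latent factor that also drives designated
  environmental variables, giving block-wise correlation structure for
  network tests.

The default shape mirrors a bloom-succession survey: 18 samples = 3
periods × 3 depths × 2 sampling dates, 10,000 reads per sample
(desk-scale stand-in for deep amplicon sequencing), and a log-normal
species-abundance distribution (σ = 3 on the log scale) tuned so that
roughly 2% of observed OTUs classify abundant and ~90% rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DEPTH_LEVELS, PERIOD_LEVELS, OtuTable, SampleFrame

__all__ = ["SimulationConfig", "NeutralSim", "SuccessionSim", "ModularSim",
           "simulate_neutral_table", "simulate_succession",
           "simulate_modular_counts", "default_sample_frame"]


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults shared by the generators (see module docstring)."""

    n_otus: int = 2000
    n_samples: int = 18
    depth: int = 10_000          # reads per sample
    sad_mean: float = 0.0        # log-normal SAD location
    sad_sigma: float = 3.0       # log-normal SAD width
    nm: float = 1000.0           # Dirichlet-multinomial concentration
    n_periods: int = 3
    turnover_rate: float = 0.75  # sd of the per-period log-abundance walk
    n_indicators: int = 20       # boosted OTUs per period
    indicator_effect: float = 10.0
    n_modules: int = 4
    otus_per_module: int = 25
    module_loading: float = 2.0  # latent loading of module members
    module_noise_sd: float = 0.5
    background_noise_sd: float = 1.0
    n_env: int = 4
    env_loading: float = 1.0
    env_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_otus, self.n_samples, self.depth) < 1:
            raise ValueError("counts must be positive")
        if self.turnover_rate < 0:
            raise ValueError("turnover_rate must be >= 0")
        if self.nm <= 0:
            raise ValueError("Nm must be positive")


@dataclass
class NeutralSim:
    table: OtuTable
    meta: SampleFrame
    p_meta: pd.Series = field(repr=False)   # metacommunity relative abundances
    config: SimulationConfig = SimulationConfig()


@dataclass
class SuccessionSim:
    table: OtuTable
    meta: SampleFrame
    indicators: dict[str, list[str]]         # period -> planted indicator ids
    p_periods: pd.DataFrame = field(repr=False)
    config: SimulationConfig = SimulationConfig()


@dataclass
class ModularSim:
    table: OtuTable
    meta: SampleFrame
    modules: pd.Series                       # OTU id -> planted module (−1 = none)
    env_modules: dict[str, int]              # env variable -> driving module
    latents: pd.DataFrame = field(repr=False)
    config: SimulationConfig = SimulationConfig()


def default_sample_frame(n_samples: int, n_periods: int = 3,
                         env: pd.DataFrame | None = None) -> SampleFrame:
    """Balanced period × depth × date design over ``n_samples`` samples.

    Samples are split evenly over periods; within a period, depths cycle
    surface/middle/bottom and the date index advances every
    ``n_depths`` samples, giving the 3 × 3 × 2 layout at n = 18.
    """
    ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    per_period = n_samples // n_periods
    periods, depths, dates = [], [], []
    for i in range(n_samples):
        t = min(i // per_period, n_periods - 1)
        periods.append(PERIOD_LEVELS[t] if n_periods <= 3 else f"period {t + 1}")
        within = i % per_period
        depths.append(DEPTH_LEVELS[within % 3])
        dates.append(t * max(1, per_period // 3) + within // 3 + 1)
    idx = pd.Index(ids, name="sample_id")
    return SampleFrame(
        period=pd.Series(periods, index=idx),
        depth=pd.Series(depths, index=idx),
        date_index=pd.Series(dates, index=idx, dtype=int),
        env=env if env is not None else pd.DataFrame(index=idx))


def _lognormal_sad(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    logp = cfg.sad_mean + cfg.sad_sigma * rng.standard_normal(cfg.n_otus)
    p = np.exp(logp)
    return p / p.sum()


def _dm_sample(p: np.ndarray, nm: float, depth: int,
               rng: np.random.Generator) -> np.ndarray:
    """One sample: Dirichlet(Nm·p) composition, then multinomial reads."""
    alpha = np.maximum(nm * p, 1e-300)
    g = rng.gamma(alpha)
    total = g.sum()
    if total == 0:  # pathological tiny-Nm corner: fall back to p itself
        g = p.copy()
        total = g.sum()
    return rng.multinomial(depth, g / total)


def _as_table(counts: np.ndarray, meta: SampleFrame) -> OtuTable:
    otu_ids = [f"OTU{i + 1:05d}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                      columns=meta.sample_ids)
    return OtuTable(df)


def simulate_neutral_table(config: SimulationConfig | None = None,
                           **overrides) -> NeutralSim:
    """Neutrally assembled OTU table (see module docstring)."""
    cfg = _resolve(config, overrides)
    rng = np.random.default_rng(cfg.seed)
    p = _lognormal_sad(cfg, rng)
    counts = np.column_stack([
        _dm_sample(p, cfg.nm, cfg.depth, rng) for _ in range(cfg.n_samples)])
    meta = default_sample_frame(cfg.n_samples, cfg.n_periods)
    table = _as_table(counts, meta)
    return NeutralSim(table=table, meta=meta,
                      p_meta=pd.Series(p, index=table.counts.index),
                      config=cfg)


def simulate_succession(config: SimulationConfig | None = None,
                        **overrides) -> SuccessionSim:
    """Three-period directional succession with planted indicators."""
    cfg = _resolve(config, overrides)
    if cfg.n_periods < 2:
        raise ValueError("need at least 2 periods")
    if cfg.n_indicators * cfg.n_periods > cfg.n_otus:
        raise ValueError("more indicator OTUs than OTUs")
    rng = np.random.default_rng(cfg.seed)
    meta = default_sample_frame(cfg.n_samples, cfg.n_periods)
    period_levels = list(meta.period.cat.categories)

    base_log = cfg.sad_mean + cfg.sad_sigma * rng.standard_normal(cfg.n_otus)
    logs = [base_log]
    for _ in range(cfg.n_periods - 1):
        step = cfg.turnover_rate * rng.standard_normal(cfg.n_otus)
        logs.append(logs[-1] + step)

    chosen = rng.choice(cfg.n_otus, size=cfg.n_indicators * cfg.n_periods,
                        replace=False)
    indicator_idx = {period_levels[t]:
                     chosen[t * cfg.n_indicators:(t + 1) * cfg.n_indicators]
                     for t in range(cfg.n_periods)}

    p_periods = {}
    for t, level in enumerate(period_levels):
        lg = logs[t].copy()
        mean_w = np.exp(lg).mean()
        # indicator abundance pinned at effect x the period's mean OTU
        # weight inside its own period, suppressed by the same factor
        # outside, so the planted signal is detectable by construction
        lg[indicator_idx[level]] = np.log(cfg.indicator_effect * mean_w)
        for other, idx in indicator_idx.items():
            if other != level:
                lg[idx] = np.minimum(lg[idx],
                                     np.log(mean_w / cfg.indicator_effect))
        p = np.exp(lg)
        p_periods[level] = p / p.sum()

    cols = []
    for s in meta.sample_ids:
        p = p_periods[str(meta.period[s])]
        cols.append(_dm_sample(p, cfg.nm, cfg.depth, rng))
    table = _as_table(np.column_stack(cols), meta)
    ids = table.counts.index
    indicators = {lvl: ids[idx].tolist() for lvl, idx in indicator_idx.items()}
    return SuccessionSim(table=table, meta=meta, indicators=indicators,
                         p_periods=pd.DataFrame(p_periods, index=ids),
                         config=cfg)


def simulate_modular_counts(config: SimulationConfig | None = None,
                            **overrides) -> ModularSim:
    """Planted correlated OTU blocks tied to environmental drivers.

    Defaults to a 150-OTU table (4 modules x 25 members + 50 background
    OTUs): the planted blocks need to carry a visible share of the reads,
    so the community-wide 2000-OTU default does not apply here.
    """
    if config is None and "n_otus" not in overrides:
        overrides = {**overrides, "n_otus": 150}
    cfg = _resolve(config, overrides)
    if cfg.n_modules < 2:
        raise ValueError("need at least 2 modules")
    n_member = cfg.n_modules * cfg.otus_per_module
    if n_member > cfg.n_otus:
        raise ValueError("otus_per_module x n_modules exceeds n_otus")
    rng = np.random.default_rng(cfg.seed)
    meta = default_sample_frame(cfg.n_samples, cfg.n_periods)

    latents = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    module_of = np.full(cfg.n_otus, -1)
    module_of[:n_member] = np.repeat(np.arange(cfg.n_modules),
                                     cfg.otus_per_module)
    # background OTUs are abundant and stable so they dominate each
    # sample's total: member relative abundances then stay monotone in
    # their module latent instead of being scrambled by compositional
    # renormalization
    base = np.where(module_of >= 0,
                    0.5 * rng.standard_normal(cfg.n_otus),
                    2.0 + 0.5 * rng.standard_normal(cfg.n_otus))
    log_abund = np.tile(base[:, None], (1, cfg.n_samples))
    for m in range(cfg.n_modules):
        members = module_of == m
        noise = cfg.module_noise_sd * rng.standard_normal(
            (members.sum(), cfg.n_samples))
        log_abund[members] += cfg.module_loading * latents[m] + noise
    # unstructured residual variation keeps non-member OTUs from forming
    # a spurious compositionally-correlated block
    background = module_of < 0
    log_abund[background] += cfg.background_noise_sd * rng.standard_normal(
        (int(background.sum()), cfg.n_samples))

    comp = np.exp(log_abund)
    comp /= comp.sum(axis=0)
    counts = np.column_stack([
        rng.multinomial(cfg.depth, comp[:, j]) for j in range(cfg.n_samples)])
    env = {}
    env_modules = {}
    for v in range(cfg.n_env):
        m = v % cfg.n_modules
        env_modules[f"env{v + 1}"] = m
        # exponentiated so variables are positive, like concentrations;
        # rank-based screens are unaffected by the monotone transform
        env[f"env{v + 1}"] = np.exp(
            cfg.env_loading * latents[m]
            + cfg.env_noise_sd * rng.standard_normal(cfg.n_samples))
    env_df = pd.DataFrame(env, index=pd.Index(meta.sample_ids,
                                              name="sample_id"))
    meta = default_sample_frame(cfg.n_samples, cfg.n_periods, env=env_df)
    table = _as_table(counts, meta)
    modules = pd.Series(module_of, index=table.counts.index, name="module")
    return ModularSim(table=table, meta=meta, modules=modules,
                      env_modules=env_modules,
                      latents=pd.DataFrame(latents.T, index=meta.sample_ids),
                      config=cfg)


def _resolve(config: SimulationConfig | None, overrides: dict
             ) -> SimulationConfig:
    if config is None:
        config = SimulationConfig()
    if overrides:
        from dataclasses import replace
        config = replace(config, **overrides)
    return config
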