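"""Abundance-class partitioning of OTUs.

Every OTU is assigned to exactly one of six categories from its per-sample
relative abundances, using an abundant cutoff (default 1%) and a rare
cutoff (default 0.01%):

- AAT  always abundant: ≥ abundant_cut in all samples
- CAT  conditionally abundant: ≥ rare_cut in all samples, ≥ abundant_cut
       in some but not all
- ART  always rare: < rare_cut in all samples
- CRT  conditionally rare: < rare_cut in some samples, never ≥ abundant_cut
- MT   moderate: within [rare_cut, abundant_cut) in all samples
- CRAT conditionally rare and abundant: spans the full range, from below
       rare_cut to at or above abundant_cut

AAT and CAT roll up to the abundant taxa (AT); ART and CRT to the rare
taxa (RT). Thresholds are compared with ≥ on the abundant side and strict
< on the rare side, so the moderate band owns [rare_cut, abundant_cut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import OtuTable

__all__ = [
    "ClassThresholds",
    "CATEGORIES",
    "ROLLUPS",
    "classify_otus",
    "class_proportions",
    "subcommunity_tables",
    "shared_otu_counts",
    "period_mean_abundance",
]

CATEGORIES = ("AAT", "CAT", "ART", "CRT", "MT", "CRAT")
ROLLUPS = ("AT", "RT", "MT", "CRAT")
_ROLLUP_OF = {"AAT": "AT", "CAT": "AT", "ART": "RT", "CRT": "RT",
              "MT": "MT", "CRAT": "CRAT"}


@dataclass(frozen=True)
class ClassThresholds:
    """Relative-abundance cutoffs (proportions, not percent)."""

    abundant_cut: float = 0.01    # 1%
    rare_cut: float = 0.0001      # 0.01%

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_cut < self.abundant_cut < 1.0):
            raise ValueError("need 0 < rare_cut < abundant_cut < 1")


def classify_otus(rel: pd.DataFrame,
                  thresholds: ClassThresholds = ClassThresholds()
                  ) -> pd.DataFrame:
    """Assign the six abundance categories from per-sample proportions.

    Parameters
    ----------
    rel
        Relative-abundance DataFrame (OTUs × samples, columns sum to 1).

    Returns
    -------
    DataFrame indexed by OTU id with columns ``category``, ``rollup``,
    ``min_rel``, ``max_rel``, ``mean_rel``. Exactly one category rule
    fires per OTU.
    """
    lo, hi = thresholds.rare_cut, thresholds.abundant_cut
    mn = rel.min(axis=1).to_numpy()
    mx = rel.max(axis=1).to_numpy()
    cat = np.empty(len(rel), dtype=object)
    cat[(mn >= lo) & (mx < hi)] = "MT"
    cat[(mn < lo) & (mx < hi)] = "CRT"
    cat[mx < lo] = "ART"
    cat[(mn < lo) & (mx >= hi)] = "CRAT"
    cat[(mn >= lo) & (mx >= hi)] = "CAT"
    cat[mn >= hi] = "AAT"
    out = pd.DataFrame({
        "category": cat,
        "rollup": [_ROLLUP_OF[c] for c in cat],
        "min_rel": mn,
        "max_rel": mx,
        "mean_rel": rel.mean(axis=1).to_numpy(),
    }, index=rel.index)
    return out


def class_proportions(classes: pd.DataFrame, by: str = "rollup") -> pd.DataFrame:
    """OTU counts and percentage shares per category or roll-up.

    Returns a DataFrame with columns ``n_otus`` and ``pct`` (percent of
    all classified OTUs, on the 0–100 scale).
    """
    counts = classes[by].value_counts()
    order = ROLLUPS if by == "rollup" else CATEGORIES
    counts = counts.reindex([c for c in order if c in counts.index])
    return pd.DataFrame({
        "n_otus": counts,
        "pct": 100.0 * counts / len(classes),
    })


def subcommunity_tables(table: OtuTable, classes: pd.DataFrame
                        ) -> dict[str, OtuTable]:
    """Split the count table into the AT / RT / MT / CRAT subcommunities.

    The returned tables partition the OTU set with counts unchanged; an
    empty subcommunity yields an empty (flagged) table.
    """
    unknown = set(classes.index) - set(table.otu_ids)
    if unknown:
        raise ValueError(f"classified OTUs absent from table: {sorted(unknown)[:5]}")
    missing = set(table.otu_ids) - set(classes.index)
    if missing:
        raise ValueError(f"unclassified OTUs: {sorted(missing)[:5]}")
    out: dict[str, OtuTable] = {}
    for label in ROLLUPS:
        ids = classes.index[classes["rollup"] == label]
        out[label] = table.select_otus(ids)
    return out


def shared_otu_counts(table: OtuTable, grouping: pd.Series) -> dict[str, int]:
    """Venn-region OTU counts over sample groups.

    An OTU belongs to a group when it has a positive count in at least one
    of the group's samples. Keys are ``"&"``-joined sorted group names;
    only OTUs present somewhere are counted, so the region counts sum to
    the number of observed OTUs.
    """
    grouping = grouping.reindex(table.sample_ids)
    groups = [g for g in pd.unique(grouping.dropna())]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    presence = {}
    for g in groups:
        cols = grouping.index[grouping == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no samples")
        presence[g] = table.counts[cols].sum(axis=1) > 0
    member = pd.DataFrame(presence)
    regions: dict[str, int] = {}
    for key, sub in member.groupby(list(member.columns)):
        present = [str(g) for g, flag in zip(member.columns, key) if flag]
        if present:
            regions["&".join(sorted(present))] = len(sub)
    return regions


def period_mean_abundance(rel: pd.DataFrame, grouping: pd.Series
                          ) -> pd.DataFrame:
    """Mean relative abundance of each OTU within each sample group.

    Also returns the three-way ternary coordinates (group means
    renormalized to sum to 1) when exactly three groups are given; OTUs
    absent everywhere get NaN coordinates and are flagged via the
    ``defined`` column.
    """
    grouping = grouping.reindex(rel.columns)
    means = rel.T.groupby(grouping, observed=True).mean().T
    total = means.sum(axis=1)
    out = means.copy()
    out.columns = [f"mean_{c}" for c in means.columns]
    out["defined"] = total > 0
    if means.shape[1] == 3:
        tern = means.div(total, axis=0)
        tern.columns = [f"ternary_{c}" for c in means.columns]
        out = pd.concat([out, tern], axis=1)
    return out
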