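"""Factor-combination audit and downsampling.

Public expression catalogs are heavily unbalanced: a handful of
(family, tissue, stress) combinations contribute most samples. This module
tallies the observed 3-way combinations against the number possible given
the observed factor levels, and caps the most common combinations by seeded
random subsampling so the robustness of the Mapper topology to sampling
bias can be tested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["ComboCountTable", "combo_counts", "downsample_top_combos"]

FACTORS = ["family", "tissue", "stress"]


@dataclasses.dataclass
class ComboCountTable:
    """Observed (family, tissue, stress) counts plus the possible-combination
    count implied by the observed factor levels."""

    counts: pd.DataFrame  # columns: family, tissue, stress, count
    n_possible: int

    @property
    def n_observed(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return int(self.counts["count"].sum())


def combo_counts(meta: pd.DataFrame) -> ComboCountTable:
    """Exact tally of observed 3-way factor combinations."""
    missing = [c for c in FACTORS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata missing factor column(s): {missing}")
    counts = (
        meta.groupby(FACTORS, observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["count", *FACTORS], ascending=[False, True, True, True], kind="mergesort")
        .reset_index(drop=True)
    )
    n_possible = int(np.prod([meta[c].nunique() for c in FACTORS])) if len(meta) else 0
    return ComboCountTable(counts=counts, n_possible=n_possible)


def downsample_top_combos(
    meta: pd.DataFrame, top_k: int = 30, cap: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Cap each of the ``top_k`` most common combinations at ``cap`` samples.

    The top_k combinations are ranked by count (ties by lexicographic
    triple); each is subsampled without replacement to min(count, cap) using
    the given seed. All samples outside the top_k combinations are retained
    untouched; the output preserves the input row order.
    """
    if top_k < 1 or cap < 1:
        raise ConfigurationError("top_k and cap must be >= 1")
    table = combo_counts(meta)
    rng = np.random.default_rng(seed)
    keep = pd.Series(True, index=meta.index)
    for _, row in table.counts.head(top_k).iterrows():
        combo_mask = (
            (meta["family"] == row["family"])
            & (meta["tissue"] == row["tissue"])
            & (meta["stress"] == row["stress"])
        )
        idx = meta.index[combo_mask]
        if len(idx) > cap:
            chosen = rng.choice(len(idx), size=cap, replace=False)
            drop = idx.delete(np.sort(chosen))
            keep.loc[drop] = False
    return meta.loc[keep].copy()
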