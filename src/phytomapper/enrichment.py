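"""Lens-correlated orthogroup ranking and gene-set enrichment.

Orthogroups are ranked by the Pearson correlation of their (log2) expression
with a lens; the extreme tails (default 2.5% per side) represent the genes
most characteristic of each end of the lens gradient — e.g. the negatively
tissue-lens-correlated tail is photosynthesis-flavoured. Tails are tested
for over/under-representation of a reference inventory (GreenCut2-style) by
an exact one-sided binomial test, and against flat term -> gene sets
(GO-style, no DAG semantics) by hypergeometric upper tails with
Benjamini-Hochberg correction.

Also houses the adjusted-R^2 (Wherry/McNemar) summary used to report how
strongly surrogate variables associate with study factors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, FormatError
from .lens import transform_expression

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "lens_correlation",
    "select_extremes",
    "binomial_enrichment",
    "flat_set_enrichment",
    "adjusted_r2",
    "read_gmt",
    "write_gmt",
]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap between selection and reference set
    n: int  # selection size
    p0: float  # background proportion of the reference set in the universe
    p_value: float
    direction: str  # "greater" or "less"


def lens_correlation(
    X: pd.DataFrame,
    f: pd.Series,
    transform: str = "log2",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of every orthogroup's expression with the lens values.

    Returns a DataFrame indexed by orthogroup with columns ``r`` and
    ``degenerate``; zero-variance rows (or a constant lens) get r = 0 with
    the degenerate flag set rather than NaN, keeping the ranking total.
    """
    shared = [s for s in X.columns if s in f.index]
    if len(shared) < 3:
        raise ConfigurationError("need at least 3 shared samples for correlation")
    T = transform_expression(X[shared], transform).to_numpy(dtype=float)
    y = f.loc[shared].to_numpy(dtype=float)
    if method == "spearman":
        T = stats.rankdata(T, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ConfigurationError(f"unknown correlation method: {method!r}")

    Tc = T - T.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    row_norm = np.linalg.norm(Tc, axis=1)
    y_norm = np.linalg.norm(yc)
    degenerate = (row_norm == 0.0) | (y_norm == 0.0)
    denom = np.where(degenerate, 1.0, row_norm * (y_norm if y_norm > 0 else 1.0))
    r = np.where(degenerate, 0.0, (Tc @ yc) / denom)
    return pd.DataFrame({"r": r, "degenerate": degenerate}, index=X.index)


def select_extremes(
    tbl: pd.DataFrame, tail_frac: float = 0.025
) -> tuple[list[str], list[str]]:
    """Top and bottom ``floor(tail_frac * N)`` orthogroups by correlation.

    Ties are broken by orthogroup id; degenerate (zero-variance) rows never
    enter a tail. N counts all table rows, so 2.5% of 6,328 orthogroups
    gives 158 per tail."""
    if not 0.0 < tail_frac < 0.5:
        raise ConfigurationError("tail_frac must be in (0, 0.5)")
    n_tail = int(np.floor(tail_frac * len(tbl)))
    if n_tail == 0:
        raise ConfigurationError("tail_frac * N rounds down to zero orthogroups")
    usable = tbl.loc[~tbl["degenerate"]].sort_index()
    k = min(n_tail, len(usable))
    # mergesort is stable, so the prior id sort breaks ties deterministically
    positive = list(usable.sort_values("r", ascending=False, kind="mergesort").index[:k])
    negative = list(usable.sort_values("r", ascending=True, kind="mergesort").index[:k])
    return positive, negative


def binomial_enrichment(
    selection: Iterable[str],
    reference: GeneSet,
    universe: Iterable[str],
    direction: str = "greater",
) -> EnrichmentResult:
    """Exact one-sided binomial test for reference-set membership in a
    selection, against the background proportion in the universe.

    ``p0 = |reference ∩ universe| / |universe|``; the p-value is
    ``P(X >= k)`` (greater) or ``P(X <= k)`` (less) for
    ``X ~ Binomial(|selection|, p0)``.
    """
    uni = set(universe)
    if not uni:
        raise ConfigurationError("empty universe")
    sel = set(selection)
    if not sel <= uni:
        raise ConfigurationError("selection is not a subset of the universe")
    if direction not in ("greater", "less"):
        raise ConfigurationError(f"direction must be 'greater' or 'less', got {direction!r}")
    p0 = len(reference.members & uni) / len(uni)
    k = len(sel & reference.members)
    n = len(sel)
    if direction == "greater":
        p = float(stats.binom.sf(k - 1, n, p0))
    else:
        p = float(stats.binom.cdf(k, n, p0))
    return EnrichmentResult(
        set_name=reference.name, k=k, n=n, p0=p0, p_value=min(p, 1.0), direction=direction
    )


def flat_set_enrichment(
    selection: Iterable[str],
    term_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of flat term -> gene sets.

    Per term: upper-tail probability of drawing at least the observed
    overlap when sampling ``|selection|`` genes from the universe without
    replacement; q-values are Benjamini-Hochberg across terms. Returns a
    DataFrame (term, k, n, K, p0, p, q); empty ``term_sets`` gives an empty
    frame."""
    uni = set(universe)
    if not uni:
        raise ConfigurationError("empty universe")
    sel = set(selection) & uni
    rows = []
    for term in term_sets:
        K = len(term.members & uni)
        k = len(sel & term.members)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, len(sel)))
        rows.append(
            {
                "term": term.name,
                "k": k,
                "n": len(sel),
                "K": K,
                "p0": K / len(uni),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "p0", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1); may be negative."""
    if not 0.0 <= r2 <= 1.0:
        raise ConfigurationError("r2 must lie in [0, 1]")
    if n <= p + 1:
        raise ConfigurationError("need n > p + 1 observations")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    sets = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: line {line_no} has fewer than 2 fields")
        name, desc, *members = parts
        sets.append(GeneSet(name=name, members=frozenset(m for m in members if m), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
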