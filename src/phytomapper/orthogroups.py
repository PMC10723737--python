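"""Cross-species orthogroup expression matrix assembly.

Reads orthogroup membership in the OrthoFinder ``Orthogroups.tsv`` dialect
(first column ``Orthogroup``, one column per species, cells holding
comma+space-separated gene lists), applies the conservation and copy-number
filters used to restrict the analysis to deeply conserved low-copy
orthogroups, sums gene-level TPMs to orthogroup level per species, and
merges the per-species matrices into one orthogroup x sample matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "OrthogroupTable",
    "GeneExpressionTable",
    "parse_orthogroups",
    "write_orthogroups",
    "filter_conserved",
    "aggregate_tpm",
    "merge_species",
]

logger = logging.getLogger(__name__)

GENE_SEP = ", "


@dataclasses.dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup id -> species id -> gene ids."""

    genes: dict[str, dict[str, list[str]]]
    species: list[str]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def orthogroup_ids(self) -> list[str]:
        return list(self.genes)

    def presence_count(self, og: str) -> int:
        """Number of species with at least one gene in this orthogroup."""
        return sum(bool(g) for g in self.genes[og].values())


@dataclasses.dataclass
class GeneExpressionTable:
    """Per-species gene-level TPMs (gene x sample)."""

    species: str
    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise FormatError(f"negative TPM values for species {self.species}")
        if self.tpm.columns.duplicated().any():
            raise FormatError(f"duplicate sample ids for species {self.species}")


def parse_orthogroups(path: str | Path, species_roster: Sequence[str]) -> OrthogroupTable:
    """Parse an ``Orthogroups.tsv`` file against a species roster."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    species_cols = list(df.columns[1:])
    unknown = set(species_cols) - set(species_roster)
    if unknown:
        raise FormatError(f"unknown species column(s): {sorted(unknown)}")
    og_col = df.columns[0]
    if df[og_col].duplicated().any():
        dupes = df.loc[df[og_col].duplicated(), og_col].tolist()
        raise FormatError(f"duplicate orthogroup id(s): {dupes}")

    genes: dict[str, dict[str, list[str]]] = {}
    seen_per_species: dict[str, set[str]] = {sp: set() for sp in species_cols}
    for _, row in df.iterrows():
        og = row[og_col]
        entry: dict[str, list[str]] = {}
        for sp in species_cols:
            cell = row[sp].strip()
            gene_list = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            for g in gene_list:
                if g in seen_per_species[sp]:
                    raise FormatError(f"gene {g} listed twice for species {sp}")
                seen_per_species[sp].add(g)
            entry[sp] = gene_list
        genes[og] = entry
    return OrthogroupTable(genes=genes, species=species_cols)


def write_orthogroups(tbl: OrthogroupTable, path: str | Path) -> None:
    """Write the table back in the ``Orthogroups.tsv`` dialect."""
    rows = []
    for og in sorted(tbl.genes):
        row = {"Orthogroup": og}
        for sp in tbl.species:
            row[sp] = GENE_SEP.join(tbl.genes[og].get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *tbl.species]).to_csv(
        path, sep="\t", index=False
    )


def filter_conserved(
    tbl: OrthogroupTable,
    min_species: int,
    max_mean_copies: float,
    ploidy: Mapping[str, str],
) -> OrthogroupTable:
    """Keep orthogroups present in >= ``min_species`` species whose mean gene
    count across the *diploid* species that contain them is
    <= ``max_mean_copies``.

    Polyploid species are exempt from the copy filter (their orthogroup copy
    numbers scale with ploidy); ``ploidy`` maps every species in the table to
    ``"diploid"`` or ``"polyploid"``.
    """
    if min_species > tbl.n_species:
        raise ConfigurationError("min_species exceeds the species roster size")
    missing = set(tbl.species) - set(ploidy)
    if missing:
        raise ConfigurationError(f"species missing from ploidy map: {sorted(missing)}")

    kept: dict[str, dict[str, list[str]]] = {}
    for og, per_species in tbl.genes.items():
        if tbl.presence_count(og) < min_species:
            continue
        diploid_counts = [
            len(gl)
            for sp, gl in per_species.items()
            if gl and ploidy[sp] == "diploid"
        ]
        if diploid_counts and sum(diploid_counts) / len(diploid_counts) > max_mean_copies:
            continue
        kept[og] = per_species
    return OrthogroupTable(genes=kept, species=list(tbl.species))


def aggregate_tpm(tbl: OrthogroupTable, expr: GeneExpressionTable) -> pd.DataFrame:
    """Sum gene-level TPMs to orthogroup level for one species.

    Returns an orthogroup x sample DataFrame over *all* orthogroups in the
    table; single-copy orthogroups pass their raw TPM through unchanged, and
    orthogroups with no genes in this species give rows of zeros. Genes
    listed for the species but absent from the expression table contribute 0
    and are logged.
    """
    if expr.species not in tbl.species:
        raise ConfigurationError(f"species {expr.species} not in orthogroup table")
    known = set(expr.tpm.index)
    out = pd.DataFrame(
        0.0, index=list(tbl.genes), columns=list(expr.tpm.columns)
    )
    for og, per_species in tbl.genes.items():
        gene_list = per_species.get(expr.species, [])
        present = [g for g in gene_list if g in known]
        absent = set(gene_list) - set(present)
        if absent:
            logger.warning(
                "orthogroup %s: %d gene(s) missing from %s expression table",
                og,
                len(absent),
                expr.species,
            )
        if present:
            out.loc[og] = expr.tpm.loc[present].sum(axis=0)
    return out


def merge_species(
    matrices: Iterable[tuple[str, pd.DataFrame]],
    orthogroup_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Column-concatenate per-species orthogroup matrices.

    Parameters
    ----------
    matrices : iterable of (species id, orthogroup x sample DataFrame)
    orthogroup_ids : optional row universe; defaults to the union of rows.

    Returns the merged matrix (rows canonically sorted lexicographically,
    columns in input order) and a list of (orthogroup, species) pairs that
    were absent in a species' matrix and filled with 0.
    """
    pairs = list(matrices)
    if orthogroup_ids is None:
        universe: set[str] = set()
        for _, m in pairs:
            universe.update(m.index)
        rows = sorted(universe)
    else:
        rows = sorted(orthogroup_ids)

    seen_samples: set[str] = set()
    filled: list[tuple[str, str]] = []
    blocks = []
    for sp, m in pairs:
        clash = seen_samples & set(m.columns)
        if clash:
            raise FormatError(f"duplicate sample id(s) across species: {sorted(clash)}")
        seen_samples.update(m.columns)
        for og in rows:
            if og not in m.index:
                filled.append((og, sp))
        blocks.append(m.reindex(rows, fill_value=0.0))
    if not blocks:
        return pd.DataFrame(index=rows), filled
    merged = pd.concat(blocks, axis=1)
    return merged, filled
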