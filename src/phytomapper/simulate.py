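"""Synthetic cross-species expression catalogs.

Emulates the statistical structure of a large, heterogeneous compendium of
public plant RNA-seq samples: an orthogroup x sample TPM matrix whose signal
is organised by tissue identity (a photosynthesis-analog gene module that is
high in leaf and low elsewhere), by stress (a stress-responsive module that
scales with a per-sample stress severity), and by nuisance factors (plant
family offsets and per-bioproject batch offsets), with the factor
combinations drawn from a heavily skewed (Zipf-like) distribution, as in
real sample catalogs where a few (family, tissue, stress) combinations
dominate.

The generator is deterministic given ``SimulationConfig.seed`` and returns
the planted ground truth (which orthogroups carry tissue / stress signal and
each sample's stress severity) so that downstream lens, Mapper and
enrichment stages can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_metadata",
    "simulate_expression",
    "write_truth",
    "read_truth",
]

HEALTHY_LABEL = "healthy"
LEAF_LABEL = "leaf"

_TISSUE_NAMES = ["leaf", "root", "seed", "flower", "fruit", "stem", "shoot", "callus"]
_STRESS_NAMES = [
    "healthy",
    "drought",
    "heat",
    "cold",
    "salt",
    "light",
    "wounding",
    "fungal",
    "bacterial",
    "nutrient",
]

# fixed per-operation offsets mixed into the seed so that metadata,
# gene-level and sample-level draws come from independent streams
_META_STREAM = 1
_GENE_STREAM = 2
_SAMPLE_STREAM = 3


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic catalog.

    Effects and standard deviations are on the log2 scale; the returned
    matrix is TPM-like (``2**x - 1``, clipped at zero). Exactly one stress
    level is designated healthy and one tissue level is the leaf
    (photosynthetic) reference.
    """

    n_families: int = 16
    n_tissues: int = 8
    n_stresses: int = 10
    n_species_per_family: int = 3
    n_orthogroups: int = 1000
    n_samples: int = 300
    frac_tissue_genes: float = 0.05
    frac_stress_genes: float = 0.05
    tissue_effect: float = 2.0
    stress_effect: float = 2.0
    family_sd: float = 0.25
    batch_sd: float = 0.25
    noise_sd: float = 0.5
    combo_skew: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_families",
            "n_tissues",
            "n_stresses",
            "n_species_per_family",
            "n_orthogroups",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        for name in ("frac_tissue_genes", "frac_stress_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("family_sd", "batch_sd", "noise_sd", "combo_skew"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    # --- factor level names -------------------------------------------------
    @property
    def families(self) -> list[str]:
        return [f"Fam{i + 1:02d}" for i in range(self.n_families)]

    @property
    def tissues(self) -> list[str]:
        extra = [f"tissue{i + 1:02d}" for i in range(len(_TISSUE_NAMES), self.n_tissues)]
        return (_TISSUE_NAMES + extra)[: self.n_tissues]

    @property
    def stresses(self) -> list[str]:
        extra = [f"stress{i + 1:02d}" for i in range(len(_STRESS_NAMES), self.n_stresses)]
        return (_STRESS_NAMES + extra)[: self.n_stresses]

    @property
    def species(self) -> dict[str, list[str]]:
        """family -> species names."""
        return {
            fam: [f"{fam}_sp{k + 1}" for k in range(self.n_species_per_family)]
            for fam in self.families
        }

    @property
    def orthogroup_ids(self) -> list[str]:
        return [f"OG{i:07d}" for i in range(self.n_orthogroups)]


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted signal: which orthogroups carry effects, per-sample severity."""

    tissue_gene_ids: frozenset[str]
    stress_gene_ids: frozenset[str]
    severity: pd.Series  # indexed by sample id; 0 for healthy samples


def _combo_rank_key(cfg: SimulationConfig):
    """Canonical combo ordering: healthy before stressed, leaf before other
    tissues, then factor index — so the Zipf head lands on the combinations
    that dominate real catalogs (healthy leaf/root surveys)."""
    t_idx = {t: i for i, t in enumerate(cfg.tissues)}
    s_idx = {s: i for i, s in enumerate(cfg.stresses)}
    f_idx = {f: i for i, f in enumerate(cfg.families)}

    def key(combo):
        fam, tis, stress = combo
        return (
            stress != HEALTHY_LABEL,
            tis != LEAF_LABEL,
            f_idx[fam],
            t_idx[tis],
            s_idx[stress],
        )

    return key


def simulate_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw a sample metadata table (sample, species, family, tissue, stress,
    bioproject).

    (family, tissue, stress) triples are sampled with Zipf-like weights
    ``rank**-combo_skew`` over the canonically ordered combination list, so
    the observed combination counts are heavily unbalanced. Species are
    uniform within the drawn family; bioprojects split each (species, stress)
    group into at most two batches.
    """
    cols = ["sample", "species", "family", "tissue", "stress", "bioproject"]
    if cfg.n_samples == 0:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng([cfg.seed, _META_STREAM])
    combos = [
        (fam, tis, stress)
        for fam in cfg.families
        for tis in cfg.tissues
        for stress in cfg.stresses
    ]
    combos.sort(key=_combo_rank_key(cfg))
    ranks = np.arange(1, len(combos) + 1, dtype=float)
    weights = ranks ** (-cfg.combo_skew)
    weights /= weights.sum()

    picks = rng.choice(len(combos), size=cfg.n_samples, p=weights)
    species_by_family = cfg.species
    rows = []
    for j, c in enumerate(picks):
        fam, tis, stress = combos[c]
        sp = species_by_family[fam][rng.integers(cfg.n_species_per_family)]
        batch = rng.integers(2)
        rows.append(
            {
                "sample": f"S{j + 1:06d}",
                "species": sp,
                "family": fam,
                "tissue": tis,
                "stress": stress,
                "bioproject": f"PRJ-{sp}-{stress}-{batch}",
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _check_meta(cfg: SimulationConfig, meta: pd.DataFrame) -> None:
    required = {"sample", "species", "family", "tissue", "stress", "bioproject"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigurationError(f"metadata missing columns: {sorted(missing)}")
    if not set(meta["family"]).issubset(cfg.families):
        raise ConfigurationError("metadata families do not match config")
    if not set(meta["tissue"]).issubset(cfg.tissues):
        raise ConfigurationError("metadata tissues do not match config")
    if not set(meta["stress"]).issubset(cfg.stresses):
        raise ConfigurationError("metadata stresses do not match config")


def simulate_expression(
    cfg: SimulationConfig, meta: pd.DataFrame
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the orthogroup x sample TPM matrix plus planted ground truth.

    Log2-scale model for orthogroup i in sample j::

        x_ij = baseline_i
               - tissue_effect * 1[i in tissue genes] * 1[tissue_j != leaf]
               + stress_effect * severity_j * 1[i in stress genes]
               + family_offset[family_j, i]
               + batch_offset[bioproject_j, i]
               + noise_ij

    Tissue (photosynthesis-analog) genes are *down* outside leaf tissue;
    severity is 0 for healthy samples and ~Uniform(0.25, 1.75) otherwise.
    The returned matrix is ``clip(2**x - 1, 0)`` — TPM-like and non-negative.
    Gene-level draws (baselines, planted gene sets, factor offsets) come from
    a stream independent of the sample-level stream, so adding samples does
    not perturb them.
    """
    _check_meta(cfg, meta)
    og_ids = cfg.orthogroup_ids
    n_g = cfg.n_orthogroups
    n_s = len(meta)

    gene_rng = np.random.default_rng([cfg.seed, _GENE_STREAM])
    baseline = gene_rng.uniform(2.0, 8.0, size=n_g)
    n_tissue_genes = int(round(cfg.frac_tissue_genes * n_g))
    n_stress_genes = int(round(cfg.frac_stress_genes * n_g))
    tissue_idx = np.sort(gene_rng.choice(n_g, size=n_tissue_genes, replace=False))
    stress_idx = np.sort(gene_rng.choice(n_g, size=n_stress_genes, replace=False))
    fam_offsets = gene_rng.normal(0.0, 1.0, size=(cfg.n_families, n_g)) * cfg.family_sd
    projects = sorted(meta["bioproject"].unique())
    batch_offsets = gene_rng.normal(0.0, 1.0, size=(len(projects), n_g)) * cfg.batch_sd

    sample_rng = np.random.default_rng([cfg.seed, _SAMPLE_STREAM])
    stressed = (meta["stress"] != HEALTHY_LABEL).to_numpy()
    severity = np.where(stressed, sample_rng.uniform(0.25, 1.75, size=n_s), 0.0)
    noise = sample_rng.normal(0.0, 1.0, size=(n_g, n_s)) * cfg.noise_sd

    x = np.tile(baseline[:, None], (1, n_s))
    nonleaf = (meta["tissue"] != LEAF_LABEL).to_numpy()
    x[np.ix_(tissue_idx, np.flatnonzero(nonleaf))] -= cfg.tissue_effect
    x[stress_idx, :] += cfg.stress_effect * severity[None, :]
    fam_map = {f: i for i, f in enumerate(cfg.families)}
    prj_map = {p: i for i, p in enumerate(projects)}
    x += fam_offsets[[fam_map[f] for f in meta["family"]], :].T
    x += batch_offsets[[prj_map[p] for p in meta["bioproject"]], :].T
    x += noise

    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    matrix = pd.DataFrame(tpm, index=og_ids, columns=list(meta["sample"]))
    truth = SyntheticTruth(
        tissue_gene_ids=frozenset(og_ids[i] for i in tissue_idx),
        stress_gene_ids=frozenset(og_ids[i] for i in stress_idx),
        severity=pd.Series(severity, index=list(meta["sample"]), name="severity"),
    )
    return matrix, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "tissue_gene_ids": sorted(truth.tissue_gene_ids),
        "stress_gene_ids": sorted(truth.stress_gene_ids),
        "severity": {k: float(v) for k, v in truth.severity.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    sev = pd.Series(payload["severity"], name="severity", dtype=float)
    return SyntheticTruth(
        tissue_gene_ids=frozenset(payload["tissue_gene_ids"]),
        stress_gene_ids=frozenset(payload["stress_gene_ids"]),
        severity=sev,
    )
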