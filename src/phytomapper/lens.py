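"""Residual-norm lens functions over expression samples.

A lens maps each sample to a single non-negative number used to build the
Mapper cover. Both lenses here follow the disease-state construction of
Nicolau and colleagues: fit an affine subspace (mean + truncated SVD basis)
to a reference subset of samples — leaf samples for the *tissue* lens,
healthy samples for the *stress* lens — then score every sample by the
Euclidean norm of its residual after projection onto that subspace. Samples
resembling the idealized reference expression get small lens values; samples
far from it (non-photosynthetic tissues, severely stressed samples) get
large ones.

Expression is transformed to log2(TPM+1) by default before fitting and
projecting; z-score and identity transforms are available.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .simulate import HEALTHY_LABEL, LEAF_LABEL

__all__ = [
    "LensModel",
    "transform_expression",
    "select_reference",
    "fit_reference_model",
    "residual_lens",
]

_SV_TOL = 1e-10  # relative singular-value cutoff for numerically zero directions


def transform_expression(
    X: pd.DataFrame,
    method: str = "log2",
    center: pd.Series | None = None,
    scale: pd.Series | None = None,
) -> pd.DataFrame:
    """Transform a TPM matrix: ``log2`` -> log2(X+1); ``zscore`` -> per-row
    standardisation of log2(X+1) (stats from ``center``/``scale`` if given);
    ``none`` -> identity."""
    if method == "none":
        return X
    if method == "log2":
        return np.log2(X + 1.0)
    if method == "zscore":
        L = np.log2(X + 1.0)
        mu = L.mean(axis=1) if center is None else center
        sd = L.std(axis=1, ddof=0) if scale is None else scale
        sd = sd.replace(0.0, 1.0)
        return L.sub(mu, axis=0).div(sd, axis=0)
    raise ConfigurationError(f"unknown expression transform: {method!r}")


@dataclasses.dataclass
class LensModel:
    """Affine subspace fit to reference samples.

    ``mean`` and the orthonormal ``basis`` (features x rank) live on the
    transformed expression scale recorded in ``transform``.
    """

    mean: pd.Series
    basis: np.ndarray
    rank: int
    transform: str
    center: pd.Series | None = None  # z-score stats, when transform == "zscore"
    scale: pd.Series | None = None

    @property
    def feature_ids(self) -> pd.Index:
        return self.mean.index


def select_reference(
    meta: pd.DataFrame,
    lens_kind: str,
    healthy_label: str = HEALTHY_LABEL,
    leaf_label: str = LEAF_LABEL,
) -> set[str]:
    """Reference samples: healthy samples for the stress lens, leaf samples
    for the tissue lens."""
    for col in ("tissue", "stress"):
        if col not in meta.columns:
            raise ConfigurationError(f"metadata lacks a {col!r} column")
    if lens_kind == "stress":
        mask = meta["stress"] == healthy_label
    elif lens_kind == "tissue":
        mask = meta["tissue"] == leaf_label
    else:
        raise ConfigurationError(f"unknown lens kind: {lens_kind!r}")
    ids = set(meta.loc[mask, "sample"])
    if not ids:
        raise ConfigurationError(f"empty reference set for the {lens_kind} lens")
    return ids


def _parse_rank_rule(rank_rule: str) -> tuple[str, float]:
    try:
        kind, _, value = rank_rule.partition(":")
        if kind == "ev":
            tau = float(value)
            if not 0.0 < tau <= 1.0:
                raise ValueError
            return "ev", tau
        if kind == "fixed":
            r = int(value)
            if r < 0:
                raise ValueError
            return "fixed", r
    except ValueError:
        pass
    raise ConfigurationError(f"bad rank rule {rank_rule!r}; use 'ev:0.95' or 'fixed:k'")


def fit_reference_model(
    X: pd.DataFrame,
    ref_ids: Iterable[str],
    rank_rule: str = "ev:0.95",
    transform: str = "log2",
) -> LensModel:
    """Fit the reference affine subspace by truncated SVD.

    The mean of the transformed reference columns is the model origin; the
    basis holds the leading left singular vectors of the mean-centered
    reference matrix, truncated to the smallest rank reaching the requested
    cumulative explained variance (``"ev:0.95"``) or to a fixed rank
    (``"fixed:k"``). Rank never exceeds ``n_ref - 1`` and numerically zero
    singular directions are dropped, so identical reference columns give a
    rank-0 (pure mean) model.
    """
    ref = sorted(set(ref_ids))
    if len(ref) < 2:
        raise ConfigurationError("need at least 2 reference samples to fit a lens model")
    missing = set(ref) - set(X.columns)
    if missing:
        raise ConfigurationError(f"reference samples absent from matrix: {sorted(missing)}")

    center = scale = None
    if transform == "zscore":
        L = np.log2(X + 1.0)
        center = L.mean(axis=1)
        scale = L.std(axis=1, ddof=0).replace(0.0, 1.0)
    T = transform_expression(X[ref], transform, center=center, scale=scale)
    mu = T.mean(axis=1)
    C = T.to_numpy() - mu.to_numpy()[:, None]
    U, s, _ = np.linalg.svd(C, full_matrices=False)

    nonzero = s > _SV_TOL * (s[0] if s.size and s[0] > 0 else 1.0)
    r_max = min(int(nonzero.sum()), len(ref) - 1)
    kind, value = _parse_rank_rule(rank_rule)
    if kind == "fixed":
        r = min(int(value), r_max)
    else:
        if r_max == 0:
            r = 0
        else:
            var = s[:r_max] ** 2
            cum = np.cumsum(var) / var.sum()
            r = int(np.searchsorted(cum, value - 1e-12) + 1)
    basis = U[:, :r].copy()
    return LensModel(
        mean=mu, basis=basis, rank=r, transform=transform, center=center, scale=scale
    )


def residual_lens(X: pd.DataFrame, model: LensModel) -> pd.Series:
    """Lens values: per-sample residual norms off the reference subspace.

    ``f(x) = || (x - mu) - B B^T (x - mu) ||_2`` on the model's transformed
    scale. Samples in the reference span get (numerically) zero.
    """
    if not X.index.equals(model.feature_ids):
        if set(X.index) != set(model.feature_ids):
            raise ConfigurationError("matrix rows do not match the lens model features")
        X = X.loc[model.feature_ids]
    T = transform_expression(X, model.transform, center=model.center, scale=model.scale)
    D = T.to_numpy() - model.mean.to_numpy()[:, None]
    if model.rank > 0:
        D = D - model.basis @ (model.basis.T @ D)
    f = np.linalg.norm(D, axis=0)
    return pd.Series(f, index=X.columns, name="lens_value")
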