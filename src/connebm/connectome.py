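"""Weighted connectome container and weight/length conversions.

A connectome is an undirected, weighted graph over a fixed parcellation of
brain regions, stored as a symmetric, zero-diagonal adjacency matrix whose
entries are anatomical connection densities normalized to [0, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConnectomeError

__all__ = [
    "WeightedConnectome",
    "normalize_weights",
    "weights_to_lengths",
    "read_connectome_csv",
    "write_connectome_csv",
]

_SYM_TOL = 1e-9


@dataclass
class WeightedConnectome:
    """Node labels plus a symmetric nonnegative adjacency matrix."""

    node_labels: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise InvalidConnectomeError("adjacency matrix must be square")
        if len(self.node_labels) != self.weights.shape[0]:
            raise InvalidConnectomeError(
                f"{len(self.node_labels)} labels for {self.weights.shape[0]} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def validate(self, *, normalized: bool = False) -> None:
        """Raise unless the matrix is symmetric, nonnegative and zero-diagonal.

        With ``normalized=True`` additionally require all weights <= 1.
        """
        W = self.weights
        if not np.all(np.isfinite(W)):
            raise InvalidConnectomeError("non-finite weights")
        if np.any(W < 0):
            raise InvalidConnectomeError("negative weights")
        if not np.allclose(W, W.T, atol=_SYM_TOL, rtol=0):
            raise InvalidConnectomeError("matrix not symmetric within 1e-9")
        if np.any(np.diag(W) != 0):
            raise InvalidConnectomeError("diagonal must be exactly zero")
        if normalized and np.any(W > 1):
            raise InvalidConnectomeError("weights exceed 1 after normalization")

    def copy(self) -> "WeightedConnectome":
        return WeightedConnectome(list(self.node_labels), self.weights.copy())


def normalize_weights(c: WeightedConnectome) -> WeightedConnectome:
    """Symmetrize, zero the diagonal, and rescale weights to [0, 1] by the max.

    An all-zero matrix is returned unchanged with a warning (no connections
    to scale).
    """
    W = np.asarray(c.weights, dtype=float)
    if np.any(W < 0):
        raise InvalidConnectomeError("negative weights cannot be normalized")
    if not np.allclose(W, W.T, atol=_SYM_TOL, rtol=0):
        raise InvalidConnectomeError("matrix asymmetric beyond tolerance 1e-9")
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    wmax = W.max(initial=0.0)
    if wmax > 0:
        W = W / wmax
    else:
        warnings.warn("all-zero connectome: normalization is a no-op", stacklevel=2)
    out = WeightedConnectome(list(c.node_labels), W)
    out.validate(normalized=True)
    return out


def weights_to_lengths(c: WeightedConnectome) -> np.ndarray:
    """Convert connection weights to lengths: L_ij = 1/W_ij, +inf if unconnected.

    Stronger connections are shorter; the diagonal is 0. Input is expected to
    be normalized to [0, 1] so lengths are >= 1.
    """
    W = c.weights
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def read_connectome_csv(path: str | Path) -> WeightedConnectome:
    """Read a square matrix CSV with node labels as header row and first column."""
    df = pd.read_csv(path, index_col=0, comment="#")
    labels = [str(x) for x in df.columns]
    if [str(x) for x in df.index] != labels:
        raise InvalidConnectomeError(f"{path}: row labels do not match column labels")
    return WeightedConnectome(labels, df.to_numpy(dtype=float))


def write_connectome_csv(c: WeightedConnectome, path: str | Path) -> None:
    df = pd.DataFrame(c.weights, index=c.node_labels, columns=c.node_labels)
    df.to_csv(path)
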