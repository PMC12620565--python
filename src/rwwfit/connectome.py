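"""Structural connectomes: validation, thresholding, normalization, and the
coupling Laplacian used by the network dynamics.

A structural connectome (SC) is a symmetric nonnegative N x N matrix of
anatomical connection strengths (typically streamline counts) between
parcellated brain regions, with a zero diagonal. Before entering the dynamics
it is log-transformed (log(1+w), preserving zeros/sparsity) and divided by its
maximum entry, mapping weights into [0, 1]. Long-range coupling acts through
the graph Laplacian L = D - C, with D the diagonal matrix of row sums of C, so
that a spatially uniform excitatory state receives exactly zero network input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StructuralConnectome",
    "CouplingLaplacian",
    "threshold_edges",
    "normalize_sc",
    "build_laplacian",
    "read_connectome",
    "write_connectome",
]

_SYM_ATOL = 1e-8


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative weighted graph over N parcels.

    Parameters
    ----------
    weights
        N x N matrix of nonnegative connection strengths. Must be symmetric
        with an exactly zero diagonal.
    labels
        Optional region names, length N.
    """

    weights: np.ndarray
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValueError("a connectome needs at least 2 nodes")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(f"non-finite weight at entry ({i}, {j})")
        asym = np.abs(w - w.T)
        if asym.max() > _SYM_ATOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"weights not symmetric: entry ({i}, {j})={w[i, j]:g} vs "
                f"({j}, {i})={w[j, i]:g}"
            )
        if np.any(np.diag(w) != 0):
            i = int(np.nonzero(np.diag(w))[0][0])
            raise ValueError(f"diagonal must be exactly zero; node {i} has {w[i, i]:g}")
        if w.min() < 0:
            i, j = np.unravel_index(np.argmin(w), w.shape)
            raise ValueError(f"negative weight {w[i, j]:g} at entry ({i}, {j})")
        # exact symmetry from here on
        self.weights = (w + w.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if self.labels is not None and len(self.labels) != w.shape[0]:
            raise ValueError(
                f"got {len(self.labels)} labels for {w.shape[0]} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class CouplingLaplacian:
    """Graph Laplacian L = D - C of a normalized connectome.

    ``matrix`` has zero row sums (within numerical tolerance) and non-positive
    off-diagonal entries; ``degree`` holds the row sums of the adjacency C.
    """

    matrix: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.matrix, dtype=float)
        row_sums = L.sum(axis=1)
        if np.abs(row_sums).max() > 1e-10:
            raise ValueError(
                f"Laplacian row sums must vanish; worst residual {np.abs(row_sums).max():g}"
            )
        off = L - np.diag(np.diag(L))
        if off.max() > _SYM_ATOL:
            raise ValueError("Laplacian off-diagonal entries must be <= 0")
        self.matrix = L
        self.degree = np.asarray(self.degree, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def threshold_edges(sc: StructuralConnectome, min_streamlines: int) -> StructuralConnectome:
    """Zero out edges supported by fewer than ``min_streamlines`` streamlines.

    Entries strictly below the threshold are removed; symmetry and the zero
    diagonal are preserved. ``min_streamlines=0`` is a no-op.
    """
    if min_streamlines < 0:
        raise ValueError(f"min_streamlines must be >= 0, got {min_streamlines}")
    w = sc.weights.copy()
    w[w < min_streamlines] = 0.0
    meta = dict(sc.meta)
    meta["threshold"] = int(min_streamlines)
    return StructuralConnectome(w, labels=sc.labels, meta=meta)


def normalize_sc(sc: StructuralConnectome) -> StructuralConnectome:
    """Log-transform and unit-normalize: w -> log(1+w) / max(log(1+w)).

    Zeros stay exactly zero (log1p(0) = 0) and the output lies in [0, 1] with
    the rank order of nonzero weights preserved. Raises on an all-zero matrix
    (normalization undefined).
    """
    w = np.log1p(sc.weights)
    mx = w.max()
    if mx <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    meta = dict(sc.meta)
    meta["transform"] = "log1p"
    meta["normalization_max"] = float(mx)
    return StructuralConnectome(w / mx, labels=sc.labels, meta=meta)


def build_laplacian(sc: StructuralConnectome) -> CouplingLaplacian:
    """Assemble L = D - C from a (normalized) connectome.

    D is the diagonal matrix of row sums (node degree) of the adjacency C.
    Row sums of L vanish identically, so a uniform state receives zero input.
    """
    C = sc.weights
    deg = C.sum(axis=1)
    L = np.diag(deg) - C
    return CouplingLaplacian(matrix=L, degree=deg)


def laplacian_from_adjacency(C: np.ndarray) -> np.ndarray:
    """L = D - C for a raw adjacency array (no validation; used in hot loops)."""
    C = np.asarray(C, dtype=float)
    deg = C.sum(axis=-1)
    L = -C.copy()
    idx = np.arange(C.shape[-1])
    L[..., idx, idx] += deg
    return L


# ---------------------------------------------------------------------------
# text I/O: whitespace- or comma-delimited square matrices, optional header row


def _detect_delimiter(line: str) -> str | None:
    return "," if "," in line else None


def read_connectome(path: str | Path, validate: bool = True) -> StructuralConnectome:
    """Read an SC matrix from delimited text.

    Accepts whitespace- or comma-delimited numeric rows and an optional leading
    header row of region labels. Validation failures report the offending
    entry pair.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])
    first = lines[0].split(delim)
    labels: list[str] | None = None
    try:
        [float(tok) for tok in first]
        data_lines = lines
    except ValueError:
        labels = [tok.strip() for tok in first]
        data_lines = lines[1:]
    rows = []
    for ln_no, ln in enumerate(data_lines):
        toks = ln.split(delim)
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln_no + 1}: non-numeric token ({exc})")
    w = np.array(rows, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, expected square")
    if not validate:
        sc = StructuralConnectome.__new__(StructuralConnectome)
        sc.weights, sc.labels, sc.meta = w, labels, {}
        return sc
    return StructuralConnectome(w, labels=labels)


def write_connectome(
    path: str | Path,
    sc: StructuralConnectome,
    delimiter: str = "\t",
    sidecar: bool = True,
) -> None:
    """Write the matrix as delimited text (header row iff labels are present).

    Normalization provenance (threshold, transform, max used) is recorded in a
    sidecar JSON next to the matrix file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if sc.labels is not None:
            fh.write(delimiter.join(sc.labels) + "\n")
        for row in sc.weights:
            fh.write(delimiter.join(f"{v:.10g}" for v in row) + "\n")
    if sidecar:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump({"n_nodes": sc.n_nodes, **sc.meta}, fh, indent=2)
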