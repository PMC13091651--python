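"""Nucleotide contact graphs and the normalized graph-convolutional encoder.

A miRNA is encoded by running p symmetric-normalized GCN layers over its
secondary-structure contact graph (self-loops added) and mean-pooling the
final node states into one vector.  Initial node features are either
one-hot nucleotide identities (4 columns) or an externally supplied
per-nucleotide embedding matrix standing in for an RNA language model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import RnaSequence

__all__ = [
    "ContactMap",
    "NodeFeatures",
    "GcnStack",
    "dotbracket_to_contact",
    "read_dotbracket_tsv",
    "load_contact_matrix",
    "save_contact_matrix",
    "onehot_features",
    "normalized_adjacency",
    "gcn_layer",
    "encode_mirna",
]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class ContactMap:
    """Symmetric binary nucleotide-nucleotide adjacency with zero diagonal."""

    rna_id: str
    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"contact map for {self.rna_id!r} must be square")
        if not np.array_equal(A, A.T):
            raise ValueError(f"contact map for {self.rna_id!r} is not symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError(f"contact map for {self.rna_id!r} has nonzero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError(f"contact map for {self.rna_id!r} has non-binary entries")
        self.A = A

    @property
    def L(self) -> int:
        return self.A.shape[0]


def dotbracket_to_contact(structure: str, rna_id: str = "") -> ContactMap:
    """Parse a dot-bracket string into a contact map.

    Only one bracket family ``()`` is supported (no pseudoknots).
    Unbalanced strings raise with the offending position.
    """
    L = len(structure)
    A = np.zeros((L, L))
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            A[i, j] = A[j, i] = 1.0
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return ContactMap(rna_id=rna_id, A=A)


def read_dotbracket_tsv(path: str | Path) -> dict[str, ContactMap]:
    """Read a 2-column TSV of (id, dot-bracket string) into contact maps."""
    out: dict[str, ContactMap] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            rna_id, structure = parts
            if rna_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {rna_id!r}")
            try:
                out[rna_id] = dotbracket_to_contact(structure, rna_id=rna_id)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not out:
        raise ValueError(f"no structures found in {path}")
    return out


def load_contact_matrix(path: str | Path, threshold: float = 0.5,
                        rna_id: str = "") -> ContactMap:
    """Load a whitespace-delimited square matrix and binarize it.

    Entries >= ``threshold`` become 1; the result is symmetrized by
    elementwise max with its transpose, and the diagonal is zeroed.
    """
    M = np.loadtxt(path, ndmin=2)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"contact matrix in {path} is not square: {M.shape}")
    B = (M >= threshold).astype(np.float64)
    B = np.maximum(B, B.T)
    np.fill_diagonal(B, 0.0)
    return ContactMap(rna_id=rna_id or Path(path).stem, A=B)


def save_contact_matrix(cmap: ContactMap, path: str | Path) -> None:
    np.savetxt(path, cmap.A, fmt="%d")


@dataclass
class NodeFeatures:
    """Initial per-nucleotide feature matrix (L x d0)."""

    rna_id: str
    H0: np.ndarray
    source: str = "onehot"  # "onehot" | "external"

    def __post_init__(self):
        self.H0 = np.asarray(self.H0, dtype=np.float64)
        if self.H0.ndim != 2:
            raise ValueError("H0 must be a 2-D matrix")
        if self.source not in ("onehot", "external"):
            raise ValueError(f"unknown feature source {self.source!r}")
        if self.source == "onehot":
            if self.H0.shape[1] != 4 or not np.all(self.H0.sum(axis=1) == 1):
                raise ValueError("one-hot features must be L x 4 with unit rows")


def onehot_features(seq: RnaSequence) -> NodeFeatures:
    """One-hot nucleotide identity features (bundled fallback encoder)."""
    H0 = np.zeros((seq.length, 4))
    for i, ch in enumerate(seq.seq):
        H0[i, _NT_INDEX[ch]] = 1.0
    return NodeFeatures(rna_id=seq.id, H0=H0, source="onehot")


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^-1/2 (A + I) D^-1/2 with self-loops.

    Self-loops guarantee every degree is >= 1, so no division by zero.
    """
    A = np.asarray(A, dtype=np.float64)
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "identity": lambda x: x,
}


@dataclass
class GcnStack:
    """Stack of p GCN weight matrices with a shared activation tag."""

    weights: list[np.ndarray]
    activation: str = "relu"

    def __post_init__(self):
        if not self.weights:
            raise ValueError("GcnStack needs at least one layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.weights = [np.asarray(W, dtype=np.float64) for W in self.weights]
        for Wa, Wb in zip(self.weights, self.weights[1:]):
            if Wa.shape[1] != Wb.shape[0]:
                raise ValueError(
                    f"layer widths do not chain: {Wa.shape} -> {Wb.shape}"
                )

    @classmethod
    def init(cls, d0: int, hidden: int, layers: int, seed: int = 0,
             activation: str = "relu") -> "GcnStack":
        rng = np.random.default_rng(seed)
        widths = [d0] + [hidden] * layers
        weights = []
        for a, b in zip(widths[:-1], widths[1:]):
            lim = np.sqrt(6.0 / (a + b))
            weights.append(rng.uniform(-lim, lim, (a, b)))
        return cls(weights=weights, activation=activation)


def gcn_layer(H: np.ndarray, cmap: ContactMap, W: np.ndarray,
              activation: str = "relu") -> np.ndarray:
    """One normalized propagation step: sigma(D^-1/2 (A+I) D^-1/2 H W)."""
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if H.shape[0] != cmap.L:
        raise ValueError(f"feature rows {H.shape[0]} != contact-map size {cmap.L}")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"feature width {H.shape[1]} != weight rows {W.shape[0]}")
    act = _ACTIVATIONS[activation]
    return act(normalized_adjacency(cmap.A) @ H @ W)


def encode_mirna(features: NodeFeatures, cmap: ContactMap,
                 stack: GcnStack) -> np.ndarray:
    """Run the GCN stack and mean-pool node states into one vector."""
    if features.H0.shape[0] != cmap.L:
        raise ValueError(
            f"features for {features.rna_id!r} have {features.H0.shape[0]} rows "
            f"but contact map has {cmap.L}"
        )
    H = features.H0
    for W in stack.weights:
        H = gcn_layer(H, cmap, W, stack.activation)
    return H.mean(axis=0)
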