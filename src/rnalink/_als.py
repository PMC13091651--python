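"""Logit-scale alternating least squares — the recoverability oracle.

A deliberately simple rank-r factorization fit by alternating ridge
regressions on logit-scale targets: observed training positives get
target +t with full weight, every other (non-excluded) cell acts as a
weak negative with target -t and weight ``w0`` (the implicit-feedback
trick that makes very sparse matrices identifiable).  Held-out cells are
excluded from the fit entirely.

The oracle exists to certify that a planted benchmark is learnable
before the full model is blamed for failing on it; it shares no code
with the model path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["als_logit_factorize", "als_scores"]


def als_logit_factorize(n_rows: int, n_cols: int,
                        pos_pairs: list[tuple[int, int]],
                        exclude: list[tuple[int, int]] = (),
                        rank: int = 4, iters: int = 40, reg: float = 2.0,
                        target: float = 4.0, w0: float = 0.3,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fit U (n_rows x r), V (n_cols x r) so U V^T approximates the
    +/-target logit pattern of the training matrix."""
    rng = np.random.default_rng(seed)
    U = 0.1 * rng.standard_normal((n_rows, rank))
    V = 0.1 * rng.standard_normal((n_cols, rank))

    W = np.full((n_rows, n_cols), w0)
    T = np.full((n_rows, n_cols), -target)
    for i, j in pos_pairs:
        W[i, j] = 1.0
        T[i, j] = target
    for i, j in exclude:
        W[i, j] = 0.0

    eye = reg * np.eye(rank)
    for _ in range(iters):
        for i in range(n_rows):
            w = W[i]
            A = (V * w[:, None]).T @ V + eye
            b = (V * (w * T[i])[:, None]).sum(axis=0)
            U[i] = np.linalg.solve(A, b)
        for j in range(n_cols):
            w = W[:, j]
            A = (U * w[:, None]).T @ U + eye
            b = (U * (w * T[:, j])[:, None]).sum(axis=0)
            V[j] = np.linalg.solve(A, b)
    return U, V


def als_scores(U: np.ndarray, V: np.ndarray,
               pairs: list[tuple[int, int]]) -> np.ndarray:
    return np.array([U[i] @ V[j] for i, j in pairs])
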