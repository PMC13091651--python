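"""Synthetic inputs: random RNA sequences, hairpin contact maps, and
planted low-rank bipartite interaction graphs.

The planted generator draws rank-r latent factors per entity and samples
edges with probability sigmoid(a * u_i . v_j + b + noise), with the
intercept b calibrated by bisection so the expected density matches the
requested value.  The true factors are returned alongside the table so
recovery tests can verify the benchmark is learnable at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig, derive_seed
from .io import InteractionTable, RnaSequence, write_fasta, write_interactions
from .mirna import ContactMap, save_contact_matrix

__all__ = [
    "PlantedGraphSpec",
    "gen_sequences",
    "gen_coupled_sequences",
    "gen_external_embeddings",
    "gen_hairpin_contact",
    "gen_planted_interactions",
    "make_fixture_bundle",
    "Benchmark",
    "make_benchmark",
]

_LETTERS = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Parameters of the planted low-rank interaction structure."""

    N: int
    M: int
    latent_dim: int = 4
    density: float = 0.05
    scale: float = 3.0      # a: slope on the latent inner product
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be positive")


def gen_sequences(n: int, length_range: tuple[int, int], rna_type: str,
                  seed: int = 0, prefix: str | None = None) -> list[RnaSequence]:
    """Uniform i.i.d. A/C/G/U sequences with lengths uniform in range."""
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    if prefix is None:
        prefix = "lnc" if rna_type == "lncRNA" else "mi"
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(_LETTERS[rng.integers(0, 4, size=L)])
        out.append(RnaSequence(id=f"{prefix}{i:04d}", seq=seq, rna_type=rna_type))
    return out


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def gen_coupled_sequences(factors: np.ndarray, length_range: tuple[int, int],
                          rna_type: str, seed: int = 0,
                          coupling: float = 1.0,
                          prefix: str | None = None) -> list[RnaSequence]:
    """Sequences whose dinucleotide statistics encode the latent factors.

    Each entity's sequence is a first-order Markov chain whose 4x4
    transition-logit matrix is a fixed random linear map of the entity's
    planted factor, scaled by ``coupling``.  This couples sequence content
    to the planted interaction structure so that sequence encoders carry
    genuine signal about interactions, mirroring real benchmarks where
    sequence features are informative.  The letter-map seed is shared
    across entities of a type so the code (not the noise) is common.
    """
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    factors = np.asarray(factors, dtype=np.float64)
    if prefix is None:
        prefix = "lnc" if rna_type == "lncRNA" else "mi"
    r = factors.shape[1]
    code_rng = np.random.default_rng(derive_seed(seed, "letter-code"))
    C = coupling * code_rng.standard_normal((16, r))
    rng = np.random.default_rng(seed)
    out = []
    for i, w in enumerate(factors):
        T = _softmax_rows((C @ w).reshape(4, 4))
        L = int(rng.integers(lo, hi + 1))
        states = np.empty(L, dtype=np.intp)
        states[0] = rng.integers(0, 4)
        for t in range(1, L):
            states[t] = rng.choice(4, p=T[states[t - 1]])
        seq = "".join(_LETTERS[states])
        out.append(RnaSequence(id=f"{prefix}{i:04d}", seq=seq, rna_type=rna_type))
    return out


def gen_external_embeddings(factors: np.ndarray,
                            sequences: list[RnaSequence],
                            noise_sd: float = 0.5,
                            seed: int = 0) -> dict[str, np.ndarray]:
    """Per-nucleotide embedding matrices standing in for an RNA language model.

    Row t of an entity's L x (4 + r) matrix is the one-hot nucleotide
    identity concatenated with a per-position noisy copy of the entity's
    latent factor.  A pretrained language model likewise embeds both local
    identity and molecule-level functional context; the one-hot ablation
    removes exactly the functional part.
    """
    factors = np.asarray(factors, dtype=np.float64)
    if len(sequences) != factors.shape[0]:
        raise ValueError("one factor row per sequence required")
    rng = np.random.default_rng(seed)
    nt_index = {"A": 0, "C": 1, "G": 2, "U": 3}
    out: dict[str, np.ndarray] = {}
    for rec, w in zip(sequences, factors):
        L = rec.length
        onehot = np.zeros((L, 4))
        for t, ch in enumerate(rec.seq):
            onehot[t, nt_index[ch]] = 1.0
        context = w[None, :] + noise_sd * rng.standard_normal((L, w.size))
        out[rec.id] = np.hstack([onehot, context])
    return out


def gen_hairpin_contact(L: int, stem: int, rna_id: str = "") -> ContactMap:
    """Single-stem hairpin: pairs (i, L-1-i) for i in 0..stem-1."""
    if stem < 0 or 2 * stem >= L:
        raise ValueError(f"stem {stem} infeasible for length {L} (need 2*stem < L)")
    A = np.zeros((L, L))
    for i in range(stem):
        A[i, L - 1 - i] = A[L - 1 - i, i] = 1.0
    return ContactMap(rna_id=rna_id, A=A)


def _calibrate_intercept(logits: np.ndarray, density: float,
                         tol: float = 1e-4, max_iter: int = 200) -> float:
    """Bisection on b so mean(sigmoid(logits + b)) == density."""
    lo, hi = -60.0, 60.0

    def mean_p(b: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(logits + b)))).mean())

    if not mean_p(lo) <= density <= mean_p(hi):
        raise RuntimeError("density calibration failed: target out of range")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < density:
            lo = mid
        else:
            hi = mid
        if abs(mean_p(mid) - density) < tol:
            return mid
    raise RuntimeError(f"density calibration did not converge within {max_iter} steps")


def gen_planted_interactions(spec: PlantedGraphSpec,
                             lnc_ids: list[str] | None = None,
                             mi_ids: list[str] | None = None
                             ) -> tuple[InteractionTable, dict]:
    """Sample a planted low-rank interaction table plus its true factors."""
    rng = np.random.default_rng(spec.seed)
    U = rng.standard_normal((spec.N, spec.latent_dim))
    V = rng.standard_normal((spec.M, spec.latent_dim))
    logits = spec.scale * (U @ V.T)
    if spec.noise_sd > 0:
        logits = logits + spec.noise_sd * rng.standard_normal(logits.shape)
    b = _calibrate_intercept(logits, spec.density)
    P = 1.0 / (1.0 + np.exp(-(logits + b)))
    A = rng.random((spec.N, spec.M)) < P

    if lnc_ids is None:
        lnc_ids = [f"lnc{i:04d}" for i in range(spec.N)]
    if mi_ids is None:
        mi_ids = [f"mi{i:04d}" for i in range(spec.M)]
    pairs = [(lnc_ids[i], mi_ids[j], 1)
             for i, j in zip(*np.nonzero(A))]
    table = InteractionTable.from_pairs(pairs, lnc_ids=lnc_ids, mi_ids=mi_ids)
    factors = {"U": U, "V": V, "intercept": b, "prob": P, "adjacency": A}
    return table, factors


_SCALES = {"tiny": (8, 12, 0.18), "small": (60, 80, 0.05)}


@dataclass
class Benchmark:
    """In-memory planted benchmark: everything the trainer consumes."""

    table: InteractionTable
    lnc_seqs: dict
    mi_seqs: dict
    contacts: dict
    external_mi: dict | None
    factors: dict


def make_benchmark(scale: str, seed: int, couple: bool = True) -> Benchmark:
    """Build the planted benchmark in memory (same layout as the bundle).

    ``couple=True`` ties sequence content and external embeddings to the
    planted factors so sequence encoders carry interaction signal.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}")
    N, M, density = _SCALES[scale]
    gspec = PlantedGraphSpec(N=N, M=M, latent_dim=4, density=density,
                             seed=derive_seed(seed, "planted"))
    lnc_ids = [f"lnc{i:04d}" for i in range(N)]
    mi_ids = [f"mi{i:04d}" for i in range(M)]
    table, factors = gen_planted_interactions(gspec, lnc_ids=lnc_ids,
                                              mi_ids=mi_ids)
    if couple:
        lnc = gen_coupled_sequences(factors["U"], (200, 400), "lncRNA",
                                    seed=derive_seed(seed, "lnc-seqs"),
                                    coupling=1.0)
        mi = gen_coupled_sequences(factors["V"], (20, 25), "miRNA",
                                   seed=derive_seed(seed, "mi-seqs"),
                                   coupling=1.5)
        external = gen_external_embeddings(factors["V"], mi, noise_sd=0.5,
                                           seed=derive_seed(seed, "mi-embed"))
    else:
        lnc = gen_sequences(N, (200, 400), "lncRNA",
                            seed=derive_seed(seed, "lnc-seqs"))
        mi = gen_sequences(M, (20, 25), "miRNA",
                           seed=derive_seed(seed, "mi-seqs"))
        external = None
    stem_rng = np.random.default_rng(derive_seed(seed, "stems"))
    contacts = {r.id: gen_hairpin_contact(
        r.length, int(stem_rng.integers(3, r.length // 2)), r.id) for r in mi}
    return Benchmark(table=table,
                     lnc_seqs={r.id: r for r in lnc},
                     mi_seqs={r.id: r for r in mi},
                     contacts=contacts, external_mi=external, factors=factors)


def make_fixture_bundle(scale: str, seed: int, out_dir: str | Path,
                        config: RunConfig | None = None,
                        couple: bool = False) -> dict:
    """Write a self-describing, runnable end-to-end example directory.

    Contents: lncRNA/miRNA FASTA, one contact-map file per miRNA,
    interaction TSV, a config YAML, and a JSON manifest.  Byte-identical
    under identical (scale, seed, couple).

    With ``couple=True`` sequences are generated from the planted latent
    factors (see :func:`gen_coupled_sequences`) and an ``embeddings/``
    directory of per-nucleotide matrices for miRNAs is added, so sequence
    features carry real signal about the planted interactions.  By default
    sequences and interactions are independent.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}")
    N, M, density = _SCALES[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "contacts").mkdir(exist_ok=True)

    gspec = PlantedGraphSpec(N=N, M=M, latent_dim=4, density=density,
                             seed=derive_seed(seed, "planted"))
    lnc_ids = [f"lnc{i:04d}" for i in range(N)]
    mi_ids = [f"mi{i:04d}" for i in range(M)]
    table, factors = gen_planted_interactions(gspec, lnc_ids=lnc_ids,
                                              mi_ids=mi_ids)
    write_interactions(table, out / "interactions.tsv")

    if couple:
        lnc = gen_coupled_sequences(factors["U"], (200, 400), "lncRNA",
                                    seed=derive_seed(seed, "lnc-seqs"),
                                    coupling=1.0)
        mi = gen_coupled_sequences(factors["V"], (20, 25), "miRNA",
                                   seed=derive_seed(seed, "mi-seqs"),
                                   coupling=1.5)
        emb = gen_external_embeddings(factors["V"], mi, noise_sd=0.5,
                                      seed=derive_seed(seed, "mi-embed"))
        (out / "embeddings").mkdir(exist_ok=True)
        for mid, H0 in emb.items():
            np.savetxt(out / "embeddings" / f"{mid}.txt", H0, fmt="%.6f")
    else:
        lnc = gen_sequences(N, (200, 400), "lncRNA",
                            seed=derive_seed(seed, "lnc-seqs"))
        mi = gen_sequences(M, (20, 25), "miRNA",
                           seed=derive_seed(seed, "mi-seqs"))
    write_fasta(lnc, out / "lnc.fasta")
    write_fasta(mi, out / "mi.fasta")

    stem_rng = np.random.default_rng(derive_seed(seed, "stems"))
    for rec in mi:
        stem = int(stem_rng.integers(3, rec.length // 2))
        cmap = gen_hairpin_contact(rec.length, stem, rna_id=rec.id)
        save_contact_matrix(cmap, out / "contacts" / f"{rec.id}.txt")

    cfg = config if config is not None else RunConfig(seed=seed)
    cfg.to_yaml(out / "config.yaml")

    files = ["lnc.fasta", "mi.fasta", "interactions.tsv", "config.yaml",
             "contacts/"]
    if couple:
        files.append("embeddings/")
    manifest = {
        "scale": scale,
        "seed": seed,
        "coupled": couple,
        "n_lnc": N,
        "n_mi": M,
        "n_positive": len(table.positives),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
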