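"""Training loop, negative sampling, feature preparation and ranking.

Training is full-batch Adam on binary cross-entropy with logits for up to
``max_epochs`` epochs, keeping the snapshot with the best validation AUC.
Negative pairs are sampled uniformly outside the full positive set (and
any caller-supplied forbidden set) so no presumed negative is a known
positive anywhere in the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Adam, bce_with_logits
from .config import RunConfig, derive_seed
from .gegcn import build_bipartite_graph
from .io import InteractionTable, RnaSequence
from .lncrna import infer_doc_vector, segment_kmers, train_pvdm
from .metrics import roc_auc
from .mirna import ContactMap, onehot_features
from .model import LinkModel

__all__ = [
    "PairExample",
    "TrainState",
    "sample_negatives",
    "prepare_lnc_stacks",
    "prepare_mi_features",
    "train_model",
    "predict_ranked",
]


@dataclass(frozen=True)
class PairExample:
    lnc_id: str
    mi_id: str
    label: int
    split_tag: str = "train"  # "train" | "val" | "test"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.split_tag not in ("train", "val", "test"):
            raise ValueError(f"bad split_tag {self.split_tag!r}")


@dataclass
class TrainState:
    epochs_run: int = 0
    loss_trace: list[float] = field(default_factory=list)
    val_auc_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")
    seed: int = 0


def sample_negatives(table: InteractionTable, ratio: float, seed: int,
                     forbidden: Iterable[tuple[str, str]] = (),
                     n_reference: int | None = None,
                     lnc_subset: Sequence[str] | None = None,
                     mi_subset: Sequence[str] | None = None,
                     split_tag: str = "train") -> list[PairExample]:
    """Uniformly sample floor(ratio * P) distinct presumed-negative pairs.

    Excluded are all positive pairs of ``table`` (regardless of fold) and
    everything in ``forbidden``.  ``lnc_subset``/``mi_subset`` restrict the
    candidate grid, which blind splits use to keep sampled training
    negatives away from blinded entities.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    positives = set(table.positives)
    banned = positives | set(forbidden)
    p_count = n_reference if n_reference is not None else len(positives)
    want = int(ratio * p_count)
    if want == 0:
        return []
    lncs = list(lnc_subset) if lnc_subset is not None else table.lnc_ids
    mis = list(mi_subset) if mi_subset is not None else table.mi_ids
    candidates = [(l, m) for l in lncs for m in mis if (l, m) not in banned]
    if len(candidates) < want:
        raise ValueError(
            f"cannot sample {want} negatives: only {len(candidates)} candidate "
            "pairs outside the positive/forbidden sets"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=want, replace=False)
    return [PairExample(*candidates[i], label=0, split_tag=split_tag)
            for i in sorted(chosen)]


def prepare_lnc_stacks(sequences: dict[str, RnaSequence], config: RunConfig,
                       train_ids: Sequence[str] | None = None
                       ) -> dict[str, np.ndarray]:
    """Multiscale PV-DM stacks for every lncRNA.

    PV-DM models are trained per scale on ``train_ids`` only (leak-free
    default); the remaining sequences get vectors by frozen-table
    inference.  With ``leak_free_pvdm=False`` or ``train_ids=None`` all
    sequences join pretraining.
    """
    all_ids = list(sequences)
    if train_ids is None or not config.leak_free_pvdm:
        train_ids = all_ids
    else:
        train_ids = [i for i in all_ids if i in set(train_ids)]
    if not train_ids:
        raise ValueError("no training sequences for PV-DM pretraining")
    held_out = [i for i in all_ids if i not in set(train_ids)]

    per_scale: list[dict[str, np.ndarray]] = []
    for k in config.k_values:
        corpus = [segment_kmers(sequences[i], k) for i in train_ids]
        model = train_pvdm(
            corpus, dim=config.embed_dim, window=config.window,
            n_negative=config.n_negative, epochs=config.pvdm_epochs,
            lr=config.pvdm_lr, seed=derive_seed(config.seed, f"pvdm-k{k}"),
        )
        vecs = {i: model.doc_table[j] for j, i in enumerate(train_ids)}
        for i in held_out:
            doc = segment_kmers(sequences[i], k)
            infer_seed = derive_seed(config.seed, f"infer-k{k}-{i}")
            try:
                vecs[i] = infer_doc_vector(
                    model, doc, steps=config.infer_steps, lr=config.pvdm_lr,
                    seed=infer_seed)
            except ValueError:
                # fully out-of-vocabulary at this scale (plausible for large
                # k): fall back to the seeded initialization
                rng = np.random.default_rng(infer_seed)
                vecs[i] = (rng.random(config.embed_dim) - 0.5) / config.embed_dim
        per_scale.append(vecs)

    return {i: np.stack([vecs[i] for vecs in per_scale]) for i in all_ids}


def prepare_mi_features(sequences: dict[str, RnaSequence],
                        config: RunConfig,
                        external: dict[str, np.ndarray] | None = None
                        ) -> dict[str, np.ndarray]:
    """Initial node features per miRNA: external matrices or one-hot.

    ``feature_mode="onehot"`` forces the bundled one-hot fallback even
    when external embeddings are available (ablation switch).
    """
    feats: dict[str, np.ndarray] = {}
    for mid, seq in sequences.items():
        if config.feature_mode == "pretrained" and external and mid in external:
            H0 = np.asarray(external[mid], dtype=np.float64)
            if H0.shape[0] != seq.length:
                raise ValueError(
                    f"external embedding for {mid!r} has {H0.shape[0]} rows, "
                    f"sequence length is {seq.length}")
            feats[mid] = H0
        else:
            feats[mid] = onehot_features(seq).H0
    return feats


def train_model(config: RunConfig,
                train_pairs: Sequence[PairExample],
                val_pairs: Sequence[PairExample],
                graph_table: InteractionTable,
                lnc_stacks: dict[str, np.ndarray],
                mi_features: dict[str, np.ndarray],
                mi_contacts: dict[str, ContactMap],
                _clamp_broadcast: bool = False) -> tuple[LinkModel, TrainState]:
    """Train end-to-end and return the best-validation snapshot.

    ``graph_table`` defines the interaction graph visible during training
    (training positives only); validation/test pairs must never appear in
    it.  ``_clamp_broadcast`` zeroes broadcast-weight gradients every step
    (used to verify the vanilla-GCN ablation identity).
    """
    if not train_pairs:
        raise ValueError("empty training split")
    lnc_ids = list(lnc_stacks)
    mi_ids = list(mi_features)
    graph = build_bipartite_graph(graph_table)
    model = LinkModel(config, lnc_ids, mi_ids, lnc_stacks, mi_features,
                      mi_contacts, graph)

    li = np.array([model._lnc_pos[p.lnc_id] for p in train_pairs], dtype=np.intp)
    mi = np.array([model._mi_pos[p.mi_id] for p in train_pairs], dtype=np.intp)
    labels = np.array([p.label for p in train_pairs], dtype=np.float64)
    val_tuples = [(p.lnc_id, p.mi_id) for p in val_pairs]
    val_labels = np.array([p.label for p in val_pairs], dtype=np.int64)
    val_usable = len(val_pairs) > 0 and 0 < val_labels.sum() < len(val_labels)

    opt = Adam(model.trainable_parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    state = TrainState(seed=config.seed)
    best_snap = model.snapshot()

    for epoch in range(1, config.max_epochs + 1):
        logits = model.forward_logits(li, mi, training=True)
        loss = bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(lr={config.lr}, mode={config.interaction_mode})")
        opt.zero_grad()
        loss.backward()
        if _clamp_broadcast:
            model.B_lnc.grad = None
            model.B_mi.grad = None
            model.B_lnc.data[:] = 0.0
            model.B_mi.data[:] = 0.0
        opt.step()
        state.loss_trace.append(float(loss.data))
        state.epochs_run = epoch

        if val_usable:
            val_auc = roc_auc(model.predict_proba(val_tuples), val_labels)
            state.val_auc_trace.append(val_auc)
            if not (val_auc <= state.best_val_auc):  # NaN-safe first update
                state.best_val_auc = val_auc
                state.best_epoch = epoch
                best_snap = model.snapshot()

    if val_usable:
        model.restore(best_snap)
    else:
        state.best_epoch = state.epochs_run
    return model, state


def predict_ranked(model: LinkModel,
                   candidates: Sequence[tuple[str, str]]
                   ) -> list[tuple[str, str, float, int]]:
    """Rank candidate pairs by predicted probability, descending.

    Ties break lexicographically on (lnc_id, mi_id) for reproducibility.
    """
    probs = model.predict_proba(candidates)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-probs[i], candidates[i][0], candidates[i][1]))
    return [(candidates[i][0], candidates[i][1], float(probs[i]), rank + 1)
            for rank, i in enumerate(order)]
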