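"""Cross-validation and cold-start split machinery, plus the label-noise
protocol and the per-setting experiment runner.

Three families of settings are supported:

* ``standard`` — positives partitioned into k near-equal folds;
* ``blind_lnc`` / ``blind_mi`` / ``blind_both`` — entities of the blinded
  type(s) partitioned into k folds; a fold's validation set is every
  interaction whose blinded entity (or, for blind_both, both entities)
  falls in the fold, training is everything else, and blind_both drops
  mixed pairs (exactly one blinded entity) from that fold entirely;
* ``independent`` — a single train/val/test partition of pairs.

The blind guarantee — no validation blinded entity touches any training
interaction of its fold, sampled negatives included — is enforced by
construction and re-asserted in :func:`fold_pairs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RunConfig, config_hash, derive_seed
from .io import InteractionTable, RnaSequence
from .metrics import MetricsReport, aggregate_reports, compute_metrics
from .mirna import ContactMap
from .train import (PairExample, prepare_lnc_stacks, prepare_mi_features,
                    sample_negatives, train_model)

__all__ = [
    "SplitSpec",
    "make_cv_folds",
    "make_blind_split",
    "inject_label_noise",
    "run_setting",
    "write_split",
    "read_split",
]

BLIND_MODES = ("blind_lnc", "blind_mi", "blind_both")
ALL_MODES = ("standard",) + BLIND_MODES + ("independent",)


@dataclass
class SplitSpec:
    """Fold assignment for one experimental setting.

    ``pair_folds`` maps positive pairs to folds (standard/independent);
    ``lnc_folds``/``mi_folds`` map blinded entities to folds.
    """

    mode: str
    folds: int
    seed: int
    pair_folds: dict[tuple[str, str], int] = field(default_factory=dict)
    lnc_folds: dict[str, int] = field(default_factory=dict)
    mi_folds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ALL_MODES:
            raise ValueError(f"unknown split mode {self.mode!r}")

    def fold_pairs(self, fold: int, table: InteractionTable
                   ) -> tuple[list, list, list]:
        """(train, val, dropped) positive pairs for one fold.

        Every positive pair lands in exactly one of the three lists.
        """
        if not 0 <= fold < self.folds:
            raise ValueError(f"fold {fold} out of range 0..{self.folds - 1}")
        positives = table.positives
        train, val, dropped = [], [], []
        if self.mode in ("standard", "independent"):
            for pair in positives:
                (val if self.pair_folds[pair] == fold else train).append(pair)
        elif self.mode == "blind_lnc":
            for pair in positives:
                (val if self.lnc_folds[pair[0]] == fold else train).append(pair)
        elif self.mode == "blind_mi":
            for pair in positives:
                (val if self.mi_folds[pair[1]] == fold else train).append(pair)
        else:  # blind_both
            for lnc, mi in positives:
                lnc_in = self.lnc_folds[lnc] == fold
                mi_in = self.mi_folds[mi] == fold
                if lnc_in and mi_in:
                    val.append((lnc, mi))
                elif lnc_in or mi_in:
                    dropped.append((lnc, mi))
                else:
                    train.append((lnc, mi))
        self._assert_blind(fold, train, val)
        return train, val, dropped

    def _assert_blind(self, fold: int, train, val) -> None:
        if self.mode not in BLIND_MODES:
            return
        if self.mode in ("blind_lnc", "blind_both"):
            blinded = {l for l, f in self.lnc_folds.items() if f == fold}
            assert not (blinded & {l for l, _ in train}), \
                f"blind violation: fold-{fold} lncRNAs appear in training pairs"
        if self.mode in ("blind_mi", "blind_both"):
            blinded = {m for m, f in self.mi_folds.items() if f == fold}
            assert not (blinded & {m for _, m in train}), \
                f"blind violation: fold-{fold} miRNAs appear in training pairs"

    def blinded_entities(self, fold: int) -> tuple[set[str], set[str]]:
        lnc = {l for l, f in self.lnc_folds.items() if f == fold} \
            if self.mode in ("blind_lnc", "blind_both") else set()
        mi = {m for m, f in self.mi_folds.items() if f == fold} \
            if self.mode in ("blind_mi", "blind_both") else set()
        return lnc, mi


def _partition(items: list, k: int, rng: np.random.Generator) -> dict:
    """Shuffle and deal into k folds whose sizes differ by at most one."""
    order = list(rng.permutation(len(items)))
    return {items[idx]: i % k for i, idx in enumerate(order)}


def make_cv_folds(table: InteractionTable, k: int = 5,
                  seed: int = 0) -> SplitSpec:
    """Partition positive pairs into k near-equal folds."""
    positives = table.positives
    if len(positives) < k:
        raise ValueError(f"{len(positives)} positives cannot fill {k} folds")
    rng = np.random.default_rng(derive_seed(seed, "cv-folds"))
    return SplitSpec(mode="standard", folds=k, seed=seed,
                     pair_folds=_partition(positives, k, rng))


def make_blind_split(table: InteractionTable, mode: str, k: int = 5,
                     seed: int = 0) -> SplitSpec:
    """Partition blinded entities into k folds (cold-start settings)."""
    if mode not in BLIND_MODES:
        raise ValueError(f"mode must be one of {BLIND_MODES}, got {mode!r}")
    spec = SplitSpec(mode=mode, folds=k, seed=seed)
    rng = np.random.default_rng(derive_seed(seed, f"{mode}-folds"))
    if mode in ("blind_lnc", "blind_both"):
        if len(table.lnc_ids) < k:
            raise ValueError(f"{len(table.lnc_ids)} lncRNAs cannot fill {k} folds")
        spec.lnc_folds = _partition(list(table.lnc_ids), k, rng)
    if mode in ("blind_mi", "blind_both"):
        if len(table.mi_ids) < k:
            raise ValueError(f"{len(table.mi_ids)} miRNAs cannot fill {k} folds")
        spec.mi_folds = _partition(list(table.mi_ids), k, rng)
    return spec


def inject_label_noise(pairs: Sequence[PairExample], ratio: float,
                       seed: int) -> list[PairExample]:
    """Swap the labels of floor(ratio * min(P, Q)) positives and as many
    negatives, chosen uniformly.  Class totals are conserved."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"noise ratio must be in [0, 1], got {ratio}")
    pos_idx = [i for i, p in enumerate(pairs) if p.label == 1]
    neg_idx = [i for i, p in enumerate(pairs) if p.label == 0]
    n_flip = int(ratio * min(len(pos_idx), len(neg_idx)))
    if n_flip == 0:
        return list(pairs)
    rng = np.random.default_rng(derive_seed(seed, "label-noise"))
    flip = set(rng.choice(pos_idx, size=n_flip, replace=False).tolist())
    flip |= set(rng.choice(neg_idx, size=n_flip, replace=False).tolist())
    out = []
    for i, p in enumerate(pairs):
        if i in flip:
            out.append(PairExample(p.lnc_id, p.mi_id, 1 - p.label, p.split_tag))
        else:
            out.append(p)
    return out


# -- persistence ---------------------------------------------------------------


def write_split(spec: SplitSpec, path: str | Path) -> None:
    """TSV rows: kind, id1, id2, fold — sorted for byte-stable output."""
    with open(Path(path), "w") as fh:
        fh.write(f"#mode={spec.mode}\tfolds={spec.folds}\tseed={spec.seed}\n")
        for (lnc, mi), f in sorted(spec.pair_folds.items()):
            fh.write(f"pair\t{lnc}\t{mi}\t{f}\n")
        for lnc, f in sorted(spec.lnc_folds.items()):
            fh.write(f"lnc\t{lnc}\t-\t{f}\n")
        for mi, f in sorted(spec.mi_folds.items()):
            fh.write(f"mi\t{mi}\t-\t{f}\n")


def read_split(path: str | Path) -> SplitSpec:
    pair_folds, lnc_folds, mi_folds = {}, {}, {}
    mode, folds, seed = "standard", 5, 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for item in line[1:].split("\t"):
                    key, _, value = item.partition("=")
                    if key == "mode":
                        mode = value
                    elif key == "folds":
                        folds = int(value)
                    elif key == "seed":
                        seed = int(value)
                continue
            kind, id1, id2, f = line.split("\t")
            if kind == "pair":
                pair_folds[(id1, id2)] = int(f)
            elif kind == "lnc":
                lnc_folds[id1] = int(f)
            elif kind == "mi":
                mi_folds[id1] = int(f)
    return SplitSpec(mode=mode, folds=folds, seed=seed, pair_folds=pair_folds,
                     lnc_folds=lnc_folds, mi_folds=mi_folds)


# -- experiment runner ---------------------------------------------------------


def _fold_examples(spec: SplitSpec, fold: int, table: InteractionTable,
                   config: RunConfig) -> tuple[list[PairExample], list[PairExample]]:
    """Assemble labelled train/val examples (positives + sampled negatives)."""
    train_pos, val_pos, _dropped = spec.fold_pairs(fold, table)
    blinded_lnc, blinded_mi = spec.blinded_entities(fold)
    seed_val = derive_seed(spec.seed, f"fold{fold}-val-neg")
    seed_train = derive_seed(spec.seed, f"fold{fold}-train-neg")

    # validation negatives live in the same regime as validation positives
    val_lnc = sorted(blinded_lnc) if blinded_lnc else None
    val_mi = sorted(blinded_mi) if blinded_mi else None
    val_neg = sample_negatives(table, config.eval_neg_ratio, seed_val,
                               n_reference=len(val_pos),
                               lnc_subset=val_lnc, mi_subset=val_mi,
                               split_tag="val")
    # training negatives must avoid blinded entities and validation negatives
    train_lnc = [l for l in table.lnc_ids if l not in blinded_lnc] \
        if blinded_lnc else None
    train_mi = [m for m in table.mi_ids if m not in blinded_mi] \
        if blinded_mi else None
    forbidden = {(p.lnc_id, p.mi_id) for p in val_neg}
    train_neg = sample_negatives(table, config.neg_ratio, seed_train,
                                 forbidden=forbidden,
                                 n_reference=len(train_pos),
                                 lnc_subset=train_lnc, mi_subset=train_mi,
                                 split_tag="train")
    train = [PairExample(l, m, 1, "train") for l, m in train_pos] + train_neg
    val = [PairExample(l, m, 1, "val") for l, m in val_pos] + val_neg
    return train, val


def _train_and_score(config: RunConfig, table: InteractionTable,
                     train: list[PairExample], val: list[PairExample],
                     lnc_seqs: dict[str, RnaSequence],
                     mi_seqs: dict[str, RnaSequence],
                     contacts: dict[str, ContactMap],
                     external_mi: dict[str, np.ndarray] | None,
                     noise_ratio: float) -> MetricsReport:
    if noise_ratio > 0:
        train = inject_label_noise(train, noise_ratio, config.seed)
    train_pos = [(p.lnc_id, p.mi_id) for p in train if p.label == 1]
    graph_table = InteractionTable.from_pairs(
        [(l, m, 1) for l, m in train_pos],
        lnc_ids=[l for l in table.lnc_ids
                 if l in {x for x, _ in train_pos}],
        mi_ids=[m for m in table.mi_ids
                if m in {y for _, y in train_pos}],
    )
    train_lnc_ids = sorted({p.lnc_id for p in train})
    stacks = prepare_lnc_stacks(lnc_seqs, config, train_ids=train_lnc_ids)
    feats = prepare_mi_features(mi_seqs, config, external=external_mi)
    model, _state = train_model(config, train, val, graph_table, stacks,
                                feats, contacts)
    probs = model.predict_proba([(p.lnc_id, p.mi_id) for p in val])
    labels = [p.label for p in val]
    return compute_metrics(probs, labels, threshold=config.threshold)


def run_setting(config: RunConfig, table: InteractionTable,
                lnc_seqs: dict[str, RnaSequence],
                mi_seqs: dict[str, RnaSequence],
                contacts: dict[str, ContactMap],
                mode: str = "standard",
                external_mi: dict[str, np.ndarray] | None = None,
                noise_ratio: float = 0.0,
                test_fraction: float = 0.2,
                val_fraction: float = 0.1) -> dict:
    """Run a full experimental setting and return a JSON-able report.

    Cross-validated modes train one model per fold and report per-fold
    plus mean +/- sd metrics.  ``independent`` performs one train/val/test
    partition of pairs (fractions configurable) and reports test metrics.
    """
    if mode not in ALL_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    report: dict = {
        "mode": mode,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "noise_ratio": noise_ratio,
        "folds": [],
    }

    if mode == "independent":
        positives = table.positives
        rng = np.random.default_rng(derive_seed(config.seed, "independent"))
        order = rng.permutation(len(positives))
        n_test = max(1, int(test_fraction * len(positives)))
        n_val = max(1, int(val_fraction * len(positives)))
        test_pos = [positives[i] for i in order[:n_test]]
        val_pos = [positives[i] for i in order[n_test:n_test + n_val]]
        train_pos = [positives[i] for i in order[n_test + n_val:]]
        neg_seed = derive_seed(config.seed, "independent-neg")
        test_neg = sample_negatives(table, config.eval_neg_ratio, neg_seed,
                                    n_reference=len(test_pos), split_tag="test")
        forb = {(p.lnc_id, p.mi_id) for p in test_neg}
        val_neg = sample_negatives(table, config.eval_neg_ratio, neg_seed + 1,
                                   forbidden=forb, n_reference=len(val_pos),
                                   split_tag="val")
        forb |= {(p.lnc_id, p.mi_id) for p in val_neg}
        train_neg = sample_negatives(table, config.neg_ratio, neg_seed + 2,
                                     forbidden=forb, n_reference=len(train_pos),
                                     split_tag="train")
        train = [PairExample(l, m, 1, "train") for l, m in train_pos] + train_neg
        val = [PairExample(l, m, 1, "val") for l, m in val_pos] + val_neg
        test = [PairExample(l, m, 1, "test") for l, m in test_pos] + test_neg
        if noise_ratio > 0:
            train = inject_label_noise(train, noise_ratio, config.seed)
        train_pos_now = [(p.lnc_id, p.mi_id) for p in train if p.label == 1]
        graph_table = InteractionTable.from_pairs(
            [(l, m, 1) for l, m in train_pos_now])
        stacks = prepare_lnc_stacks(
            lnc_seqs, config, train_ids=sorted({p.lnc_id for p in train}))
        feats = prepare_mi_features(mi_seqs, config, external=external_mi)
        model, _ = train_model(config, train, val, graph_table, stacks,
                               feats, contacts)
        probs = model.predict_proba([(p.lnc_id, p.mi_id) for p in test])
        rep = compute_metrics(probs, [p.label for p in test],
                              threshold=config.threshold)
        report["folds"].append(rep.to_dict())
        report["aggregate"] = aggregate_reports([rep])
        return report

    if mode == "standard":
        spec = make_cv_folds(table, k=config.folds, seed=config.seed)
    else:
        spec = make_blind_split(table, mode, k=config.folds, seed=config.seed)

    fold_reports: list[MetricsReport] = []
    for fold in range(config.folds):
        train, val = _fold_examples(spec, fold, table, config)
        if not val or len({p.label for p in val}) < 2:
            continue  # degenerate fold (e.g. no positives blinded here)
        rep = _train_and_score(config, table, train, val, lnc_seqs, mi_seqs,
                               contacts, external_mi, noise_ratio)
        fold_reports.append(rep)
        report["folds"].append(rep.to_dict())
    if not fold_reports:
        raise ValueError(f"no usable folds for mode {mode!r}")
    report["aggregate"] = aggregate_reports(fold_reports)
    return report
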