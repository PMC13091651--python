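"""End-to-end link-prediction model.

The model glues together the three encoders and the scoring head:

* lncRNA: frozen multiscale PV-DM stacks fused by trainable single-head
  self-attention;
* miRNA: trainable GCN over each contact graph, mean-pooled;
* interaction graph: trainable free node embeddings refined by the
  globally enhanced GCN over the training bipartite graph;
* head: per-view linear projections to a shared width, per-side mean
  fusion, concatenation, and a two-layer MLP emitting one logit.

Two forward paths exist on purpose.  Training runs through the autodiff
engine; evaluation (``predict_proba``) runs through the plain-NumPy
reference operations of :mod:`rnalink.lncrna`, :mod:`rnalink.mirna` and
:mod:`rnalink.gegcn`, so each path independently checks the other.

Entities absent from the training interaction graph (cold-start) receive
the trained per-type hub state as their topology embedding.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, glorot
from .config import RunConfig, derive_seed
from .gegcn import BipartiteGraph, block_adjacency, run_ge_gcn
from .lncrna import AttentionFusion, MultiscaleStack, fuse_multiscale
from .mirna import ContactMap, GcnStack, NodeFeatures, encode_mirna, normalized_adjacency

__all__ = ["LinkModel", "fuse_pair", "score_pair_numpy"]


def fuse_pair(e_m_lnc: np.ndarray, e_i_lnc: np.ndarray,
              e_m_mi: np.ndarray, e_i_mi: np.ndarray) -> np.ndarray:
    """Mean-fuse the two views per side and concatenate to a 2d vector."""
    vecs = [np.asarray(v, dtype=np.float64)
            for v in (e_m_lnc, e_i_lnc, e_m_mi, e_i_mi)]
    widths = {v.shape for v in vecs}
    if len(widths) != 1 or vecs[0].ndim != 1:
        raise ValueError(f"all four views must be equal-width vectors, got {widths}")
    lnc = (vecs[0] + vecs[1]) / 2.0
    mi = (vecs[2] + vecs[3]) / 2.0
    return np.concatenate([lnc, mi])


def score_pair_numpy(W1, b1, W2, b2, fused: np.ndarray) -> float:
    """Reference MLP: logit = relu(x W1 + b1) W2 + b2 (no dropout)."""
    h = np.maximum(fused @ W1 + b1, 0.0)
    out = np.asarray(h @ W2 + b2).ravel()
    if out.size != 1:
        raise ValueError("expected a single logit")
    return float(out[0])


class LinkModel:
    """Trainable link predictor over fixed per-entity inputs.

    Parameters are plain float64 arrays wrapped in autodiff tensors; the
    class never touches a GPU or external frameworks.
    """

    def __init__(self, config: RunConfig,
                 lnc_ids: Sequence[str], mi_ids: Sequence[str],
                 lnc_stacks: dict[str, np.ndarray],
                 mi_features: dict[str, np.ndarray],
                 mi_contacts: dict[str, ContactMap],
                 graph: BipartiteGraph,
                 seed: int | None = None):
        self.config = config
        self.lnc_ids = list(lnc_ids)
        self.mi_ids = list(mi_ids)
        self.graph = graph
        self._lnc_pos = {l: i for i, l in enumerate(self.lnc_ids)}
        self._mi_pos = {m: i for i, m in enumerate(self.mi_ids)}
        seed = config.seed if seed is None else seed

        stacks = [np.asarray(lnc_stacks[l], dtype=np.float64) for l in self.lnc_ids]
        shapes = {s.shape for s in stacks}
        if len(shapes) != 1:
            raise ValueError(f"lncRNA stacks disagree on shape: {shapes}")
        self._stack_tensor = np.stack(stacks)            # (n_lnc, S, d_pv)
        self.d_pv = self._stack_tensor.shape[2]

        self._mi_h0 = [np.asarray(mi_features[m], dtype=np.float64)
                       for m in self.mi_ids]
        self._mi_anorm = [normalized_adjacency(mi_contacts[m].A)
                          for m in self.mi_ids]
        for m, h0, a in zip(self.mi_ids, self._mi_h0, self._mi_anorm):
            if h0.shape[0] != a.shape[0]:
                raise ValueError(f"miRNA {m!r}: features/contact size mismatch")
        self.d0 = self._mi_h0[0].shape[1]

        N, M = graph.N, graph.M
        self._block_anorm = normalized_adjacency(block_adjacency(graph))
        # map each known entity to its training-graph row, or to the extra
        # hub row (index N or M) if it carries no training interactions
        self._lnc_graph_row = np.array(
            [graph.lnc_index.get(l, N) for l in self.lnc_ids], dtype=np.intp)
        self._mi_graph_row = np.array(
            [graph.mi_index.get(m, M) for m in self.mi_ids], dtype=np.intp)

        self._init_params(seed)
        self._drop_rng = np.random.default_rng(derive_seed(seed, "dropout"))

    # -- parameters -----------------------------------------------------------

    def _init_params(self, seed: int) -> None:
        cfg = self.config
        g, h, dp = cfg.ge_dim, cfg.gcn_hidden, cfg.proj_dim
        N, M = self.graph.N, self.graph.M

        # one derived rng per parameter: init draws never depend on the
        # shapes of other components (e.g. the graph size in "none" mode)
        def prng(name: str) -> np.random.Generator:
            return np.random.default_rng(derive_seed(seed, f"init-{name}"))

        self.W_Q = glorot(prng("W_Q"), self.d_pv, self.d_pv)
        self.W_K = glorot(prng("W_K"), self.d_pv, self.d_pv)
        self.W_V = glorot(prng("W_V"), self.d_pv, self.d_pv)

        widths = [self.d0] + [h] * cfg.gcn_layers
        self.gcn_Ws = [glorot(prng(f"gcn_W{i}"), a, b)
                       for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]))]

        self.ge_init = Tensor(prng("ge_init").normal(0.0, 0.1, size=(N + M, g)),
                              requires_grad=True)
        self.ge_Ws = [glorot(prng(f"ge_W{i}"), g, g)
                      for i in range(cfg.ge_layers)]
        # zero-initialized so the first step is exactly a vanilla GCN and
        # gradients still flow (tanh'(0) = 1)
        self.B_lnc = Tensor(np.zeros((g, g)), requires_grad=True)
        self.B_mi = Tensor(np.zeros((g, g)), requires_grad=True)

        self.proj_lnc_M = glorot(prng("proj_lnc_M"), self.d_pv, dp)
        self.proj_lnc_I = glorot(prng("proj_lnc_I"), g, dp)
        self.proj_mi_M = glorot(prng("proj_mi_M"), h, dp)
        self.proj_mi_I = glorot(prng("proj_mi_I"), g, dp)

        self.mlp_W1 = glorot(prng("mlp_W1"), 2 * dp, dp)
        self.mlp_b1 = Tensor(np.zeros((1, dp)), requires_grad=True)
        self.mlp_W2 = glorot(prng("mlp_W2"), dp, 1)
        self.mlp_b2 = Tensor(np.zeros((1, 1)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return ([self.W_Q, self.W_K, self.W_V] + self.gcn_Ws
                + [self.ge_init] + self.ge_Ws + [self.B_lnc, self.B_mi]
                + [self.proj_lnc_M, self.proj_lnc_I, self.proj_mi_M,
                   self.proj_mi_I, self.mlp_W1, self.mlp_b1, self.mlp_W2,
                   self.mlp_b2])

    def trainable_parameters(self) -> list[Tensor]:
        """Parameter subset optimized under the configured ablation mode."""
        mode = self.config.interaction_mode
        seq_params = [self.W_Q, self.W_K, self.W_V] + self.gcn_Ws \
            + [self.proj_lnc_M, self.proj_mi_M]
        topo_params = [self.ge_init] + self.ge_Ws \
            + [self.proj_lnc_I, self.proj_mi_I]
        head = [self.mlp_W1, self.mlp_b1, self.mlp_W2, self.mlp_b2]
        if mode == "ge_gcn":
            return seq_params + topo_params + [self.B_lnc, self.B_mi] + head
        if mode == "vanilla_gcn":
            return seq_params + topo_params + head
        if mode == "none":
            return seq_params + head
        return topo_params + head  # "only"

    # -- autodiff forward -----------------------------------------------------

    def _forward_e_m(self) -> tuple[Tensor, Tensor]:
        H = Tensor(self._stack_tensor)                       # (n, S, d)
        Q, K, V = H @ self.W_Q, H @ self.W_K, H @ self.W_V
        scores = (Q @ K.transpose_last()) / np.sqrt(self.d_pv)
        E_lnc = (scores.softmax_last() @ V).mean(axis=1)     # (n, d)

        rows = []
        for h0, anorm in zip(self._mi_h0, self._mi_anorm):
            x = Tensor(h0)
            A = Tensor(anorm)
            for W in self.gcn_Ws:
                x = ((A @ x) @ W).relu()
            rows.append(x.mean(axis=0).reshape(1, -1))
        E_mi = concat(rows, axis=0)                          # (m, h)
        return E_lnc, E_mi

    def _forward_e_i(self) -> tuple[Tensor, Tensor]:
        """Topology embeddings extended with one trailing hub row each."""
        N, M = self.graph.N, self.graph.M
        A = Tensor(self._block_anorm)
        X = self.ge_init
        idx_lnc = np.arange(N)
        idx_mi = np.arange(N, N + M)
        for W in self.ge_Ws:
            X = ((A @ X) @ W).tanh()
            hub_l = X.take_rows(idx_lnc).mean(axis=0).reshape(1, -1)
            hub_m = X.take_rows(idx_mi).mean(axis=0).reshape(1, -1)
            X = concat([
                X.take_rows(idx_lnc) + (hub_l @ self.B_lnc).tanh(),
                X.take_rows(idx_mi) + (hub_m @ self.B_mi).tanh(),
            ], axis=0)
        E_lnc = X.take_rows(idx_lnc)
        E_mi = X.take_rows(idx_mi)
        E_lnc_ext = concat([E_lnc, E_lnc.mean(axis=0).reshape(1, -1)], axis=0)
        E_mi_ext = concat([E_mi, E_mi.mean(axis=0).reshape(1, -1)], axis=0)
        return E_lnc_ext, E_mi_ext

    def forward_logits(self, lnc_idx: np.ndarray, mi_idx: np.ndarray,
                       training: bool = False) -> Tensor:
        """Logits for pairs given by positions into lnc_ids/mi_ids."""
        mode = self.config.interaction_mode
        half = 0.5

        if mode != "only":
            E_M_lnc, E_M_mi = self._forward_e_m()
            P_lm = E_M_lnc @ self.proj_lnc_M
            P_mm = E_M_mi @ self.proj_mi_M
        if mode != "none":
            E_I_lnc, E_I_mi = self._forward_e_i()
            P_li = E_I_lnc @ self.proj_lnc_I
            P_mi = E_I_mi @ self.proj_mi_I

        # without per-view normalization the free-embedding topology view can
        # grow to dominate the fused mean and memorize the training pairs
        if self.config.view_norm:
            if mode != "only":
                P_lm, P_mm = P_lm.normalize_rows(), P_mm.normalize_rows()
            if mode != "none":
                P_li, P_mi = P_li.normalize_rows(), P_mi.normalize_rows()

        gl = self._lnc_graph_row[lnc_idx]
        gm = self._mi_graph_row[mi_idx]
        if mode == "none":
            fused_l = P_lm.take_rows(lnc_idx)
            fused_m = P_mm.take_rows(mi_idx)
        elif mode == "only":
            fused_l = P_li.take_rows(gl)
            fused_m = P_mi.take_rows(gm)
        else:
            t_l = P_li.take_rows(gl)
            t_m = P_mi.take_rows(gm)
            if training and self.config.topo_dropout > 0:
                # keep the sequence view reliable on its own; the topology
                # view contributes as a stochastic bonus during training
                t_l = t_l.dropout(self.config.topo_dropout, self._drop_rng)
                t_m = t_m.dropout(self.config.topo_dropout, self._drop_rng)
            fused_l = (P_lm.take_rows(lnc_idx) + t_l) * half
            fused_m = (P_mm.take_rows(mi_idx) + t_m) * half

        x = concat([fused_l, fused_m], axis=1)
        hdn = (x @ self.mlp_W1 + self.mlp_b1).relu()
        hdn = hdn.dropout(self.config.dropout, self._drop_rng, training=training)
        return (hdn @ self.mlp_W2 + self.mlp_b2).reshape(len(lnc_idx))

    # -- NumPy reference path -------------------------------------------------

    def reference_embeddings(self) -> dict[str, np.ndarray]:
        """Eval-mode embeddings via the reference (non-autodiff) operations."""
        cfg = self.config
        out: dict[str, np.ndarray] = {}
        if cfg.interaction_mode != "only":
            att = AttentionFusion(self.W_Q.data, self.W_K.data, self.W_V.data)
            scales = list(range(self._stack_tensor.shape[1]))
            out["E_M_lnc"] = np.stack([
                fuse_multiscale(MultiscaleStack(lid, self._stack_tensor[i], scales), att)
                for i, lid in enumerate(self.lnc_ids)])
            stack = GcnStack([W.data for W in self.gcn_Ws], activation="relu")
            rows = []
            for mid, h0, anorm in zip(self.mi_ids, self._mi_h0, self._mi_anorm):
                # reconstruct the raw adjacency from the normalized one
                A_raw = (anorm > 0).astype(float)
                np.fill_diagonal(A_raw, 0.0)
                cmap = ContactMap(mid, A_raw)
                feats = NodeFeatures(mid, h0, source="external")
                rows.append(encode_mirna(feats, cmap, stack))
            out["E_M_mi"] = np.stack(rows)
        if cfg.interaction_mode != "none":
            topo = run_ge_gcn(self.graph, self.ge_init.data,
                              [W.data for W in self.ge_Ws],
                              self.B_lnc.data, self.B_mi.data,
                              activation="tanh")
            out["E_I_lnc"] = np.vstack([topo.E_lnc, topo.E_lnc.mean(axis=0)])
            out["E_I_mi"] = np.vstack([topo.E_mi, topo.E_mi.mean(axis=0)])
        return out

    def predict_logits(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Deterministic eval-mode logits through the reference path."""
        for lnc, mi in pairs:
            if lnc not in self._lnc_pos:
                raise KeyError(f"unknown lncRNA id {lnc!r} (no embedding available)")
            if mi not in self._mi_pos:
                raise KeyError(f"unknown miRNA id {mi!r} (no embedding available)")
        li = np.array([self._lnc_pos[l] for l, _ in pairs], dtype=np.intp)
        mi_ = np.array([self._mi_pos[m] for _, m in pairs], dtype=np.intp)
        emb = self.reference_embeddings()
        mode = self.config.interaction_mode
        def _norm(x):
            if not self.config.view_norm:
                return x
            return x / np.sqrt((x * x).sum(axis=1, keepdims=True) + 1e-8)

        if mode != "only":
            pm_l = _norm(emb["E_M_lnc"] @ self.proj_lnc_M.data)
            pm_m = _norm(emb["E_M_mi"] @ self.proj_mi_M.data)
        if mode != "none":
            pi_l = _norm(emb["E_I_lnc"] @ self.proj_lnc_I.data)
            pi_m = _norm(emb["E_I_mi"] @ self.proj_mi_I.data)
        gl = self._lnc_graph_row[li]
        gm = self._mi_graph_row[mi_]
        if mode == "none":
            fl, fm = pm_l[li], pm_m[mi_]
        elif mode == "only":
            fl, fm = pi_l[gl], pi_m[gm]
        else:
            fl = (pm_l[li] + pi_l[gl]) / 2.0
            fm = (pm_m[mi_] + pi_m[gm]) / 2.0
        x = np.concatenate([fl, fm], axis=1)
        h = np.maximum(x @ self.mlp_W1.data + self.mlp_b1.data, 0.0)
        return (h @ self.mlp_W2.data + self.mlp_b2.data).ravel()

    def predict_proba(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        logits = self.predict_logits(pairs)
        out = np.empty_like(logits)
        pos = logits >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-logits[pos]))
        ex = np.exp(logits[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    # -- persistence ----------------------------------------------------------

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {
            "config": self.config.to_dict(),
            "lnc_ids": self.lnc_ids,
            "mi_ids": self.mi_ids,
            "graph_lnc_ids": sorted(self.graph.lnc_index, key=self.graph.lnc_index.get),
            "graph_mi_ids": sorted(self.graph.mi_index, key=self.graph.mi_index.get),
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        arrays["A_I"] = self.graph.A_I
        arrays["stack_tensor"] = self._stack_tensor
        for i, (h0, an) in enumerate(zip(self._mi_h0, self._mi_anorm)):
            arrays[f"mi_h0_{i}"] = h0
            arrays[f"mi_anorm_{i}"] = an
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LinkModel":
        from .mirna import ContactMap
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            config = RunConfig.from_dict(meta["config"])
            graph = BipartiteGraph(
                A_I=z["A_I"],
                lnc_index={l: i for i, l in enumerate(meta["graph_lnc_ids"])},
                mi_index={m: i for i, m in enumerate(meta["graph_mi_ids"])},
            )
            stacks = {l: z["stack_tensor"][i]
                      for i, l in enumerate(meta["lnc_ids"])}
            feats, contacts = {}, {}
            for i, m in enumerate(meta["mi_ids"]):
                feats[m] = z[f"mi_h0_{i}"]
                anorm = z[f"mi_anorm_{i}"]
                A_raw = (anorm > 0).astype(float)
                np.fill_diagonal(A_raw, 0.0)
                contacts[m] = ContactMap(m, A_raw)
            model = cls(config, meta["lnc_ids"], meta["mi_ids"], stacks,
                        feats, contacts, graph)
            for i, p in enumerate(model.parameters()):
                p.data = z[f"param_{i}"].astype(np.float64)
        return model
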