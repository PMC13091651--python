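import itertools

import numpy as np
import pytest

from rnalink.io import RnaSequence
from rnalink.lncrna import (AttentionFusion, MultiscaleStack, PvdmModel,
                            attention_weights, fuse_multiscale,
                            infer_doc_vector, pvdm_hidden, pvdm_predict_prob,
                            segment_kmers, train_pvdm)
from rnalink.synthetic import gen_sequences


class TestSegmentKmers:
    def test_basic(self, rna):
        doc = segment_kmers(rna("ACGU"), 3)
        assert doc.tokens == ("ACG", "CGU")

    def test_length_equals_k(self, rna):
        doc = segment_kmers(rna("ACGUA"), 5)
        assert doc.tokens == ("ACGUA",)

    def test_too_short_errors_with_id(self, rna):
        with pytest.raises(ValueError, match="x.*length 2"):
            segment_kmers(rna("AC", rna_id="x"), 3)

    def test_count_identity_100_random(self):
        seqs = gen_sequences(100, (16, 120), "lncRNA", seed=5)
        for rec in seqs:
            for k in (3, 9, 15):
                doc = segment_kmers(rec, k)
                assert len(doc.tokens) == rec.length - k + 1
                assert all(len(t) == k for t in doc.tokens)

    def test_consecutive_overlap(self, rna):
        doc = segment_kmers(rna("ACGUACGU"), 4)
        for a, b in zip(doc.tokens, doc.tokens[1:]):
            assert a[1:] == b[:-1]


class TestPvdmHidden:
    def test_identical_vectors_average_to_themselves(self):
        x = np.full(8, 1.7)
        out = pvdm_hidden(x, [x] * 4, window=2)
        assert np.allclose(out, x)

    def test_zero_context(self):
        e = np.ones(4)
        out = pvdm_hidden(e, [np.zeros(4)] * 6, window=3)
        assert np.allclose(out, e / 7)

    def test_matches_bruteforce_mean(self, rng):
        c = 5
        doc = rng.standard_normal(16)
        ctx = [rng.standard_normal(16) for _ in range(2 * c)]
        out = pvdm_hidden(doc, ctx, window=c)
        # independent brute-force elementwise loop
        expect = np.zeros(16)
        for j in range(16):
            total = doc[j]
            for v in ctx:
                total += v[j]
            expect[j] = total / (2 * c + 1)
        assert np.max(np.abs(out - expect)) < 1e-12

    def test_wrong_context_count(self):
        with pytest.raises(ValueError, match="4 context"):
            pvdm_hidden(np.zeros(3), [np.zeros(3)] * 3, window=2)

    def test_linearity(self, rng):
        doc = rng.standard_normal(6)
        ctx = [rng.standard_normal(6) for _ in range(4)]
        assert np.allclose(pvdm_hidden(2 * doc, [2 * v for v in ctx], 2),
                           2 * pvdm_hidden(doc, ctx, 2))


def tiny_model(vectors, vocab=("AAA", "CCC", "GGG")):
    V = len(vocab)
    d = vectors.shape[1]
    return PvdmModel(k=3, vocab=list(vocab),
                     word_table=np.zeros((V, d)),
                     context_table=vectors,
                     doc_table=np.zeros((1, d)),
                     doc_ids=["doc0"], window=2, n_negative=3, seed=0)


class TestPvdmPredictProb:
    def test_uniform_when_rows_identical(self, rng):
        vecs = np.tile(rng.standard_normal(4), (3, 1))
        m = tiny_model(vecs)
        h = rng.standard_normal(4)
        for tok in m.vocab:
            assert np.isclose(pvdm_predict_prob(m, h, tok), 1 / 3)

    def test_probabilities_sum_to_one(self, rng):
        m = tiny_model(rng.standard_normal((3, 4)))
        h = rng.standard_normal(4)
        total = sum(pvdm_predict_prob(m, h, t) for t in m.vocab)
        assert abs(total - 1.0) < 1e-9

    def test_matches_bruteforce_softmax(self):
        vecs = np.array([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0]])
        m = tiny_model(vecs)
        h = np.array([0.5, -0.25])
        scores = [np.exp(v @ h) for v in vecs]
        for i, tok in enumerate(m.vocab):
            assert np.isclose(pvdm_predict_prob(m, h, tok),
                              scores[i] / sum(scores))

    def test_unknown_token_errors(self, rng):
        m = tiny_model(rng.standard_normal((3, 4)))
        with pytest.raises(KeyError):
            pvdm_predict_prob(m, np.zeros(4), "UUU")


def corpus_of(n, seed=0, length=(24, 40), k=3):
    return [segment_kmers(r, k)
            for r in gen_sequences(n, length, "lncRNA", seed=seed)]


class TestTrainPvdm:
    def test_shapes_and_vocab(self):
        docs = corpus_of(2, seed=1)
        m = train_pvdm(docs, dim=8, epochs=2, seed=0)
        assert m.doc_table.shape == (2, 8)
        distinct = {t for d in docs for t in d.tokens}
        assert set(m.vocab) == distinct

    def test_deterministic(self):
        docs = corpus_of(3, seed=2)
        a = train_pvdm(docs, dim=8, epochs=3, seed=7)
        b = train_pvdm(docs, dim=8, epochs=3, seed=7)
        assert np.array_equal(a.doc_table, b.doc_table)
        assert np.array_equal(a.word_table, b.word_table)

    def test_loss_decreases(self):
        docs = corpus_of(10, seed=3, length=(40, 60))
        _, trace = train_pvdm(docs, dim=16, epochs=20, lr=0.3, seed=0,
                              return_loss_trace=True)
        assert trace[19] < trace[0]

    def test_empty_corpus(self):
        with pytest.raises(ValueError):
            train_pvdm([], dim=4)

    def test_mixed_scales_rejected(self):
        docs = corpus_of(1, seed=1, k=3) + corpus_of(1, seed=2, k=4)
        with pytest.raises(ValueError, match="scales"):
            train_pvdm(docs, dim=4)

    def test_save_load_roundtrip(self, tmp_path):
        m = train_pvdm(corpus_of(2, seed=4), dim=8, epochs=2, seed=1)
        m.save(tmp_path / "m.npz")
        back = PvdmModel.load(tmp_path / "m.npz")
        assert back.vocab == m.vocab
        assert np.array_equal(back.doc_table, m.doc_table)
        assert back.window == m.window


class TestInferDocVector:
    def test_steps_zero_returns_seeded_init(self):
        docs = corpus_of(3, seed=5)
        m = train_pvdm(docs, dim=8, epochs=2, seed=0)
        v = infer_doc_vector(m, docs[0], steps=0, seed=42)
        rng = np.random.default_rng(42)
        assert np.array_equal(v, (rng.random(8) - 0.5) / 8)

    def test_deterministic(self):
        docs = corpus_of(3, seed=5)
        m = train_pvdm(docs, dim=8, epochs=2, seed=0)
        a = infer_doc_vector(m, docs[1], steps=10, seed=9)
        b = infer_doc_vector(m, docs[1], steps=10, seed=9)
        assert np.array_equal(a, b)

    def test_nearest_neighbor_is_own_trained_vector(self):
        # ten documents built from distinct motifs -> separable vocabularies
        rng = np.random.default_rng(6)
        letters = np.array(list("ACGU"))
        motifs = ["".join(rng.choice(letters, size=6)) for _ in range(10)]
        docs = [segment_kmers(
            RnaSequence(id=f"d{i}", seq=(m * 15)[:80], rna_type="lncRNA"), 3)
            for i, m in enumerate(motifs)]
        m = train_pvdm(docs, dim=16, epochs=40, lr=0.5, window=2, seed=0)
        center = m.doc_table.mean(axis=0)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

        hits = 0
        for target in range(10):
            v = infer_doc_vector(m, docs[target], steps=100, lr=0.5,
                                 seed=1) - center
            sims = [cos(v, m.doc_table[i] - center) for i in range(10)]
            hits += int(np.argmax(sims)) == target
        # inference is noisy at this scale; a clear majority must match
        assert hits >= 8

    def test_scale_mismatch(self):
        docs = corpus_of(2, seed=5)
        m = train_pvdm(docs, dim=8, epochs=1, seed=0)
        other = corpus_of(1, seed=5, k=4)[0]
        with pytest.raises(ValueError, match="k=4"):
            infer_doc_vector(m, other)

    def test_fully_oov_errors(self, rna):
        m = train_pvdm([segment_kmers(rna("AAAAAA"), 3)], dim=4, epochs=1)
        with pytest.raises(ValueError, match="no token"):
            infer_doc_vector(m, segment_kmers(rna("CCCCCC", rna_id="y"), 3))


class TestFuseMultiscale:
    def test_identical_rows_reduce_to_value_projection(self, rng):
        d = 6
        att = AttentionFusion.init(d, seed=0)
        x = rng.standard_normal(d)
        stack = MultiscaleStack("r", np.tile(x, (3, 1)), [3, 9, 15])
        assert np.allclose(fuse_multiscale(stack, att), x @ att.W_V)

    def test_permutation_invariance_all_orders(self, rng):
        d = 5
        att = AttentionFusion.init(d, seed=1)
        H = rng.standard_normal((3, d))
        base = fuse_multiscale(MultiscaleStack("r", H, [0, 1, 2]), att)
        for perm in itertools.permutations(range(3)):
            out = fuse_multiscale(
                MultiscaleStack("r", H[list(perm)], [0, 1, 2]), att)
            assert np.max(np.abs(out - base)) < 1e-6

    def test_attention_rows_sum_to_one(self, rng):
        att = AttentionFusion.init(4, seed=2)
        H = rng.standard_normal((6, 4))
        A = attention_weights(H, att)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-9)
        assert (A >= 0).all()

    def test_width_mismatch(self, rng):
        att = AttentionFusion.init(4, seed=0)
        stack = MultiscaleStack("r", rng.standard_normal((2, 5)), [3, 9])
        with pytest.raises(ValueError, match="width"):
            fuse_multiscale(stack, att)

    def test_rotation_equivariance_of_inputs(self, rng):
        # rotating H and the projections' input space together leaves the
        # output unchanged
        d = 4
        att = AttentionFusion.init(d, seed=3)
        H = rng.standard_normal((3, d))
        Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
        rotated = AttentionFusion(Q.T @ att.W_Q, Q.T @ att.W_K, Q.T @ att.W_V)
        out1 = fuse_multiscale(MultiscaleStack("r", H, [0, 1, 2]), att)
        out2 = fuse_multiscale(MultiscaleStack("r", H @ Q, [0, 1, 2]), rotated)
        assert np.max(np.abs(out1 - out2)) < 1e-8
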