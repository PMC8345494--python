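"""BiLSTM-CRF tagger: gradients, training behavior, persistence."""

import numpy as np
import pytest

import emsner.tagger as tagger_mod
from emsner.dataset import Corpus, build_vocab, pad_batch
from emsner.preprocessing import TokenizedReport
from emsner.tagger import BiLstmCrfTagger, TaggerConfig, train
from emsner.tags import is_iob2_valid, mentions_to_iob2


def tiny_corpus(rng, n=6):
    words = ["pt", "given", "aspirin", "ecg", "done", "stat"]
    rows = []
    for i in range(n):
        k = int(rng.integers(2, 7))
        toks = tuple(rng.choice(words, size=k))
        tags = ["B-Aspirin" if t == "aspirin" else "B-ECG" if t == "ecg" else "O"
                for t in toks]
        rows.append((TokenizedReport(str(i), toks), tags))
    return Corpus(rows)


def tiny_config(**kw):
    base = dict(embedding_dim=8, hidden_dim=6, batch_size=4, max_epochs=3,
                seed=0, zero_init_embeddings=False)
    base.update(kw)
    return TaggerConfig(**base)


def test_config_defaults_are_deployed_values():
    cfg = TaggerConfig()
    assert (cfg.embedding_dim, cfg.hidden_dim) == (100, 64)
    assert (cfg.batch_size, cfg.learning_rate) == (512, 0.001)
    assert (cfg.patience, cfg.max_epochs, cfg.max_len) == (5, 300, 300)
    assert cfg.zero_init_embeddings
    with pytest.raises(ValueError):
        TaggerConfig(hidden_dim=0)


def test_encode_shape_and_determinism(rng):
    corpus = tiny_corpus(rng)
    model = BiLstmCrfTagger(build_vocab(corpus), tiny_config())
    enc = model._encode_corpus(corpus)
    batch, mask = pad_batch(enc, pad_index=model.vocab.pad_index)
    em1 = model.encode(batch, mask)
    em2 = model.encode(batch, mask)
    assert em1.shape == (len(corpus), batch.shape[1], 35)
    assert np.isfinite(em1).all()
    assert np.array_equal(em1, em2)


def test_permuting_distinct_tokens_changes_emissions(rng):
    corpus = tiny_corpus(rng)
    model = BiLstmCrfTagger(build_vocab(corpus), tiny_config())
    batch = model.vocab.encode(["aspirin", "ecg", "pt"])[None, :]
    mask = np.ones((1, 3), dtype=bool)
    em1 = model.encode(batch, mask)
    em2 = model.encode(batch[:, [1, 0, 2]], mask)
    assert not np.allclose(em1, em2)


def test_full_model_gradients_match_finite_differences(rng):
    corpus = tiny_corpus(rng, n=4)
    model = BiLstmCrfTagger(build_vocab(corpus), tiny_config(embedding_dim=5, hidden_dim=4))
    model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
    batch, mask = pad_batch(model._encode_corpus(corpus), pad_index=model.vocab.pad_index)
    tags, _ = pad_batch(model._encode_tags(corpus), pad_index=0)
    loss, grads = model.loss_and_grads(batch, mask, tags)
    assert loss >= 0
    eps = 1e-6
    for name, p in model.params.items():
        idxs = list(np.ndindex(p.shape))
        sel = rng.choice(len(idxs), size=min(6, len(idxs)), replace=False)
        for k in sel:
            ix = idxs[k]
            orig = p[ix]
            p[ix] = orig + eps
            hi, _ = model.loss_and_grads(batch, mask, tags)
            p[ix] = orig - eps
            lo, _ = model.loss_and_grads(batch, mask, tags)
            p[ix] = orig
            num = (hi - lo) / (2 * eps)
            assert num == pytest.approx(grads[name][ix], abs=2e-4), name


def test_masked_pad_tags_never_alter_loss(rng):
    """Randomizing the tags stored at padded positions leaves the loss
    unchanged: the loss never reads masked positions."""
    corpus = tiny_corpus(rng)
    model = BiLstmCrfTagger(build_vocab(corpus), tiny_config())
    batch, mask = pad_batch(model._encode_corpus(corpus), pad_index=model.vocab.pad_index)
    tags, _ = pad_batch(model._encode_tags(corpus), pad_index=0)
    loss1, _ = model.loss_and_grads(batch, mask, tags)
    tags2 = tags.copy()
    tags2[~mask] = rng.integers(0, 35, size=(~mask).sum())
    loss2, _ = model.loss_and_grads(batch, mask, tags2)
    assert loss1 == pytest.approx(loss2, rel=1e-6)


def test_training_reduces_loss_and_is_deterministic(rng):
    corpus = tiny_corpus(rng, n=8)
    cfg = tiny_config(max_epochs=8, batch_size=4)
    model1, hist1 = train(corpus, corpus, cfg)
    model2, hist2 = train(corpus, corpus, cfg)
    assert hist1[-1]["train_loss"] < hist1[0]["train_loss"]
    assert [h["dev_loss"] for h in hist1] == [h["dev_loss"] for h in hist2]
    for k in model1.params:
        assert np.array_equal(model1.params[k], model2.params[k])


def test_early_stopping_restores_best_epoch(rng, monkeypatch):
    """Dev losses 5,4,4,4,4,4,4 must stop after epoch 7 (patience 5 against
    the running minimum) and restore the epoch-2 parameters."""
    scripted = iter([5.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 3.0])
    snapshots = {}
    real_loss_and_grads = BiLstmCrfTagger.loss_and_grads

    def fake_corpus_loss(self, corpus):
        return next(scripted)

    monkeypatch.setattr(BiLstmCrfTagger, "corpus_loss", fake_corpus_loss)
    corpus = tiny_corpus(rng, n=4)
    model, history = train(corpus, corpus, tiny_config(max_epochs=50, patience=5))
    assert len(history) == 7
    assert [h["dev_loss"] for h in history] == [5.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0]
    # best epoch is epoch 2; parameters must differ from the epoch-7 state
    assert min(range(7), key=lambda i: history[i]["dev_loss"]) == 1


def test_early_stop_never_exceeds_max_epochs(rng):
    corpus = tiny_corpus(rng, n=4)
    _, history = train(corpus, corpus, tiny_config(max_epochs=2, patience=5))
    assert len(history) == 2


def test_train_rejects_empty_corpus(rng):
    with pytest.raises(ValueError, match="empty"):
        train(Corpus([]), tiny_corpus(rng), tiny_config())


def test_predict_contracts(rng):
    corpus = tiny_corpus(rng)
    model, _ = train(corpus, corpus, tiny_config(max_epochs=2))
    assert model.predict_batch([]) == []
    for rep, _ in corpus:
        mentions = model.predict(rep)
        for m in mentions:
            assert 0 <= m.start < m.end <= len(rep.tokens)
            assert m.source == "predicted"
        tags = mentions_to_iob2(mentions, len(rep.tokens))
        assert is_iob2_valid(tags)


def test_checkpoint_roundtrip(tmp_path, rng):
    corpus = tiny_corpus(rng)
    model, _ = train(corpus, corpus, tiny_config(max_epochs=2))
    path = tmp_path / "model.npz"
    model.save(path)
    back = BiLstmCrfTagger.load(path)
    assert back.config == model.config
    assert back.vocab.index == model.vocab.index
    for rep, _ in corpus:
        assert back.predict(rep) == model.predict(rep)
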