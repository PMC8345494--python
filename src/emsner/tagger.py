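"""The BiLSTM-CRF sequence tagger and its training loop.

Architecture: a trainable word-embedding table (zero-initialized by
default), a bidirectional LSTM encoder (hidden size per direction), a
linear projection to per-tag emission scores, and a linear-chain CRF whose
forward-algorithm likelihood is the training objective and whose Viterbi
path is the prediction.

Training uses Adam, mini-batches over shuffled reports, and early stopping:
the run halts once the development loss has failed to improve on its
running minimum for ``patience`` consecutive epochs, and the parameters of
the best-development-loss epoch are restored.  Everything is NumPy; the
gradients (manual BPTT through the encoder, forward-backward marginals
through the CRF) are finite-difference-checked in the test suite.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bilstm import LSTMParams, lstm_backward, lstm_forward, reverse_within_length
from .crf import (
    CrfParams,
    batch_log_partition,
    batch_marginals,
    batch_path_score,
    batch_viterbi,
)
from .dataset import Corpus, Vocab, build_vocab, pad_batch
from .lexicon import DEFAULT_SCHEMA, EntitySchema
from .preprocessing import TokenizedReport
from .tags import Mention, iob2_to_mentions, tag_vocabulary

__all__ = ["TaggerConfig", "BiLstmCrfTagger", "train"]

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "emsner-bilstm-crf-v1"


@dataclass
class TaggerConfig:
    """Hyperparameters; the defaults are the deployed configuration."""

    embedding_dim: int = 100
    hidden_dim: int = 64  # per direction; encoder output is 2x this
    batch_size: int = 512
    learning_rate: float = 0.001
    patience: int = 5
    max_epochs: int = 300
    seed: int = 0
    max_len: int = 300
    zero_init_embeddings: bool = True
    min_count: int = 1

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_dim", "batch_size", "patience",
                     "max_epochs", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


class BiLstmCrfTagger:
    """A trained (or trainable) BiLSTM-CRF model bound to a vocabulary and
    tag inventory."""

    def __init__(
        self,
        vocab: Vocab,
        config: TaggerConfig,
        schema: EntitySchema = DEFAULT_SCHEMA,
    ):
        self.vocab = vocab
        self.config = config
        self.schema = schema
        self.tag_list = tag_vocabulary(schema)
        self.tag_index = {t: i for i, t in enumerate(self.tag_list)}
        rng = np.random.default_rng(config.seed)
        V, D, H = len(vocab), config.embedding_dim, config.hidden_dim
        T = len(self.tag_list)
        if config.zero_init_embeddings:
            emb = np.zeros((V, D), dtype=np.float32)
        else:
            emb = rng.uniform(-0.1, 0.1, (V, D)).astype(np.float32)
        fwd = LSTMParams.init(D, H, rng)
        bwd = LSTMParams.init(D, H, rng)
        k = 1.0 / np.sqrt(2 * H)
        self.params: dict[str, np.ndarray] = {
            "emb": emb,
            "f_Wx": fwd.Wx, "f_Wh": fwd.Wh, "f_b": fwd.b,
            "b_Wx": bwd.Wx, "b_Wh": bwd.Wh, "b_b": bwd.b,
            "Wout": rng.uniform(-k, k, (2 * H, T)).astype(np.float32),
            "bout": np.zeros(T, dtype=np.float32),
            "trans": np.zeros((T, T), dtype=np.float32),
            "start": np.zeros(T, dtype=np.float32),
            "end": np.zeros(T, dtype=np.float32),
        }

    # -- forward ----------------------------------------------------------

    def _crf(self) -> CrfParams:
        p = self.params
        return CrfParams(
            p["trans"].astype(np.float64),
            p["start"].astype(np.float64),
            p["end"].astype(np.float64),
        )

    def encode(
        self, batch: np.ndarray, mask: np.ndarray, with_cache: bool = False
    ):
        """Emission scores (B, L, T) for a padded index batch."""
        p = self.params
        x = p["emb"][batch]
        h_f, cache_f = lstm_forward(x, mask, LSTMParams(p["f_Wx"], p["f_Wh"], p["f_b"]))
        x_r = reverse_within_length(x, mask)
        h_b_r, cache_b = lstm_forward(
            x_r, mask, LSTMParams(p["b_Wx"], p["b_Wh"], p["b_b"])
        )
        h_b = reverse_within_length(h_b_r, mask)
        h2 = np.concatenate([h_f, h_b], axis=2)
        emissions = h2 @ p["Wout"] + p["bout"]
        if with_cache:
            return emissions, {"x": x, "h2": h2, "cache_f": cache_f,
                               "cache_b": cache_b, "batch": batch, "mask": mask}
        return emissions

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(
        self, batch: np.ndarray, mask: np.ndarray, tags: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean CRF negative log-likelihood over the batch and gradients for
        every parameter."""
        p = self.params
        emissions, cache = self.encode(batch, mask, with_cache=True)
        # float32 throughout the training path; the float64 single-sequence
        # API in crf.py is the reference the tests compare against
        crf = CrfParams(p["trans"], p["start"], p["end"])
        logZ, unary, pairwise, boundary_end = batch_marginals(emissions, mask, crf)
        gold = batch_path_score(emissions, mask, tags, crf)
        B, L, T = emissions.shape
        loss = float(np.mean(logZ.astype(np.float64) - gold.astype(np.float64)))

        lengths = mask.sum(axis=1)
        rb = np.arange(B)
        d_start = (
            unary[:, 0].sum(axis=0) - np.bincount(tags[:, 0], minlength=T)
        ) / B
        d_end = (
            boundary_end.sum(axis=0)
            - np.bincount(tags[rb, lengths - 1], minlength=T)
        ) / B

        gold_pairs = np.zeros((T, T), dtype=np.float32)
        if L > 1:
            prev = tags[:, :-1][mask[:, 1:]]
            nxt = tags[:, 1:][mask[:, 1:]]
            np.add.at(gold_pairs, (prev, nxt), 1.0)
        d_trans = (pairwise.sum(axis=0) - gold_pairs) / B

        # reuse the unary buffer as the emission gradient
        d_em32 = unary
        rows, cols = np.nonzero(mask)
        d_em32[rows, cols, tags[rows, cols]] -= 1.0
        d_em32 /= B

        # backprop through the projection and the two LSTM directions
        h2 = cache["h2"]
        d_Wout = h2.reshape(B * L, -1).T @ d_em32.reshape(B * L, T)
        d_bout = d_em32.sum(axis=(0, 1))
        d_h2 = d_em32 @ p["Wout"].T
        H = self.config.hidden_dim
        dx_f, g_f = lstm_backward(
            d_h2[:, :, :H], cache["cache_f"], LSTMParams(p["f_Wx"], p["f_Wh"], p["f_b"])
        )
        d_hb_r = reverse_within_length(d_h2[:, :, H:], mask)
        dx_b_r, g_b = lstm_backward(
            d_hb_r, cache["cache_b"], LSTMParams(p["b_Wx"], p["b_Wh"], p["b_b"])
        )
        dx = dx_f + reverse_within_length(dx_b_r, mask)
        d_emb = np.zeros_like(p["emb"])
        np.add.at(d_emb, cache["batch"][mask], dx[mask])

        grads = {
            "emb": d_emb,
            "f_Wx": g_f.Wx, "f_Wh": g_f.Wh, "f_b": g_f.b,
            "b_Wx": g_b.Wx, "b_Wh": g_b.Wh, "b_b": g_b.b,
            "Wout": d_Wout, "bout": d_bout,
            "trans": d_trans.astype(p["trans"].dtype),
            "start": d_start.astype(p["start"].dtype),
            "end": d_end.astype(p["end"].dtype),
        }
        return loss, grads

    # -- corpus-level helpers ---------------------------------------------

    def _encode_corpus(self, corpus: Corpus) -> list[np.ndarray]:
        return [self.vocab.encode(rep.tokens[: self.config.max_len])
                for rep, _ in corpus]

    def _encode_tags(self, corpus: Corpus) -> list[np.ndarray]:
        idx = self.tag_index
        return [
            np.array([idx[t] for t in tags[: self.config.max_len]], dtype=np.int64)
            for _, tags in corpus
        ]

    def corpus_loss(self, corpus: Corpus) -> float:
        """Mean NLL over a labeled corpus (no gradients)."""
        enc, tag_enc = self._encode_corpus(corpus), self._encode_tags(corpus)
        crf = self._crf()
        total, n = 0.0, 0
        bs = self.config.batch_size
        order = sorted(range(len(enc)), key=lambda i: len(enc[i]))
        for lo in range(0, len(order), bs):
            sel = order[lo : lo + bs]
            batch, mask = pad_batch([enc[i] for i in sel], pad_index=self.vocab.pad_index)
            tags, _ = pad_batch([tag_enc[i] for i in sel], pad_index=0)
            em = self.encode(batch, mask).astype(np.float64)
            logZ = batch_log_partition(em, mask, crf)
            gold = batch_path_score(em, mask, tags, crf)
            total += float(np.sum(logZ - gold))
            n += len(logZ)
        return total / n

    def predict(self, report: TokenizedReport) -> list[Mention]:
        """Viterbi-decode one report to predicted mentions."""
        return self.predict_batch([report])[0]

    def predict_batch(self, reports: Sequence[TokenizedReport]) -> list[list[Mention]]:
        if not reports:
            return []
        enc = [self.vocab.encode(r.tokens[: self.config.max_len]) for r in reports]
        out: list[list[Mention] | None] = [None] * len(enc)
        bs = self.config.batch_size
        crf = self._crf()
        nonempty = [i for i in range(len(enc)) if len(enc[i])]
        for i in range(len(enc)):
            if not len(enc[i]):
                out[i] = []
        nonempty.sort(key=lambda i: len(enc[i]))  # length-bucketed decoding
        for lo in range(0, len(nonempty), bs):
            sel = nonempty[lo : lo + bs]
            batch, mask = pad_batch([enc[i] for i in sel], pad_index=self.vocab.pad_index)
            em = self.encode(batch, mask).astype(np.float64)
            for i, path in zip(sel, batch_viterbi(em, mask, crf)):
                tags = [self.tag_list[j] for j in path]
                out[i] = iob2_to_mentions(tags, source="predicted")
        return out

    def predict_tags(self, report: TokenizedReport) -> list[str]:
        from .tags import mentions_to_iob2

        mentions = self.predict(report)
        return mentions_to_iob2(mentions, min(len(report), self.config.max_len))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint (config, vocab, tensors)."""
        header = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "vocab": list(self.vocab.index),
            "entities": {e: self.schema.category[e] for e in self.schema.entities},
        }
        np.savez(
            path,
            __header__=np.frombuffer(
                json.dumps(header).encode("utf-8"), dtype=np.uint8
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmCrfTagger":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode("utf-8"))
            if header.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format in {path}")
            params = {k: data[k] for k in data.files if k != "__header__"}
        vocab = Vocab({t: i for i, t in enumerate(header["vocab"])})
        config = TaggerConfig(**header["config"])
        schema = EntitySchema(dict(header["entities"]))
        model = cls(vocab, config, schema)
        model.params = params
        return model


def train(
    train_corpus: Corpus,
    dev_corpus: Corpus,
    config: TaggerConfig = TaggerConfig(),
    schema: EntitySchema = DEFAULT_SCHEMA,
) -> tuple[BiLstmCrfTagger, list[dict]]:
    """Fit a tagger with Adam and early stopping on the development loss.

    Returns the model restored to its best-development-loss parameters and
    the per-epoch history (train loss, dev loss).  Fully deterministic
    under ``config.seed``.
    """
    if not len(train_corpus):
        raise ValueError("empty training corpus")
    vocab = build_vocab(train_corpus, config.min_count)
    model = BiLstmCrfTagger(vocab, config, schema)
    enc = model._encode_corpus(train_corpus)
    tag_enc = model._encode_tags(train_corpus)
    rng = np.random.default_rng(config.seed)
    adam = _Adam(model.params, config.learning_rate)
    history: list[dict] = []
    best_loss = np.inf
    best_params = None
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        # shuffle, then bucket by length (stable sort keeps the shuffle as
        # tie-break) so each batch pads to a near-native length; batch
        # order is itself shuffled
        order = sorted(rng.permutation(len(enc)), key=lambda i: len(enc[i]))
        batches = [
            order[lo : lo + config.batch_size]
            for lo in range(0, len(order), config.batch_size)
        ]
        rng.shuffle(batches)
        epoch_loss, n_batches = 0.0, 0
        for sel in batches:
            batch, mask = pad_batch([enc[i] for i in sel], pad_index=vocab.pad_index)
            tags, _ = pad_batch([tag_enc[i] for i in sel], pad_index=0)
            loss, grads = model.loss_and_grads(batch, mask, tags)
            adam.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        dev_loss = model.corpus_loss(dev_corpus)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "dev_loss": dev_loss}
        )
        logger.info(
            "epoch %d train %.4f dev %.4f", epoch, epoch_loss / n_batches, dev_loss
        )
        if dev_loss < best_loss:
            best_loss = dev_loss
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best_params is not None:
        model.params = best_params
    return model, history
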