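"""Linear-chain conditional random field in log space.

Scores a tag path ``y`` for a length-T sequence as

    score(y) = start[y_0] + sum_t em[t, y_t]
             + sum_t trans[y_t, y_{t+1}] + end[y_{T-1}]

The partition function (forward algorithm), posterior marginals
(forward-backward) and the Viterbi argmax are all computed with
max-shifted log-sum-exp, so emission magnitudes up to ~1e3 stay finite.
All routines are batched over right-padded sequences with a boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """Max-shifted log-sum-exp along one axis (fast path; no NaN plumbing)."""
    m = x.max(axis=axis, keepdims=True)
    out = np.log(np.exp(x - m).sum(axis=axis))
    out += np.squeeze(m, axis=axis)
    return out

__all__ = [
    "CrfParams",
    "crf_path_score",
    "crf_log_partition",
    "viterbi_decode",
    "batch_log_partition",
    "batch_path_score",
    "batch_marginals",
    "batch_viterbi",
]


@dataclass
class CrfParams:
    """Transition scores between tags plus start/end boundary scores."""

    transitions: np.ndarray  # (T, T): score of tag i followed by tag j
    start: np.ndarray  # (T,)
    end: np.ndarray  # (T,)

    @classmethod
    def zeros(cls, n_tags: int, dtype=np.float64) -> "CrfParams":
        return cls(
            np.zeros((n_tags, n_tags), dtype=dtype),
            np.zeros(n_tags, dtype=dtype),
            np.zeros(n_tags, dtype=dtype),
        )

    @property
    def n_tags(self) -> int:
        return len(self.start)


# ---------------------------------------------------------------------------
# Single-sequence API (used by tests and small-scale scoring)


def crf_path_score(emissions: np.ndarray, crf: CrfParams, tags: np.ndarray) -> float:
    """Unnormalized log score of one tag path."""
    tags = np.asarray(tags)
    T = len(tags)
    if emissions.shape[0] != T:
        raise ValueError("tags length must match emissions length")
    score = crf.start[tags[0]] + emissions[np.arange(T), tags].sum() + crf.end[tags[-1]]
    if T > 1:
        score += crf.transitions[tags[:-1], tags[1:]].sum()
    return float(score)


def crf_log_partition(emissions: np.ndarray, crf: CrfParams) -> float:
    """log-sum-exp over all tag paths, by the forward algorithm."""
    alpha = crf.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _lse(alpha[:, None] + crf.transitions, axis=0) + emissions[t]
    return float(_lse((alpha + crf.end)[None], axis=1)[0])


def viterbi_decode(emissions: np.ndarray, crf: CrfParams) -> tuple[np.ndarray, float]:
    """Best path and its score; ties break toward the lower tag index."""
    L = emissions.shape[0]
    alpha = crf.start + emissions[0]
    backptr = np.zeros((L, crf.n_tags), dtype=np.int64)
    for t in range(1, L):
        scores = alpha[:, None] + crf.transitions
        backptr[t] = scores.argmax(axis=0)
        alpha = scores.max(axis=0) + emissions[t]
    alpha = alpha + crf.end
    best = int(alpha.argmax())
    path = np.empty(L, dtype=np.int64)
    path[-1] = best
    for t in range(L - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return path, float(alpha[best])


# ---------------------------------------------------------------------------
# Batched API over right-padded (B, L, T) emissions with (B, L) mask


def _forward(emissions: np.ndarray, mask: np.ndarray, crf: CrfParams) -> np.ndarray:
    """Forward log-messages alpha (B, L, T); padded steps carry the last
    real alpha forward unchanged."""
    B, L, T = emissions.shape
    alpha = np.empty((B, L, T), dtype=emissions.dtype)
    alpha[:, 0] = crf.start + emissions[:, 0]
    for t in range(1, L):
        new = (
            _lse(alpha[:, t - 1, :, None] + crf.transitions, axis=1)
            + emissions[:, t]
        )
        m = mask[:, t, None]
        alpha[:, t] = np.where(m, new, alpha[:, t - 1])
    return alpha


def batch_log_partition(
    emissions: np.ndarray, mask: np.ndarray, crf: CrfParams
) -> np.ndarray:
    alpha = _forward(emissions, mask, crf)
    return _lse(alpha[:, -1] + crf.end, axis=1)


def batch_path_score(
    emissions: np.ndarray, mask: np.ndarray, tags: np.ndarray, crf: CrfParams
) -> np.ndarray:
    """Gold-path scores for a right-padded batch; pad tags are ignored."""
    B, L, T = emissions.shape
    lengths = mask.sum(axis=1)
    rows = np.arange(B)
    em = np.take_along_axis(emissions, tags[:, :, None], axis=2)[:, :, 0]
    score = (em * mask).sum(axis=1)
    score += crf.start[tags[:, 0]]
    score += crf.end[tags[rows, lengths - 1]]
    if L > 1:
        tr = crf.transitions[tags[:, :-1], tags[:, 1:]]
        score += (tr * mask[:, 1:]).sum(axis=1)
    return score


def batch_marginals(
    emissions: np.ndarray, mask: np.ndarray, crf: CrfParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Posterior unary and pairwise marginals via forward-backward.

    Returns ``(logZ (B,), unary (B,L,T), pairwise_sum (B,T,T),
    boundary_end (B,T))`` where ``pairwise_sum`` is the expected transition
    count summed over positions and ``boundary_end`` the marginal of the
    final real tag.  These are exactly the partial derivatives of logZ with
    respect to emissions, transitions and end scores.
    """
    B, L, T = emissions.shape
    alpha = _forward(emissions, mask, crf)
    logZ = _lse(alpha[:, -1] + crf.end, axis=1)

    # beta[t] at the last real position equals the end scores; padded
    # positions never contribute.
    beta = np.empty((B, L, T), dtype=emissions.dtype)
    beta[:, L - 1] = crf.end
    for t in range(L - 2, -1, -1):
        nxt = emissions[:, t + 1] + beta[:, t + 1]
        new = _lse(crf.transitions[None] + nxt[:, None, :], axis=2)
        m = mask[:, t + 1, None]
        beta[:, t] = np.where(m, new, crf.end)

    unary = np.exp(alpha + beta - logZ[:, None, None]) * mask[:, :, None]

    # pairwise marginals, vectorized over time in blocks to bound memory
    pairwise = np.zeros((B, T, T), dtype=emissions.dtype)
    nxt_msg = emissions + beta - logZ[:, None, None]
    for lo in range(0, L - 1, 32):
        hi = min(lo + 32, L - 1)
        m = mask[:, lo + 1 : hi + 1]
        if not m.any():
            break
        log_p = (
            alpha[:, lo:hi, :, None]
            + crf.transitions[None, None]
            + nxt_msg[:, lo + 1 : hi + 1, None, :]
        )
        np.exp(log_p, out=log_p)
        log_p *= m[:, :, None, None]
        pairwise += log_p.sum(axis=1)

    lengths = mask.sum(axis=1)
    rows = np.arange(B)
    boundary_end = np.exp(
        alpha[rows, lengths - 1] + crf.end - logZ[:, None]
    )
    return logZ, unary, pairwise, boundary_end


def batch_viterbi(
    emissions: np.ndarray, mask: np.ndarray, crf: CrfParams
) -> list[np.ndarray]:
    """Viterbi paths for a right-padded batch, one array per sequence."""
    B, L, T = emissions.shape
    lengths = mask.sum(axis=1)
    alpha = crf.start + emissions[:, 0]
    backptr = np.zeros((B, L, T), dtype=np.int64)
    for t in range(1, L):
        scores = alpha[:, :, None] + crf.transitions[None]
        bp = scores.argmax(axis=1)
        new = np.take_along_axis(scores, bp[:, None, :], axis=1)[:, 0] + emissions[:, t]
        m = mask[:, t, None]
        backptr[:, t] = np.where(m, bp, np.arange(T)[None])
        alpha = np.where(m, new, alpha)
    final = alpha + crf.end
    paths = []
    for b in range(B):
        l = int(lengths[b])
        path = np.empty(l, dtype=np.int64)
        path[-1] = int(final[b].argmax())
        for t in range(l - 1, 0, -1):
            path[t - 1] = backptr[b, t, path[t]]
        paths.append(path)
    return paths
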