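"""Numba SGD kernels for the distributed-memory paragraph-vector model.

The paragraph vector is concatenated with the 2k context word vectors
(out-of-range slots filled by a trainable pad vector, word index 0) to
predict the central word via negative sampling.  All loops are serial and
the RNG is an inlined xorshift64*, so training is bitwise reproducible for
a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_MULT = _U64(0x2545F4914F6CDD1D)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=False)
def _rand_uniform(state):
    x = state[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    state[0] = x
    return float((x * _MULT) >> _U64(11)) * _INV53


@njit(cache=False)
def _sigmoid(f):
    if f > 8.0:
        return 1.0
    if f < -8.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-f))


@njit(cache=False)
def _sample_negative(neg_cdf, state):
    r = _rand_uniform(state)
    idx = np.searchsorted(neg_cdf, r, side="right")
    if idx >= neg_cdf.shape[0]:
        idx = neg_cdf.shape[0] - 1
    return idx + 1  # vocabulary ids start at 1 (0 = pad)


@njit(cache=False)
def _step(center, d, t, beg, end, tokens, word_vecs, doc_vecs, out_vecs,
          neg_cdf, window, negative, alpha, state, h, gh, slots,
          update_words):
    dim = word_vecs.shape[1]
    hidden = h.shape[0]
    for j in range(dim):
        h[j] = doc_vecs[d, j]
    si = 0
    for off in range(-window, window + 1):
        if off == 0:
            continue
        p = t + off
        w = tokens[p] if (beg <= p < end) else 0
        slots[si] = w
        base = (si + 1) * dim
        for j in range(dim):
            h[base + j] = word_vecs[w, j]
        si += 1
    for j in range(hidden):
        gh[j] = 0.0
    for nidx in range(negative + 1):
        if nidx == 0:
            target = center
            label = 1.0
        else:
            target = _sample_negative(neg_cdf, state)
            if target == center:
                continue
            label = 0.0
        f = 0.0
        for j in range(hidden):
            f += float(out_vecs[target, j]) * float(h[j])
        g = np.float32((label - _sigmoid(f)) * alpha)
        for j in range(hidden):
            gh[j] += g * out_vecs[target, j]
        if update_words:
            for j in range(hidden):
                out_vecs[target, j] += g * h[j]
    for j in range(dim):
        doc_vecs[d, j] += gh[j]
    if update_words:
        si = 0
        for off in range(-window, window + 1):
            if off == 0:
                continue
            w = slots[si]
            base = (si + 1) * dim
            for j in range(dim):
                word_vecs[w, j] += gh[base + j]
            si += 1


@njit(cache=False)
def train_epochs(tokens, offsets, word_vecs, doc_vecs, out_vecs, neg_cdf,
                 window, negative, alpha0, min_alpha, epochs, seed,
                 update_words):
    """Run `epochs` SGD passes; linear learning-rate decay over all examples.

    With ``update_words=False`` the word and softmax matrices are frozen and
    only the paragraph vectors are optimized (inference on unseen documents).
    """
    n_docs = offsets.shape[0] - 1
    dim = word_vecs.shape[1]
    hidden = (2 * window + 1) * dim
    h = np.zeros(hidden, dtype=np.float32)
    gh = np.zeros(hidden, dtype=np.float32)
    slots = np.zeros(2 * window, dtype=np.int64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = _U64(seed) * _U64(2654435761) + _U64(0x9E3779B97F4A7C15)
    total = float(tokens.shape[0]) * epochs
    if total == 0:
        return
    processed = 0.0
    for _ in range(epochs):
        for d in range(n_docs):
            beg = offsets[d]
            end = offsets[d + 1]
            for t in range(beg, end):
                alpha = alpha0 - (alpha0 - min_alpha) * (processed / total)
                processed += 1.0
                _step(tokens[t], d, t, beg, end, tokens, word_vecs, doc_vecs,
                      out_vecs, neg_cdf, window, negative, alpha, state,
                      h, gh, slots, update_words)
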