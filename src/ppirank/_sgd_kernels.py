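"""Numba-compiled inner loops for negative-sampling SGD.

The same kernel serves skip-gram-with-negative-sampling training on walk
corpora and LINE edge-sampling training: one positive (center, context)
pair plus K noise contexts per update, logistic losses, sequential
in-place updates.  Sequential execution plus an explicit xorshift RNG
state makes every run bitwise reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgd_epoch", "xorshift_uniform"]

_INV_2_53 = 1.0 / (1 << 53)


@njit(cache=True, inline="always")
def _next_uniform(state):
    # xorshift64*: full-period 64-bit generator, top 53 bits -> [0, 1)
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return ((x * np.uint64(2685821657736338717)) >> np.uint64(11)) * _INV_2_53


def xorshift_uniform(seed: int, n: int) -> np.ndarray:
    """Reference stream of the kernel's RNG (testing hook)."""
    state = np.array([seed if seed != 0 else 0x9E3779B97F4A7C15], dtype=np.uint64)
    return np.array([_next_uniform.py_func(state) for _ in range(n)])


@njit(cache=True)
def sgd_epoch(
    w_in,
    w_out,
    centers,
    contexts,
    alias_prob,
    alias_alias,
    negatives,
    lr_start,
    lr_end,
    done_before,
    total_updates,
    rng_state,
):
    """One pass of negative-sampling SGD over (center, context) pairs.

    w_in, w_out : (n, d) and (m, d) parameter tables, updated in place.
    centers, contexts : int64 arrays of equal length (the positive pairs).
    alias_prob, alias_alias : alias tables of the noise distribution over
        rows of w_out.
    negatives : noise draws per positive pair.
    lr decays linearly from lr_start to lr_end across total_updates, with
    done_before updates already performed in earlier epochs.
    rng_state : length-1 uint64 array, mutated (pass back in next epoch).

    Returns the mean loss over the epoch.
    """
    d = w_in.shape[1]
    k_noise = alias_prob.shape[0]
    n_pairs = centers.shape[0]
    grad_c = np.empty(d, dtype=np.float64)
    total_loss = 0.0

    for t in range(n_pairs):
        frac = (done_before + t) / total_updates
        lr = lr_start + (lr_end - lr_start) * frac
        c = centers[t]
        for s in range(negatives + 1):
            if s == 0:
                o = contexts[t]
                label = 1.0
            else:
                kk = int(_next_uniform(rng_state) * k_noise)
                if kk >= k_noise:
                    kk = k_noise - 1
                if _next_uniform(rng_state) < alias_prob[kk]:
                    o = kk
                else:
                    o = alias_alias[kk]
                label = 0.0
            dot = 0.0
            for j in range(d):
                dot += w_in[c, j] * w_out[o, j]
            if dot > 35.0:
                sig = 1.0
            elif dot < -35.0:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-dot))
            if label > 0.5:
                total_loss += -np.log(max(sig, 1e-300))
            else:
                total_loss += -np.log(max(1.0 - sig, 1e-300))
            g = (sig - label) * lr
            for j in range(d):
                grad_c[j] = g * w_out[o, j]
                w_out[o, j] -= g * w_in[c, j]
            for j in range(d):
                w_in[c, j] -= grad_c[j]
    return total_loss / max(n_pairs, 1)
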