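"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: likelihoods by
exhaustive placement enumeration, hypergeometric tails by draw enumeration,
AUROC by pairwise counting.
"""

import itertools
import math

import numpy as np

from regmap.motif_scoring import encode_sequence


def brute_force_loglik(seq, pwm, bg, p):
    """HMM likelihood by enumeration over all non-overlapping site placements."""
    n, w = len(seq), pwm.width
    codes = encode_sequence(seq)
    bg_lp = bg.logprob_matrix(codes[None, :])[0]

    def site_prob(t):
        if np.any(codes[t : t + w] >= 4):
            return 0.0
        fwd = math.exp(sum(math.log(pwm.probs[codes[t + j], j]) for j in range(w)))
        rev = math.exp(
            sum(math.log(pwm.probs[3 - codes[t + w - 1 - j], j]) for j in range(w))
        )
        return 0.5 * (fwd + rev)

    total = 0.0

    def rec(i, prob):
        nonlocal total
        if i == n:
            total += prob
            return
        rec(i + 1, prob * (1 - p) * math.exp(bg_lp[i]))
        if i + w <= n:
            sp = site_prob(i)
            if sp > 0:
                rec(i + w, prob * p * sp)

    rec(0, 1.0)
    return math.log(total)


def brute_force_hypergeom_sf(x, N, K, n):
    """P(X >= x) by exhaustive enumeration of all C(N, n) draws."""
    successes = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return hits / total


def brute_force_auroc(scores, labels):
    """AUROC by pairwise win counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
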