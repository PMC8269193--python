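"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive pair
counting for the AUC, a full threshold scan for sensitivity at fixed FPR,
and a coarse-to-fine grid maximizer for the logistic likelihood.
"""

import numpy as np


def brute_force_auc(scores, labels):
    """Concordant-pair count with half credit for ties (low score = positive-like)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_sens(scores, labels, target):
    """Exhaustive threshold scan: the largest cut keeping FPR <= target."""
    neg = scores[~labels]
    pos = scores[labels]
    best = None
    for t in np.concatenate([[0.0], np.unique(scores), [100.0]]):
        fpr = np.mean(neg < t)
        if fpr <= target / 100.0 and (best is None or t > best):
            best = t
    return 100.0 * np.mean(pos < best), best


def grid_search_slope(x, y):
    """Profile-likelihood grid maximizer of the logistic slope.

    For each candidate slope the intercept is profiled out exactly (the score
    equation sum(y - p) = 0 is monotone in the intercept), then the slope grid
    is refined coarse-to-fine down to ~1e-6 resolution.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    def profile_loglik(b1):
        def score(b0):
            return float(np.sum(y - expit(b0 + b1 * x)))

        b0 = brentq(score, -500.0, 500.0, xtol=1e-12)
        eta = b0 + b1 * x
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    lo, hi = -1.0, 1.0
    for _ in range(8):
        grid = np.linspace(lo, hi, 41)
        ll = np.array([profile_loglik(b) for b in grid])
        j = int(np.argmax(ll))
        step = grid[1] - grid[0]
        lo, hi = grid[j] - step, grid[j] + step
    return 0.5 * (lo + hi)
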