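"""Independent brute-force oracles used to check the statistics layer.

These deliberately avoid the implementations under test: the signed-rank
p-value is computed by full enumeration of sign assignments, and Kendall
tau-b by O(n^2) pair counting with explicit tie correction.
"""

from itertools import product

import numpy as np
from scipy.stats import rankdata


def signed_rank_p_enumeration(diffs: np.ndarray, alternative: str = "less") -> float:
    """Exact signed-rank p by enumerating all 2^m sign assignments.

    Zeros are handled by the Pratt method: ranked along with everything
    else, then held out of the statistic (their sign never varies).
    """
    d = np.asarray(diffs, float)
    ranks = rankdata(np.abs(d))
    nonzero = np.flatnonzero(d != 0)
    if nonzero.size == 0:
        return 1.0
    r = ranks[nonzero]
    w_obs = r[d[nonzero] > 0].sum()
    count = 0
    total = 0
    for signs in product([0, 1], repeat=nonzero.size):
        w = r[np.array(signs, dtype=bool)].sum()
        total += 1
        if alternative == "less":
            count += w <= w_obs
        elif alternative == "greater":
            count += w >= w_obs
        else:
            raise ValueError(alternative)
    return count / total


def kendall_tau_b_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Tau-b by explicit concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    denom = np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (concordant - discordant) / denom


def upgma_by_hand(D: np.ndarray):
    """Naive UPGMA: merge closest pair, size-weighted average distances.

    Returns the sorted list of merge heights.
    """
    D = D.astype(float).copy()
    sizes = {i: 1 for i in range(D.shape[0])}
    active = list(range(D.shape[0]))
    dist = {(i, j): D[i, j] for i in active for j in active if i < j}
    heights = []
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        new = max(max(sizes) + 1, len(D))
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            dist[(min(c, new), max(c, new))] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        active = [c for c in active if c not in (a, b)] + [new]
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
    return heights
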