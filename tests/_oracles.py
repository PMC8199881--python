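"""Independent brute-force oracles used to check the statistical endpoints.

These deliberately avoid the code paths (and libraries) they are used to
verify: AUC by exhaustive pair counting, the log-rank statistic by the
hypergeometric sum, and the rank-sum p-value by full enumeration of label
assignments.
"""

from itertools import combinations

import numpy as np


def pair_count_auc(scores, labels):
    """AUC as the Mann–Whitney probability from exhaustive pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def logrank_chi2(times, events, groups):
    """Two-group log-rank chi-square by the textbook hypergeometric sum."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    assert len(labels) == 2
    g1 = groups == labels[0]
    o1 = 0.0
    e1 = 0.0
    v = 0.0
    for t in sorted(set(times[events == 1].tolist())):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p-value by full enumeration of label assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    combined = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        wins = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    wins += 1.0
                elif x == y:
                    wins += 0.5
        return wins

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(combined))
    for subset in combinations(idx, n1):
        ga = [combined[i] for i in subset]
        gb = [combined[i] for i in idx if i not in subset]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))
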