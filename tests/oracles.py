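"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the written formulas with naive Python loops and
stay independent of the production (vectorized) code paths they check.
"""

import math


def naive_ac(scores, i, lg):
    """Auto-covariance of column i (0-based) at lag lg; positions 1..L."""
    length = len(scores)
    mean = sum(row[i] for row in scores) / length
    total = 0.0
    for j in range(length - lg):
        total += (scores[j][i] - mean) * (scores[j + lg][i] - mean)
    return total / (length - lg)


def naive_cc(scores, i1, i2, lg):
    """Cross-covariance of ordered column pair (i1, i2) at lag lg."""
    length = len(scores)
    mean1 = sum(row[i1] for row in scores) / length
    mean2 = sum(row[i2] for row in scores) / length
    total = 0.0
    for j in range(length - lg):
        total += (scores[j][i1] - mean1) * (scores[j + lg][i2] - mean2)
    return total / (length - lg)


def naive_sd(scores, m, n, k):
    """Separated-dimer sum for ordered pair (m, n) at separation k."""
    length = len(scores)
    total = 0.0
    for j in range(length - k):
        total += scores[j][m] * scores[j + k][n]
    return total


def naive_entropy(labels):
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def naive_conditional_entropy(x, y):
    n = len(x)
    h = 0.0
    for value in set(y):
        sub = [xi for xi, yi in zip(x, y) if yi == value]
        h += len(sub) / n * naive_entropy(sub)
    return h
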