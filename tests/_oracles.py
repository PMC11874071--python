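"""Independent brute-force oracles used by the test suite.

Each oracle is written from the defining formula of its statistic, in a
deliberately naive style (explicit loops, no vectorization), so it shares
no code path with the package implementation it checks.
"""

import math

import numpy as np
from scipy import stats


def sampen_counts_bruteforce(x, m, r):
    """(A, B) template-pair counts by explicit O(N^2) looping."""
    x = list(map(float, x))
    n_templates = len(x) - m
    a = b = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    return a, b


def sampen_bruteforce(x, m=1, r_frac=0.15):
    """SampEn from the brute-force counts, with the same conventions."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    a, b = sampen_counts_bruteforce(x, m, r_frac * sd)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def gesd_bruteforce(values, max_k, alpha=0.05):
    """Rosner's test, recomputing all R_i first and then all critical values."""
    x = [float(v) for v in values]
    n = len(x)
    working = list(enumerate(x))
    r_stats, removed = [], []
    for _ in range(max_k):
        vals = [v for _, v in working]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        if var == 0:
            break
        sd = math.sqrt(var)
        deviations = [abs(v - mean) for v in vals]
        pos = deviations.index(max(deviations))
        r_stats.append(deviations[pos] / sd)
        removed.append(working.pop(pos)[0])
    n_out = 0
    for i in range(1, len(r_stats) + 1):
        p = 1 - alpha / (2 * (n - i + 1))
        t = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * t / math.sqrt((n - i - 1 + t ** 2) * (n - i + 1))
        if r_stats[i - 1] > lam:
            n_out = i
    return sorted(removed[:n_out])


def complete_linkage_bruteforce(dist):
    """Agglomeration as a list of (merged index sets, height) steps.

    Clusters are frozensets of original item indices; at each step the pair
    of clusters with the smallest maximum pairwise member distance merges.
    """
    dist = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    steps = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        steps.append((merged, d))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return steps


def scipy_linkage_to_steps(Z, n):
    """Convert a scipy linkage matrix to the same (member set, height) steps."""
    members = {i: frozenset([i]) for i in range(n)}
    steps = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        steps.append((merged, float(h)))
    return steps


def pearson_bruteforce(x, y):
    """Pearson r from the covariance formula, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def student_ttest_bruteforce(a, b):
    """Pooled-variance two-sample t and two-sided p from the textbook formula."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s1 = sum((v - m1) ** 2 for v in a) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def calinski_harabasz_manual(X, labels):
    """CH index from centroid sums of squares, written out longhand."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    ks = sorted(set(labels.tolist()))
    overall = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in ks:
        sub = X[labels == c]
        centroid = sub.mean(axis=0)
        between += len(sub) * float(((centroid - overall) ** 2).sum())
        within += float(((sub - centroid) ** 2).sum())
    k = len(ks)
    return (between / (k - 1)) / (within / (n - k))
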