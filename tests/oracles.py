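"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic by direct enumeration, deliberately
sharing no code with the package implementation it checks.
"""

from itertools import combinations
from math import factorial


def ssgsea_bruteforce(values, names, gene_set, alpha):
    """Position-by-position running-sum enumeration of the ssGSEA score."""
    n = len(names)
    order = sorted(range(n), key=lambda i: (-values[i], i))  # stable tie-break
    rho = {gene_idx: n - pos for pos, gene_idx in enumerate(order)}
    in_weights = sum(
        rho[i] ** alpha for i in range(n) if names[i] in gene_set
    )
    n_out = sum(1 for name in names if name not in gene_set)
    score = 0.0
    p_in = 0.0
    p_out = 0.0
    for gene_idx in order:
        if names[gene_idx] in gene_set:
            p_in += rho[gene_idx] ** alpha / in_weights
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def chi2_bruteforce(a, b, c, d):
    """Sum of (observed - expected)^2 / expected over the four cells."""
    total = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    chi2 = 0.0
    for i, obs_row in enumerate(((a, b), (c, d))):
        for j, obs in enumerate(obs_row):
            expected = rows[i] * cols[j] / total
            chi2 += (obs - expected) ** 2 / expected
    return chi2


def holm_bruteforce(p_values):
    """Literal step-down rule: sort, scale by M-k+1, running max, cap at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def mcc_bruteforce(nodes, edges):
    """MCC per node from all maximal cliques, found by subset enumeration."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(frozenset(p) in edge_set for p in combinations(subset, 2))

    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if is_clique(subset):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    scores = {v: 0 for v in nodes}
    for clique in maximal:
        for v in clique:
            scores[v] += factorial(len(clique) - 1)
    return scores


def auc_bruteforce(scores, labels):
    """Fraction of concordant case/control pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
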