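"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def brute_identity(p1: str, p2: str) -> float:
    """All-offsets ungapped identity, written as plainly as possible."""
    best = 0
    for off in range(-(len(p2) - 1), len(p1)):
        matches = 0
        for i in range(len(p1)):
            j = i - off
            if 0 <= j < len(p2) and p1[i] == p2[j]:
                matches += 1
        best = max(best, matches)
    return best / min(len(p1), len(p2))


def brute_shares_9mer(p1: str, p2: str) -> bool:
    k1 = {p1[i : i + 9] for i in range(len(p1) - 8)}
    k2 = {p2[i : i + 9] for i in range(len(p2) - 8)}
    return bool(k1 & k2)


def brute_similar(p1: str, p2: str) -> bool:
    return brute_shares_9mer(p1, p2) or brute_identity(p1, p2) > 0.80


def brute_similar_pairs(peptides) -> set:
    return {
        (i, j)
        for i in range(len(peptides))
        for j in range(i + 1, len(peptides))
        if brute_similar(peptides[i], peptides[j])
    }


def brute_auc(scores, labels, orientation="lower-is-better") -> float:
    """Mann-Whitney pairwise count with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    if orientation == "lower-is-better":
        s = -s
    lab = np.asarray(labels, dtype=bool)
    pos, neg = s[lab], s[~lab]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_rankdata(x) -> np.ndarray:
    """Average ranks, computed by explicit tie grouping."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(x.size)
    order = np.argsort(x, kind="stable")
    i = 0
    while i < x.size:
        j = i
        while j < x.size and x[order[j]] == x[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def brute_spearman(a, b) -> float:
    """Pearson correlation of average ranks (handles ties)."""
    ra, rb = brute_rankdata(a), brute_rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))
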