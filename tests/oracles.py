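"""Independent brute-force oracles used by the test suite.

Everything here is written as straight-line arithmetic over Python lists
and fractions, deliberately sharing no code with the package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# nearest shrunken centroids, straight from the formulas
# ---------------------------------------------------------------------------

def nsc_train_oracle(X: list[list[float]], labels: list[str], delta: float) -> dict:
    """X is genes x samples (list of rows).  Returns every model quantity."""
    classes = sorted(set(labels))
    n = len(labels)
    n_genes = len(X)
    idx_by_class = {k: [i for i, l in enumerate(labels) if l == k] for k in classes}

    overall = [sum(row) / n for row in X]
    centroids = {
        k: [sum(row[i] for i in idx_by_class[k]) / len(idx_by_class[k]) for row in X]
        for k in classes
    }

    s = []
    for j in range(n_genes):
        ss = 0.0
        for k in classes:
            for i in idx_by_class[k]:
                ss += (X[j][i] - centroids[k][j]) ** 2
        s.append(math.sqrt(ss / (n - len(classes))))

    s_sorted = sorted(s)
    mid = len(s_sorted) // 2
    if len(s_sorted) % 2 == 1:
        s0 = s_sorted[mid]
    else:
        s0 = 0.5 * (s_sorted[mid - 1] + s_sorted[mid])

    m = {k: math.sqrt(1.0 / len(idx_by_class[k]) - 1.0 / n) for k in classes}

    shrunken = {}
    for k in classes:
        vals = []
        for j in range(n_genes):
            denom = m[k] * (s[j] + s0)
            d = (centroids[k][j] - overall[j]) / denom if denom > 0 else 0.0
            d_shrunk = math.copysign(max(abs(d) - delta, 0.0), d)
            vals.append(overall[j] + m[k] * (s[j] + s0) * d_shrunk)
        shrunken[k] = vals

    return {
        "classes": classes,
        "overall": overall,
        "centroids": centroids,
        "s": s,
        "s0": s0,
        "m": m,
        "shrunken": shrunken,
        "n_k": {k: len(idx_by_class[k]) for k in classes},
        "n": n,
    }


def nsc_discriminants_oracle(model: dict, x: list[float], priors: dict[str, float]) -> dict:
    out = {}
    for k in model["classes"]:
        total = 0.0
        for j, xj in enumerate(x):
            total += ((xj - model["shrunken"][k][j]) / (model["s"][j] + model["s0"])) ** 2
        out[k] = total - 2.0 * math.log(priors[k])
    return out


def pearson_oracle(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


# ---------------------------------------------------------------------------
# exact test oracles (exact rational arithmetic)
# ---------------------------------------------------------------------------

def mcnemar_exact_oracle(b: int, c: int) -> float:
    """Two-sided exact binomial p by full enumeration of the null."""
    n = b + c
    k = min(b, c)
    half = Fraction(1, 2)
    cdf = sum(Fraction(math.comb(n, i)) * half**n for i in range(k + 1))
    return float(min(Fraction(1), 2 * cdf))


def fisher_exact_oracle(table: list[list[int]]) -> float:
    """Two-sided Fisher p: sum hypergeometric probabilities of all tables
    with the observed margins that are no more likely than the observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = Fraction(math.comb(n, c1))

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x)) / total

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # tiny relative slack mirrors standard float practice for tied tables
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= cutoff))


# ---------------------------------------------------------------------------
# naive UPGMA (unweighted average linkage)
# ---------------------------------------------------------------------------

def upgma_oracle(dist: list[list[float]]) -> list[tuple[frozenset, float]]:
    """O(n^3) average-linkage agglomeration on a full distance matrix.

    Returns the merge sequence as (merged leaf set, merge height) tuples.
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist[a][b] for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def linkage_to_merges(linkage, n: int) -> list[tuple[frozenset, float]]:
    """Convert a scipy linkage matrix into (merged leaf set, height) tuples."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (i, j, height, _) in enumerate(linkage):
        merged = members[int(i)] | members[int(j)]
        members[n + row_idx] = merged
        merges.append((merged, float(height)))
    return merges
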