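"""Independent brute-force oracles, kept free of the package's internals.

Everything here is written with plain dict/loop arithmetic so it cannot
share a bug with the numpy-based implementation it checks.
"""

import itertools
import math

BASES = "ACGU"


def brute_base_probs(seq):
    n = len(seq)
    return {b: seq.count(b) / n for b in BASES}


def brute_d1(seq):
    total = 0.0
    for b in BASES:
        p = seq.count(b) / len(seq)
        if p > 0:
            total += p * math.log2(p)
    return 2.0 + total


def brute_pair_probs(seq):
    pairs = [seq[k: k + 2] for k in range(len(seq) - 1)]
    return {d: pairs.count(d) / len(pairs) for d in map("".join, itertools.product(BASES, repeat=2))}


def brute_d2(seq):
    first = 0.0
    for b in BASES:
        p = seq.count(b) / len(seq)
        if p > 0:
            first += p * math.log2(p)
    second = 0.0
    for p in brute_pair_probs(seq).values():
        if p > 0:
            second += p * math.log2(p)
    return -2.0 * first + second


def brute_gc(seq):
    return (seq.count("G") + seq.count("C")) / len(seq)


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def permutation_p(x, y):
    """Exhaustive two-sided permutation p-value for Pearson r (n <= 8)."""
    robs = abs(brute_pearson(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_pearson(x, perm)) >= robs - 1e-12:
            count += 1
    return count / total
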