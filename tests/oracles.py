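"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: the calling-rule
oracle enumerates k-subsets of the read stack with hypergeometric weights,
and the jackknife oracle is the textbook unweighted delete-one estimator.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_call_distribution(counts, m=2, k=3, f=2, max_depth=None) -> dict[str, float]:
    """Exact call distribution over {A, C, G, T, N} for one counts vector.

    Enumerates every composition of the k-subsample over the four bases,
    weighting by the multivariate hypergeometric probability
    prod(C(c_i, x_i)) / C(n, k); below depth k all reads are used.
    """
    counts = tuple(int(c) for c in counts)
    n = sum(counts)
    dist = {b: 0.0 for b in "ACGTN"}
    if n < m or (max_depth is not None and n > max_depth):
        dist["N"] = 1.0
        return dist
    if n < k:
        dist[_call_from_composition(counts, f)] = 1.0
        return dist
    total = math.comb(n, k)
    for x in _compositions(k, counts):
        weight = math.prod(math.comb(c, xi) for c, xi in zip(counts, x)) / total
        dist[_call_from_composition(x, f)] += weight
    return dist


def _compositions(k, caps):
    ranges = [range(0, min(k, c) + 1) for c in caps]
    for x in itertools.product(*ranges):
        if sum(x) == k:
            yield x


def _call_from_composition(x, f) -> str:
    reaching = [i for i, xi in enumerate(x) if xi >= f]
    if len(reaching) == 1:
        return "ACGT"[reaching[0]]
    return "N"


def all_stacks_up_to_depth(max_total: int):
    """Every (A, C, G, T) counts vector with 1 <= depth <= max_total."""
    for total in range(1, max_total + 1):
        for a in range(total + 1):
            for c in range(total - a + 1):
                for g in range(total - a - c + 1):
                    yield (a, c, g, total - a - c - g)


def unweighted_delete_one_jackknife(values) -> tuple[float, float]:
    """Classic delete-one jackknife (estimate over blocks, SE).

    ``values`` are the delete-one estimates theta_{-j}; returns their mean
    and the jackknife standard error sqrt((g-1)/g * sum (theta_{-j} -
    mean)^2).
    """
    values = np.asarray(values, dtype=float)
    g = len(values)
    mean = values.mean()
    var = (g - 1) / g * np.sum((values - mean) ** 2)
    return float(mean), float(math.sqrt(var))
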