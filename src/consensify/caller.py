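"""The subsampled-consensus (Consensify) base-calling rule.

At each reference position with read-support counts (A, C, G, T) and depth
``n``, the rule with parameters (m, k, f, M):

* makes no call (N) when ``n < m`` or ``n > M``;
* when ``n >= k``, draws ``k`` reads uniformly *without replacement* from the
  stack and calls the base supported by at least ``f`` of them, else N;
* when ``f <= n < k``, uses all ``n`` reads and calls the base supported by at
  least ``f`` of them, else N.

The canonical parameterisation is m=2, k=3, f=2: subsample three reads, call
the base two of them agree on. m=k=f=1 recovers standard single-read
pseudohaploidisation. The maximum depth M masks repeat-rich/mismapped regions
and is typically derived from the 95th percentile of the coverage
distribution (:func:`max_depth_cap`).

Subsampling without replacement means the subsample composition is
multivariate hypergeometric in the stack counts; :func:`call_sites` samples
it with a chained vectorised hypergeometric draw, so whole scaffolds are
called in a few array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import N_CODE, ScaffoldIndex, SiteCounts

CODE_TO_CHAR = np.frombuffer(b"ACGTN", dtype="S1")


@dataclass(frozen=True)
class ConsensifyParams:
    """Calling-rule knobs: min depth m, subsample size k, agreement f, cap M.

    ``max_depth=None`` means unbounded. Defaults are the canonical 2-of-3
    rule.
    """

    m: int = 2
    k: int = 3
    f: int = 2
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 1 or self.f < 1:
            raise ValueError("m, k and f must all be >= 1")
        if self.f > self.k:
            raise ValueError(f"f ({self.f}) must not exceed k ({self.k})")
        if self.max_depth is not None and self.max_depth < self.m:
            raise ValueError(
                f"max depth {self.max_depth} is below the minimum depth m={self.m}: "
                "no site could ever be called"
            )


@dataclass
class CallStats:
    """Bookkeeping of how many sites were seen and successfully called."""

    sites_seen: int = 0
    sites_called: int = 0
    per_scaffold: dict[str, int] = field(default_factory=dict)

    def _validate(self) -> None:
        assert self.sites_called <= self.sites_seen
        assert sum(self.per_scaffold.values()) == self.sites_called


def _subsample_without_replacement(
    counts: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k reads without replacement from each row of stack counts.

    Sequential conditional hypergeometric draws over the four base
    categories; equivalent to a uniform draw of a k-subset of the reads.
    """
    counts = np.asarray(counts, dtype=np.int64)
    remaining_total = counts.sum(axis=1)
    remaining_k = np.full(counts.shape[0], k, dtype=np.int64)
    out = np.zeros_like(counts)
    for j in range(4):
        good = counts[:, j]
        bad = remaining_total - good
        draw = np.zeros_like(good)
        active = remaining_k > 0
        if active.any():
            draw[active] = rng.hypergeometric(good[active], bad[active], remaining_k[active])
        out[:, j] = draw
        remaining_total -= good
        remaining_k -= draw
    return out


def _consensus_from_subsample(sub: np.ndarray, f: int) -> np.ndarray:
    """Apply the >=f agreement rule to subsample compositions.

    A call is made only when exactly one base reaches f supporting reads;
    ties (possible only when 2f <= k) and no-agreement both yield N.
    """
    reaching = sub >= f
    n_reaching = reaching.sum(axis=1)
    code = np.full(sub.shape[0], N_CODE, dtype=np.int64)
    callable_ = n_reaching == 1
    code[callable_] = np.argmax(sub[callable_], axis=1)
    return code


def call_sites(
    counts: np.ndarray, params: ConsensifyParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised calling rule over an (n_sites, 4) counts array.

    Returns integer codes 0..3 for A/C/G/T and 4 for N.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an (n_sites, 4) array")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    depth = counts.sum(axis=1)
    code = np.full(counts.shape[0], N_CODE, dtype=np.int64)

    in_range = depth >= params.m
    if params.max_depth is not None:
        in_range &= depth <= params.max_depth

    deep = in_range & (depth >= params.k)
    if deep.any():
        sub = _subsample_without_replacement(counts[deep], params.k, rng)
        code[deep] = _consensus_from_subsample(sub, params.f)

    shallow = in_range & (depth < params.k)
    if shallow.any():
        code[shallow] = _consensus_from_subsample(counts[shallow], params.f)
    return code


def call_site(
    counts: Iterable[int], params: ConsensifyParams, rng: np.random.Generator
) -> str:
    """Call a single site; returns one of 'A','C','G','T','N'."""
    code = call_sites(np.asarray(list(counts), dtype=np.int64)[None, :], params, rng)[0]
    return "ACGTN"[code]


def consensify_genome(
    sites: Iterable[SiteCounts],
    index: ScaffoldIndex,
    params: ConsensifyParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, str], CallStats]:
    """Call a whole genome from a sorted SiteCounts stream.

    Every indexed scaffold is emitted at full length; positions without a
    counts record (zero coverage) are N. Input must be sorted by scaffold (in
    index order) and position.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    order = {name: i for i, (name, _) in enumerate(index)}
    lengths = dict(index.entries)

    per_scaffold_sites: dict[str, tuple[list[int], list[tuple[int, int, int, int]]]] = {
        name: ([], []) for name in order
    }
    last_key: tuple[int, int] | None = None
    n_seen = 0
    for site in sites:
        n_seen += 1
        if site.scaffold not in order:
            raise ValueError(f"scaffold {site.scaffold!r} not in index")
        if site.position > lengths[site.scaffold]:
            raise ValueError(
                f"position {site.position} beyond scaffold {site.scaffold!r} "
                f"length {lengths[site.scaffold]}"
            )
        key = (order[site.scaffold], site.position)
        if last_key is not None and key <= last_key:
            raise ValueError(
                f"input not sorted by (scaffold, position) at {site.scaffold}:{site.position}"
            )
        last_key = key
        positions, rows = per_scaffold_sites[site.scaffold]
        positions.append(site.position)
        rows.append(site.counts)

    sequences: dict[str, str] = {}
    stats = CallStats(sites_seen=n_seen)
    for name, length in index:
        positions, rows = per_scaffold_sites[name]
        seq_codes = np.full(length, N_CODE, dtype=np.int64)
        called = 0
        if positions:
            codes = call_sites(np.asarray(rows, dtype=np.int64), params, rng)
            seq_codes[np.asarray(positions) - 1] = codes
            called = int((codes != N_CODE).sum())
        sequences[name] = CODE_TO_CHAR[seq_codes].tobytes().decode()
        stats.per_scaffold[name] = called
        stats.sites_called += called
    stats._validate()
    return sequences, stats


def depth_histogram(sites: Iterable[SiteCounts]) -> dict[int, int]:
    """Histogram of read depth over the covered sites of a counts stream."""
    hist: dict[int, int] = {}
    for site in sites:
        hist[site.depth] = hist.get(site.depth, 0) + 1
    return hist


def max_depth_cap(histogram: Mapping[int, int], percentile: float = 0.95) -> int:
    """Maximum-depth cap: largest integer strictly below the depth percentile.

    The empirical percentile of the covered-site depth distribution is taken
    as the order statistic at 0-based rank ``ceil(p * (n - 1))`` (the
    'higher' convention, so the top (1-p) tail is excluded); the cap is the
    largest integer strictly below that value. May fall below the minimum
    calling depth for degenerate distributions, in which case callers should
    warn (the cap is returned regardless).
    """
    if not histogram:
        raise ValueError("empty depth histogram")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    n = sum(histogram.values())
    rank = math.ceil(percentile * (n - 1))  # 0-based order statistic
    cum = 0
    for depth in sorted(histogram):
        cum += histogram[depth]
        if cum >= rank + 1:
            return depth - 1
    raise AssertionError("unreachable: histogram exhausted before rank")
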