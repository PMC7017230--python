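"""ABBA/BABA D statistic with weighted block jackknife standard errors.

For four pseudohaploid sequences arranged (((P1, P2), P3), P4) the base
sampled in the outgroup P4 is taken as ancestral (A) and the alternate state
as derived (B). Biallelic columns with pattern (A,B,B,A) — P2 and P3 share
the derived allele — are ABBA sites; (B,A,B,A) — P1 and P3 share it — are
BABA sites. Everything else (monomorphic, >2 states, BBAA, private derived
alleles) is uninformative. The statistic

    D = (nABBA - nBABA) / (nABBA + nBABA)

lies in [-1, 1]; under the null of no gene flow between P3 and either of
P1/P2 its expectation is zero. Significance is assessed with a weighted
block jackknife over large genomic windows (5 Mb by default), blocks
weighted by their informative-site counts (delete-m_j estimator of Busing,
Meijer & van der Leeden 1999), with |Z| > 3 conventionally taken as
significant.

Columns containing any N across the four individuals must be excluded before
classification; a 4-row :class:`~consensify.reduce.ReducedAlignment`
guarantees this by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .reduce import ReducedAlignment

BLOCK_SIZE_DEFAULT = 5_000_000

_TRANSITION_PAIRS = {frozenset({0, 2}), frozenset({1, 3})}  # A/G, C/T


@dataclass(frozen=True)
class BlockCounts:
    """ABBA/BABA counts within one jackknife window.

    Blocks tile each scaffold with fixed-width half-open intervals
    [start, start + block_size) anchored at position 1.
    """

    scaffold: str
    start: int  # 1-based start of the window
    n_abba: int
    n_baba: int

    def __post_init__(self) -> None:
        if self.n_abba < 0 or self.n_baba < 0:
            raise ValueError("ABBA/BABA counts must be non-negative")

    @property
    def n_informative(self) -> int:
        return self.n_abba + self.n_baba


@dataclass(frozen=True)
class DResult:
    """Point estimate and jackknife uncertainty of the D statistic."""

    d: float
    n_abba: int
    n_baba: int
    se: float | None
    z: float | None
    n_blocks: int
    degenerate_variance: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.d <= 1.0:
            raise ValueError(f"D must lie in [-1, 1], got {self.d}")


def classify_site(b1: str, b2: str, b3: str, b4: str, remove_transitions: bool = False) -> str | None:
    """Classify one 4-base column as 'ABBA', 'BABA' or None (uninformative).

    Bases must be A/C/G/T (no N). The outgroup base b4 is ancestral; a
    column is informative only when exactly two states are present and the
    derived state is shared by exactly {P2, P3} (ABBA) or {P1, P3} (BABA).
    With ``remove_transitions`` columns whose two states form A/G or C/T are
    dropped.
    """
    bases = (b1, b2, b3, b4)
    if any(b not in "ACGT" for b in bases):
        raise ValueError(f"bases must be A/C/G/T, got {bases}")
    states = set(bases)
    if len(states) != 2:
        return None
    if remove_transitions and frozenset("ACGT".index(b) for b in states) in _TRANSITION_PAIRS:
        return None
    anc = b4
    derived = (states - {anc}).pop()
    pattern = tuple(b == derived for b in (b1, b2, b3))
    if pattern == (False, True, True):
        return "ABBA"
    if pattern == (True, False, True):
        return "BABA"
    return None


def classify_columns(matrix: np.ndarray, remove_transitions: bool = False) -> np.ndarray:
    """Vectorised column classification: +1 for ABBA, -1 for BABA, 0 otherwise.

    ``matrix`` is a (4, n_sites) base-code array ordered (P1, P2, P3, P4).
    """
    if matrix.shape[0] != 4:
        raise ValueError("need exactly 4 individuals ordered (P1, P2, P3, P4)")
    b1, b2, b3, b4 = (matrix[i] for i in range(4))
    abba = (b2 == b3) & (b1 == b4) & (b1 != b2)
    baba = (b1 == b3) & (b2 == b4) & (b1 != b2)
    if remove_transitions:
        # informative columns are biallelic by construction; the two states
        # are {b1, b2} in both patterns
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        transition = ((lo == 0) & (hi == 2)) | ((lo == 1) & (hi == 3))
        abba &= ~transition
        baba &= ~transition
    out = np.zeros(matrix.shape[1], dtype=np.int8)
    out[abba] = 1
    out[baba] = -1
    return out


def block_counts(
    aln: ReducedAlignment,
    block_size: int = BLOCK_SIZE_DEFAULT,
    remove_transitions: bool = False,
) -> list[BlockCounts]:
    """Tally ABBA/BABA sites into fixed-width jackknife blocks.

    The alignment must hold exactly the four individuals in (P1, P2, P3,
    P4) order. Each informative site is assigned to the block containing its
    reference position; blocks with zero informative sites are dropped (they
    carry no jackknife weight).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    signs = classify_columns(aln.matrix, remove_transitions=remove_transitions)
    blocks: dict[tuple[str, int], list[int]] = {}
    informative = np.nonzero(signs)[0]
    for j in informative:
        start = ((int(aln.positions[j]) - 1) // block_size) * block_size + 1
        key = (str(aln.scaffolds[j]), start)
        tallies = blocks.setdefault(key, [0, 0])
        if signs[j] > 0:
            tallies[0] += 1
        else:
            tallies[1] += 1
    return [
        BlockCounts(scaf, start, abba, baba)
        for (scaf, start), (abba, baba) in sorted(blocks.items())
    ]


def d_statistic(blocks: list[BlockCounts]) -> DResult:
    """Point estimate of D from block tallies (no jackknife)."""
    n_abba = sum(b.n_abba for b in blocks)
    n_baba = sum(b.n_baba for b in blocks)
    if n_abba + n_baba == 0:
        raise ValueError("no informative (ABBA/BABA) sites: D is undefined")
    d = (n_abba - n_baba) / (n_abba + n_baba)
    return DResult(d, n_abba, n_baba, se=None, z=None, n_blocks=len(blocks))


def weighted_block_jackknife(blocks: list[BlockCounts]) -> tuple[float, float, bool]:
    """Weighted delete-one-block jackknife (SE, Z, degenerate flag).

    Implements the delete-m_j estimator with block weights equal to their
    informative-site counts: with g blocks, m_j sites in block j, n total
    sites, h_j = n / m_j, whole-sample estimate D and delete-block estimates
    D_{-j},

        D_J  = g D - sum_j (1 - m_j / n) D_{-j}
        var  = (1/g) sum_j (h_j D - (h_j - 1) D_{-j} - D_J)^2 / (h_j - 1)

    Under equal block weights this reduces exactly to the ordinary
    delete-one jackknife. When every D_{-j} equals D the variance is zero:
    SE = 0 is returned with the degenerate flag set (Z is 0 when D == 0,
    infinite otherwise).
    """
    blocks = [b for b in blocks if b.n_informative > 0]
    g = len(blocks)
    if g < 2:
        raise ValueError("jackknife needs at least 2 non-empty blocks")
    abba = np.array([b.n_abba for b in blocks], dtype=np.float64)
    baba = np.array([b.n_baba for b in blocks], dtype=np.float64)
    m = abba + baba
    n = m.sum()
    A, B = abba.sum(), baba.sum()
    d = (A - B) / (A + B)
    denom_minus = (A + B) - m
    if (denom_minus == 0).any():
        raise ValueError("a single block holds all informative sites; jackknife undefined")
    d_minus = ((A - abba) - (B - baba)) / denom_minus
    h = n / m
    d_jack = g * d - ((1.0 - m / n) * d_minus).sum()
    var = float(np.sum((h * d - (h - 1.0) * d_minus - d_jack) ** 2 / (h - 1.0)) / g)
    se = math.sqrt(var)
    if se == 0.0:
        return 0.0, (0.0 if d == 0.0 else math.copysign(math.inf, d)), True
    return se, d / se, False


def d_test(
    aln: ReducedAlignment,
    block_size: int = BLOCK_SIZE_DEFAULT,
    remove_transitions: bool = False,
) -> DResult:
    """Full D-statistic test on a 4-individual reduced alignment."""
    blocks = block_counts(aln, block_size=block_size, remove_transitions=remove_transitions)
    point = d_statistic(blocks)
    usable = [b for b in blocks if b.n_informative > 0]
    if len(usable) >= 2:
        se, z, degenerate = weighted_block_jackknife(blocks)
    else:
        se, z, degenerate = None, None, False
    return DResult(
        point.d, point.n_abba, point.n_baba, se, z, len(usable), degenerate
    )
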