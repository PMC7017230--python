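"""Alignment reduction and distance-based downstream analyses.

Pseudohaploid sequences of several individuals are stacked into a
multi-individual alignment from which every column containing missing data
(N) in *any* individual is excluded, so all individuals are compared over an
identical set of sites. From the reduced alignment: optional variable-site
extraction with transition and singleton filters, pairwise JC69 distances,
neighbour-joining trees and principal-coordinates ordination.

Filters are applied in a fixed order — missing-data exclusion, then
variability, then transition/singleton removal — because singleton counts
depend on which columns survive earlier steps. The distance treatment
intended for subsampled-consensus sequences uses all sites (transitions
included); transition removal exists for comparisons, not as a default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
import skbio
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io_formats import N_CODE, ScaffoldIndex

logger = logging.getLogger(__name__)

_CHAR_TO_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CHAR_TO_CODE[_b] = _i
_PURINES = frozenset({0, 2})  # A, G
_PYRIMIDINES = frozenset({1, 3})  # C, T


@dataclass(frozen=True)
class ReducedAlignment:
    """Individuals x sites base matrix with zero missing data.

    ``matrix`` holds base codes 0..3 (A,C,G,T); ``scaffolds``/``positions``
    record the reference provenance (1-based) of each retained column.
    """

    individuals: tuple[str, ...]
    scaffolds: np.ndarray  # object array of scaffold names, one per column
    positions: np.ndarray  # int array of 1-based positions, one per column
    matrix: np.ndarray  # uint8, shape (n_individuals, n_sites)

    def __post_init__(self) -> None:
        n_ind, n_sites = self.matrix.shape
        if n_ind != len(self.individuals):
            raise ValueError("matrix row count does not match individuals")
        if len(self.scaffolds) != n_sites or len(self.positions) != n_sites:
            raise ValueError("site provenance length does not match matrix width")
        if (self.matrix > 3).any():
            raise ValueError("reduced alignment must not contain N")
        for scaf in np.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {scaf!r}")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> str:
        return "".join("ACGT"[c] for c in self.matrix[:, j])

    def select_columns(self, keep: np.ndarray) -> "ReducedAlignment":
        return ReducedAlignment(
            self.individuals, self.scaffolds[keep], self.positions[keep], self.matrix[:, keep]
        )

    def select_individuals(self, names: Sequence[str]) -> "ReducedAlignment":
        rows = [self.individuals.index(n) for n in names]
        return ReducedAlignment(
            tuple(names), self.scaffolds, self.positions, self.matrix[rows, :]
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise distances with per-pair site counts and saturation flags."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    n_sites: np.ndarray  # sites used per pair
    saturated: np.ndarray  # bool, True where JC69 was undefined (p >= 3/4)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(self.matrix) == 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_skbio(self) -> skbio.DistanceMatrix:
        if self.saturated.any():
            raise ValueError("saturated (infinite) distances cannot be used downstream")
        return skbio.DistanceMatrix(self.matrix, ids=list(self.labels))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes (N and unknowns -> 4)."""
    return _CHAR_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def build_alignment(
    sequences: Mapping[str, Mapping[str, str]],
    index: ScaffoldIndex,
) -> ReducedAlignment:
    """Stack per-individual genome sequences, dropping all columns with N.

    ``sequences`` maps individual -> (scaffold -> base string); every
    individual must cover every indexed scaffold at the indexed length.
    Retains exactly the positions at which no individual has missing data,
    preserving reference order.
    """
    individuals = tuple(sequences)
    if not individuals:
        raise ValueError("no individuals supplied")
    scaf_chunks, pos_chunks, mat_chunks = [], [], []
    for scaffold, length in index:
        rows = []
        for ind in individuals:
            try:
                seq = sequences[ind][scaffold]
            except KeyError:
                raise ValueError(f"individual {ind!r} is missing scaffold {scaffold!r}") from None
            if len(seq) != length:
                raise ValueError(
                    f"individual {ind!r}, scaffold {scaffold!r}: length {len(seq)} != "
                    f"indexed length {length}"
                )
            rows.append(encode_sequence(seq))
        mat = np.vstack(rows)
        keep = (mat != N_CODE).all(axis=0)
        if keep.any():
            mat_chunks.append(mat[:, keep])
            pos_chunks.append(np.nonzero(keep)[0] + 1)
            scaf_chunks.append(np.full(int(keep.sum()), scaffold, dtype=object))
    if not mat_chunks:
        empty = np.empty((len(individuals), 0), dtype=np.uint8)
        return ReducedAlignment(
            individuals, np.empty(0, dtype=object), np.empty(0, dtype=np.int64), empty
        )
    return ReducedAlignment(
        individuals,
        np.concatenate(scaf_chunks),
        np.concatenate(pos_chunks),
        np.hstack(mat_chunks),
    )


def alignment_from_codes(
    codes: Mapping[str, np.ndarray], scaffold: str = "scaf1"
) -> ReducedAlignment:
    """Build a reduced alignment from per-individual base-code arrays.

    Convenience for simulated single-scaffold data: stacks the arrays
    (codes 0..3, 4 = N) and drops every column containing an N, exactly as
    :func:`build_alignment` does for sequence strings.
    """
    individuals = tuple(codes)
    mat = np.vstack([np.asarray(codes[ind], dtype=np.uint8) for ind in individuals])
    keep = (mat != N_CODE).all(axis=0)
    return ReducedAlignment(
        individuals,
        np.full(int(keep.sum()), scaffold, dtype=object),
        np.nonzero(keep)[0] + 1,
        mat[:, keep],
    )


def _column_state_masks(matrix: np.ndarray) -> np.ndarray:
    """(4, n_sites) boolean: which bases occur in each column."""
    return np.stack([(matrix == b).any(axis=0) for b in range(4)])


def variable_sites(
    aln: ReducedAlignment,
    remove_transitions: bool = False,
    remove_singletons: bool = False,
) -> ReducedAlignment:
    """Keep variable columns, optionally dropping transitions and singletons.

    A column is variable when at least two bases are observed. The
    transition filter drops biallelic columns whose two states are A/G or
    C/T. The singleton filter drops columns whose rarest observed state
    occurs in exactly one individual.
    """
    present = _column_state_masks(aln.matrix)
    n_states = present.sum(axis=0)
    keep = n_states >= 2
    if remove_transitions:
        is_ag = present[0] & present[2] & (n_states == 2)
        is_ct = present[1] & present[3] & (n_states == 2)
        keep &= ~(is_ag | is_ct)
    if remove_singletons:
        counts = np.stack([(aln.matrix == b).sum(axis=0) for b in range(4)])
        counts_masked = np.where(present, counts, np.iinfo(np.int64).max)
        keep &= counts_masked.min(axis=0) != 1
    return aln.select_columns(keep)


def p_distance(aln: ReducedAlignment) -> np.ndarray:
    """Pairwise proportion of mismatching sites."""
    if aln.n_sites < 1:
        raise ValueError("alignment has no sites")
    n = len(aln.individuals)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = np.mean(aln.matrix[i] != aln.matrix[j])
    return p


def jc69_distance(aln: ReducedAlignment) -> DistanceMatrix:
    """JC69 evolutionary distances d = -(3/4) ln(1 - (4/3) p).

    Pairs with p >= 3/4 are beyond the model's resolvable range: the distance
    is reported infinite and flagged saturated rather than raising, so one
    bad pair does not kill a run.
    """
    p = p_distance(aln)
    saturated = p >= 0.75
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    d[saturated] = np.inf
    np.fill_diagonal(d, 0.0)
    if saturated.any():
        logger.warning("JC69 saturation (p >= 3/4) for %d pair(s)", saturated.sum() // 2)
    n_sites = np.full(p.shape, aln.n_sites, dtype=np.int64)
    return DistanceMatrix(tuple(aln.individuals), d, n_sites, saturated)


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> tuple[skbio.TreeNode, str]:
    """Saitou–Nei neighbour joining, optionally rooted on the outgroup edge.

    Negative branch lengths produced by NJ on non-additive matrices are
    clamped to zero with the deficit transferred to the adjacent (parent)
    branch, preserving tip-to-root path lengths as far as possible; the
    event is logged. Returns the tree and its Newick text.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    tree = skbio.tree.nj(dm.to_skbio(), neg_as_zero=False)
    _clamp_negative_branches(tree)
    if outgroup is not None:
        tip = tree.find(outgroup)
        tree = tree.root_at(tip, above=True, reset=True)
    newick = str(tree).strip()
    return tree, newick


def _clamp_negative_branches(tree: skbio.TreeNode) -> None:
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            parent = node.parent
            if parent is not None and parent.length is not None:
                parent.length += -deficit
            logger.warning("negative NJ branch (%g) clamped to zero", deficit)


def pcoa(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres -1/2 D^2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues. Returns (coordinates,
    eigenvalues): eigenvalues in decreasing order (negative ones reported
    but carrying no coordinate axis), coordinates restricted to the
    positive-eigenvalue axes.
    """
    if len(dm.labels) < 2:
        raise ValueError("PCoA requires at least 2 taxa")
    res = _skbio_pcoa(dm.to_skbio(), method="eigh")
    eigvals = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    positive = eigvals > 1e-12 * max(eigvals.max(initial=0.0), 1.0)
    return coords[:, positive], eigvals


def write_distance_tsv(dm: DistanceMatrix, sink: str | IO[str]) -> None:
    """Write a labelled square distance matrix as TSV."""
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for label, row in zip(dm.labels, dm.matrix):
            fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    finally:
        if own:
            fh.close()


def read_distance_tsv(source: str | IO[str]) -> DistanceMatrix:
    """Read a labelled square distance matrix TSV (as written above)."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        labels = tuple(header[1:])
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in fields[1:]])
    finally:
        if own:
            fh.close()
    mat = np.asarray(rows)
    sat = ~np.isfinite(mat)
    n_sites = np.zeros(mat.shape, dtype=np.int64)  # unknown after round-trip
    return DistanceMatrix(labels, mat, n_sites, sat)
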