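"""Count-level read-stack and quartet simulators.

Everything the calling rule consumes is a per-site (A, C, G, T) read-count
vector, so ancient-DNA-like data can be emulated directly at the count
level: per site the depth is Poisson in the mean coverage, and each read's
observed base is drawn from the single-read error model
(:mod:`consensify.error_model`) given the site's diploid genotype. Cytosine
deamination is modelled as a uniform per-read excess probability ``delta``
that a read over a true C reports T (and over a G reports A — the
blunt-end-repair complement), rather than a position-in-read decay profile:
the caller never sees read coordinates, and the qualitative artefact (an
asymmetric C-to-T excess) is what matters downstream.

The quartet simulator produces four individuals related as
(((P1, P2), P3), P4): an ancestral sequence is mutated independently down
each branch (per-site substitution probability 1 - exp(-b) for branch length
b in expected substitutions/site, new base uniform over the other three),
admixture from P3 into P2 replaces a fraction ``alpha`` of P2's sites with
P3's state after lineage mutation, and per-individual read stacks are then
simulated — optionally with *differential* error (elevated Pg/delta in one
individual) to reproduce the artefact regime where error asymmetry mimics
gene flow. ABBA/BABA-informative sites arise from homoplasy and error, not
from incomplete lineage sorting: this is deliberately not a coalescent
simulation.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io_formats import SiteCounts, write_counts


@dataclass(frozen=True)
class StackSimSpec:
    """One individual's genome and sequencing conditions.

    ``heterozygosity`` is the fraction of sites with two distinct alleles;
    ``mean_coverage`` the Poisson mean read depth; ``pg`` the global
    per-read error rate (the simulated-palaeo treatments of the source
    domain use 0.001, i.e. 0.1%); ``delta`` the per-read deamination-like
    C->T / G->A excess probability.
    """

    length: int = 100_000
    heterozygosity: float = 0.001
    mean_coverage: float = 3.0
    pg: float = 0.001
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name in ("heterozygosity", "pg", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass(frozen=True)
class QuartetSimSpec:
    """Four-taxon scenario (((P1, P2), P3), P4) with optional admixture.

    Branch lengths are expected substitutions/site: ``b_p1``/``b_p2`` the
    terminal branches of the sister pair, ``b_anc12`` the internal branch to
    their common ancestor, ``b_p3`` and ``b_outgroup`` the branches to P3
    and P4 from the root. ``alpha`` is the P3->P2 admixture fraction.
    ``stack`` gives the shared sequencing conditions; ``overrides`` replaces
    them per individual (e.g. elevated error in P2).
    """

    length: int = 1_000_000
    b_p1: float = 0.15
    b_p2: float = 0.15
    b_anc12: float = 0.05
    b_p3: float = 0.2
    b_outgroup: float = 0.3
    alpha: float = 0.0
    stack: StackSimSpec = field(default_factory=StackSimSpec)
    overrides: Mapping[str, StackSimSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        for b in (self.b_p1, self.b_p2, self.b_anc12, self.b_p3, self.b_outgroup):
            if b < 0:
                raise ValueError("branch lengths must be >= 0")

    def stack_for(self, individual: str) -> StackSimSpec:
        base = self.overrides.get(individual, self.stack)
        return replace(base, length=self.length)


@dataclass(frozen=True)
class Truth:
    """Ground truth for one simulated individual."""

    reference: np.ndarray  # base codes 0..3
    genotypes: np.ndarray  # (length, 2) base codes; equal columns = homozygous

    @property
    def heterozygous(self) -> np.ndarray:
        return self.genotypes[:, 0] != self.genotypes[:, 1]


def simulate_truth(spec: StackSimSpec, rng: np.random.Generator | int | None = None) -> Truth:
    """Draw a reference sequence and per-site diploid genotypes.

    Homozygous sites carry the reference base on both chromosomes; a
    fraction ``heterozygosity`` of sites carries a second, uniformly chosen
    alternative allele.
    """
    rng = _as_rng(rng)
    ref = rng.integers(0, 4, size=spec.length)
    genotypes = np.stack([ref, ref], axis=1)
    het = rng.random(spec.length) < spec.heterozygosity
    alt = (ref + rng.integers(1, 4, size=spec.length)) % 4
    genotypes[het, 1] = alt[het]
    return Truth(reference=ref, genotypes=genotypes)


def _read_prob_matrix(pg: float, delta: float) -> np.ndarray:
    """(4, 4) matrix: row = true allele, column = observed base probability."""
    pe = pg / 4.0
    v = np.full((4, 4), pe)
    np.fill_diagonal(v, (1.0 - pg) + pe)
    if delta > 0.0:
        # deamination applied on top of the error model: with prob delta a
        # read over C reports T, over G reports A
        v[1] = (1.0 - delta) * v[1]
        v[1, 3] += delta
        v[2] = (1.0 - delta) * v[2]
        v[2, 0] += delta
    return v


def simulate_counts(
    truth: Truth, spec: StackSimSpec, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Simulate per-site (A, C, G, T) read counts for one individual.

    Depth is Poisson(``mean_coverage``); each read draws its source allele
    uniformly from the two chromosomes and its observed base from the
    single-read error model with the deamination excess applied. Returns an
    (length, 4) integer array; sites with zero depth have all-zero rows (and
    are omitted when written to pos/counts files).
    """
    rng = _as_rng(rng)
    v = _read_prob_matrix(spec.pg, spec.delta)
    probs = 0.5 * (v[truth.genotypes[:, 0]] + v[truth.genotypes[:, 1]])
    depth = rng.poisson(spec.mean_coverage, size=len(probs))
    return rng.multinomial(depth, probs)


def counts_to_sites(counts: np.ndarray, scaffold: str = "scaf1") -> list[SiteCounts]:
    """Convert a counts array to a SiteCounts stream, dropping zero-depth rows."""
    covered = np.nonzero(counts.sum(axis=1) > 0)[0]
    return [
        SiteCounts(scaffold, int(i) + 1, tuple(int(c) for c in counts[i]))
        for i in covered
    ]


def write_counts_files(
    counts: np.ndarray, pos_path, counts_path, scaffold: str = "scaf1"
) -> None:
    """Write a simulated counts array in the paired pos/counts dialect."""
    write_counts(counts_to_sites(counts, scaffold), pos_path, counts_path)


INDIVIDUALS = ("P1", "P2", "P3", "P4")


@dataclass(frozen=True)
class QuartetData:
    """Simulated quartet: true haploid sequences, counts, and the truth log."""

    spec: QuartetSimSpec
    reference: np.ndarray
    haplotypes: dict[str, np.ndarray]  # lineage base codes per individual
    counts: dict[str, np.ndarray]  # (length, 4) per individual
    admixed_sites: np.ndarray  # indices where P2 took P3's state

    def true_sequences(self) -> dict[str, str]:
        return {
            name: "".join("ACGT"[c] for c in haplo)
            for name, haplo in self.haplotypes.items()
        }


def _mutate(seq: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    if branch_length == 0.0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < -np.expm1(-branch_length)
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def simulate_quartet(
    spec: QuartetSimSpec, rng: np.random.Generator | int | None = None
) -> QuartetData:
    """Simulate four related individuals' read stacks.

    Individuals are treated as homozygous for their lineage state (the
    quartet machinery probes D-statistic behaviour, not within-individual
    diversity). Admixture replaces a Bernoulli(``alpha``) subset of P2's
    sites with P3's state after lineage mutation.
    """
    rng = _as_rng(rng)
    ancestral = rng.integers(0, 4, size=spec.length)
    p4 = _mutate(ancestral, spec.b_outgroup, rng)
    anc3 = ancestral  # root to (P1,P2,P3) ancestor collapsed into branches
    p3 = _mutate(anc3, spec.b_p3, rng)
    anc12 = _mutate(anc3, spec.b_anc12, rng)
    p1 = _mutate(anc12, spec.b_p1, rng)
    p2 = _mutate(anc12, spec.b_p2, rng)
    if spec.alpha > 0.0:
        admixed = np.nonzero(rng.random(spec.length) < spec.alpha)[0]
        p2[admixed] = p3[admixed]
    else:
        admixed = np.empty(0, dtype=np.int64)

    haplotypes = dict(zip(INDIVIDUALS, (p1, p2, p3, p4)))
    counts = {}
    for name, haplo in haplotypes.items():
        stack = spec.stack_for(name)
        truth = Truth(reference=ancestral, genotypes=np.stack([haplo, haplo], axis=1))
        counts[name] = simulate_counts(truth, stack, rng)
    return QuartetData(spec, ancestral, haplotypes, counts, admixed)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
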