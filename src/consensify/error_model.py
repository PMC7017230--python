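"""Analytic error model for the 2-of-3 subsampled-consensus rule.

Sequencing error is modelled Jukes–Cantor style: base composition is equal,
all error types are equiprobable, and a single global error rate Pg
summarises the machine. The probability that an error reports any particular
base is then Pe = Pg/4 (an error may re-report the original base). For a
single read over a homozygous site the probability of observing the correct
base is

    Phom = (1 - Pg) + Pe,

and over a heterozygous site a truth-consistent base (either allele) is seen
with

    Phet = (1 - Pg) + 2 Pe.

Sampling three reads at one position has 4^3 = 64 ordered outcomes; summing
outcome probabilities under the 2-of-3 agreement rule gives the chance of a
correct call, of missing data (N), and of an incorrect call. Standard
pseudohaploidisation (one random read per site) serves as the comparator: its
error is 1 - Phom (resp. 1 - Phet) and is linear in Pg, whereas the
subsampled-consensus error is quadratic in Pe at leading order — hence the
large fold-reductions at realistic error rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

GENOTYPES = ("homozygous", "heterozygous")


@dataclass(frozen=True)
class ErrorModelSpec:
    """Global error rate and genotype class for one model evaluation."""

    pg: float
    genotype: str = "homozygous"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pg < 1.0:
            raise ValueError(f"Pg must be in [0, 1), got {self.pg}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")

    @property
    def pe(self) -> float:
        """Per-base error probability Pe = Pg/4."""
        return self.pg / 4.0


@dataclass(frozen=True)
class OutcomeDistribution:
    """Probabilities of {correct call, no call (N), incorrect call}."""

    p_correct: float
    p_nocall: float
    p_error: float

    def __post_init__(self) -> None:
        total = self.p_correct + self.p_nocall + self.p_error
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"outcome probabilities sum to {total}, not 1")
        for p in (self.p_correct, self.p_nocall, self.p_error):
            if not -1e-15 <= p <= 1 + 1e-15:
                raise ValueError(f"probability {p} outside [0, 1]")

    @property
    def p_error_per_call(self) -> float:
        """Error probability conditioned on a call being made."""
        called = self.p_correct + self.p_error
        if called == 0.0:
            raise ZeroDivisionError("no calls are ever made")
        return self.p_error / called


def per_read_base_probs(spec: ErrorModelSpec) -> np.ndarray:
    """Single-read observation probabilities over the four bases.

    The returned vector is ordered truth-first: for a homozygous genotype,
    index 0 is the true base and 1–3 the three wrong bases; for a
    heterozygous genotype, indices 0–1 are the two alleles (drawn with equal
    probability) and 2–3 the two wrong bases.
    """
    pg, pe = spec.pg, spec.pe
    if spec.genotype == "homozygous":
        return np.array([(1 - pg) + pe, pe, pe, pe])
    allele = 0.5 * (1 - pg) + pe  # read drawn from either allele, then error
    return np.array([allele, allele, pe, pe])


def outcome_probs_consensify(spec: ErrorModelSpec) -> OutcomeDistribution:
    """Exact 64-outcome enumeration of the 2-of-3 rule under the model.

    Every ordered triple of observed bases is enumerated; the call is the
    base appearing at least twice (all-distinct triples give N). For a
    heterozygous genotype a call matching either allele counts as correct.
    """
    probs = per_read_base_probs(spec)
    truth = {0} if spec.genotype == "homozygous" else {0, 1}
    p_correct = p_nocall = p_error = 0.0
    for triple in itertools.product(range(4), repeat=3):
        p = probs[triple[0]] * probs[triple[1]] * probs[triple[2]]
        call = _majority(triple)
        if call is None:
            p_nocall += p
        elif call in truth:
            p_correct += p
        else:
            p_error += p
    return OutcomeDistribution(p_correct, p_nocall, p_error)


def _majority(triple: tuple[int, ...]) -> int | None:
    for base in set(triple):
        if triple.count(base) >= 2:
            return base
    return None


def error_rate_single_read(spec: ErrorModelSpec) -> float:
    """Per-site error of standard pseudohaploidisation (one random read)."""
    pg, pe = spec.pg, spec.pe
    if spec.genotype == "homozygous":
        return 1.0 - ((1 - pg) + pe)
    return 1.0 - ((1 - pg) + 2 * pe)


def fold_reduction(pg: float, genotype: str = "homozygous", per_called_base: bool = False) -> float:
    """Single-read-to-consensus error-rate ratio at global error rate Pg.

    With ``per_called_base=False`` (default) the ratio is between per-site
    error rates; it is then *exactly* equal for homozygous and heterozygous
    genotypes (both reduce to Pg / (4E) with E = 3 Pe^2 (1-Pe) + Pe^3), and
    that equality is asserted against the enumeration. With
    ``per_called_base=True`` the consensus error is conditioned on a call
    being made (the consensus can emit N, a single read cannot); at
    realistic Pg the two conventions agree to well within two significant
    figures.
    """
    if not 0.0 < pg < 1.0:
        raise ValueError(f"fold reduction is undefined at Pg={pg}; need 0 < Pg < 1")
    ratios = {}
    for g in GENOTYPES:
        spec = ErrorModelSpec(pg, g)
        outcome = outcome_probs_consensify(spec)
        cons = outcome.p_error_per_call if per_called_base else outcome.p_error
        ratios[g] = error_rate_single_read(spec) / cons
    if not per_called_base:
        # model prediction, checked rather than assumed
        if not math.isclose(ratios["homozygous"], ratios["heterozygous"], rel_tol=1e-9):
            raise AssertionError(
                f"per-site fold-reduction differs between genotypes: {ratios}"
            )
    return ratios[genotype]


def minor_allele_call_prob(p: float) -> float:
    """Probability the 2-of-3 consensus call equals an allele at stack frequency p.

    Models a large read stack: each of the 3 sampled reads carries the allele
    independently with probability p, so the call probability is
    3 p^2 (1-p) + p^3 (at least two of three). The single-read comparator is
    simply p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    return 3 * p**2 * (1 - p) + p**3


def minor_allele_call_prob_finite(n_allele: int, depth: int, k: int = 3, f: int = 2) -> float:
    """Finite-stack variant: exact call probability for an allele seen
    ``n_allele`` times in a biallelic stack of ``depth`` reads, when ``k``
    reads are subsampled without replacement and ``f`` must agree.

    Converges to :func:`minor_allele_call_prob` as the stack grows; useful as
    a cross-check against the caller's subsampling.
    """
    if not 0 <= n_allele <= depth:
        raise ValueError("need 0 <= n_allele <= depth")
    if depth < k:
        k = depth
    rv = hypergeom(depth, n_allele, k)
    return float(sum(rv.pmf(x) for x in range(f, k + 1)))
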