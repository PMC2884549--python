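"""Closed-form Mendelian expectations for a single transposon insertion locus.

A diploid locus carries 0, 1, or 2 copies of a DNA-transposon insertion
(absent, heterozygous, homozygous).  Under clonal reproduction the genotype
is transmitted unchanged; under selfing, independent assortment gives a
heterozygote a 1/4 chance of segregating away entirely and a 1/4 chance of
fixing as a homozygote; outcrossing to an unoccupied partner loses the
insertion half the time.  These exact probabilities are the analytic
backbone against which the forward simulator and the rate estimators are
validated.

All loci are treated as unlinked and assorting independently; linkage and
crossover are deliberately not modelled.
"""

from __future__ import annotations

from enum import IntEnum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Genotype",
    "OffspringDistribution",
    "selfing_offspring_distribution",
    "loss_probability",
    "state_after_k_selfings",
    "expected_segregational_losses",
]

#: Tolerance for probability-sum checks on the exact Mendelian lattice.
PROB_TOL = 1e-12


class Genotype(IntEnum):
    """Copy number of one insertion locus on a pair of homologues."""

    ABSENT = 0
    HET = 1
    HOM = 2


class OffspringDistribution(NamedTuple):
    """Probabilities that a single offspring carries 0, 1, or 2 copies."""

    p_absent: float
    p_het: float
    p_hom: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


# Selfing transition matrix over genotypes (rows: parent 0/1/2).
# A selfed heterozygote (Aa x Aa) yields aa/Aa/AA at 1/4, 1/2, 1/4;
# 0 and 2 copies are absorbing.
_SELFING_T = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.25, 0.5, 0.25],
        [0.0, 0.0, 1.0],
    ]
)

LOSS_MODES = ("clonal", "selfing", "outcross_to_unoccupied")


def _as_genotype(g: int | Genotype) -> Genotype:
    try:
        return Genotype(int(g))
    except ValueError:
        raise ValueError(f"genotype must be 0, 1, or 2 copies; got {g!r}") from None


def selfing_offspring_distribution(g: int | Genotype) -> OffspringDistribution:
    """Exact offspring genotype distribution for one selfed diploid locus.

    Parameters
    ----------
    g
        Parental copy number (0, 1, or 2).

    Returns
    -------
    OffspringDistribution
        ``(p_absent, p_het, p_hom)``; for a heterozygote this is
        ``(0.25, 0.50, 0.25)`` by independent assortment.
    """
    row = _SELFING_T[_as_genotype(g)]
    return OffspringDistribution(*row)


def loss_probability(g: int | Genotype, mode: str) -> float:
    """Probability that one offspring carries zero copies at this locus.

    Only meiotic segregation is considered; excision and other local-loss
    mechanisms are handled by the simulator.  ``mode`` is one of
    ``"clonal"`` (mitotic transmission), ``"selfing"``, or
    ``"outcross_to_unoccupied"`` (mating with a 0-copy partner, the case
    relevant to loss predictions).
    """
    geno = _as_genotype(g)
    if mode == "clonal":
        return 1.0 if geno == Genotype.ABSENT else 0.0
    if mode == "selfing":
        return float(selfing_offspring_distribution(geno).p_absent)
    if mode == "outcross_to_unoccupied":
        # Offspring copy number = parental gamete contribution (partner
        # contributes none).  P(gamete empty) = 1, 1/2, 0 for 0/1/2 copies.
        return (1.0, 0.5, 0.0)[geno]
    raise ValueError(f"unknown mode {mode!r}; expected one of {LOSS_MODES}")


def state_after_k_selfings(g: int | Genotype, k: int) -> OffspringDistribution:
    """Genotype distribution after ``k`` successive selfing bouts.

    Iterates the selfing Markov chain; 0 and 2 copies are absorbing, and a
    heterozygote's probability of remaining heterozygous halves each bout:
    ``p_het = (1/2)**k`` with the remainder split equally between loss and
    fixation.  ``k = 0`` is the identity.
    """
    geno = _as_genotype(g)
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError(f"k must be an integer, got {k!r}")
    if k < 0:
        raise ValueError(f"number of selfing bouts must be >= 0, got {k}")
    start = np.zeros(3)
    start[geno] = 1.0
    row = start @ np.linalg.matrix_power(_SELFING_T, int(k))
    return OffspringDistribution(*row)


def expected_segregational_losses(n_lineages: int, p_loss: float) -> float:
    """Expected number of lineages losing a locus by segregation alone.

    With ``n_lineages`` independent selfed lines and per-line loss
    probability ``p_loss``, the binomial expectation is simply
    ``n_lineages * p_loss`` — e.g. 45 lines at the heterozygote loss
    probability 0.25 gives 11.25 expected losses.
    """
    if n_lineages < 0:
        raise ValueError(f"n_lineages must be >= 0, got {n_lineages}")
    if not 0.0 <= p_loss <= 1.0:
        raise ValueError(f"p_loss must be in [0, 1], got {p_loss}")
    return float(n_lineages) * float(p_loss)
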