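"""Closed-form genetics arithmetic for selfing TILLING populations.

These calculators cover the back-of-envelope design numbers a TILLING
screen rests on: how selfing partitions induced mutations into homozygous,
heterozygous and segregated-away fractions; how a mutation rate observed in
a late generation converts to the canonical M2 rate; how an incomplete
polyploid reference dilutes observed allele frequencies; and how large a
population must be screened to find a loss-of-function allele of a typical
gene with given confidence.

Generation indexing: ``g`` counts rounds of self-fertilisation since the
mutagenised M1 generation, so M2 corresponds to ``g=1`` and M5 to ``g=4``.
Every induced mutation starts heterozygous in M1; each selfing round halves
the heterozygous fraction, splitting the other half equally between
fixation and loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GeneArchitecture",
    "RateSpec",
    "zygosity_after_selfing",
    "retained_fraction",
    "convert_rate",
    "dilution_af",
    "null_probability",
    "lines_for_confidence",
    "targeted_space",
]


@dataclass(frozen=True)
class GeneArchitecture:
    """Averaged architecture of a target gene.

    Defaults describe the average bread-wheat gene: ~1,100 bp of coding
    sequence interrupted by 2.25 introns, ~5% of coding substitutions
    creating a premature stop, and two essential G residues (donor GT,
    acceptor AG) per intron.
    """

    cds_len: float = 1100.0
    introns_per_gene: float = 2.25
    stop_fraction: float = 0.05
    essential_g_per_intron: float = 2.0

    def __post_init__(self) -> None:
        for name in ("cds_len", "introns_per_gene", "stop_fraction", "essential_g_per_intron"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RateSpec:
    """A mutation rate (per Mb of sequence) tied to a selfing generation."""

    rate_per_mb: float
    generation: int

    def __post_init__(self) -> None:
        if self.rate_per_mb < 0:
            raise ValueError("rate_per_mb must be non-negative")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")


def zygosity_after_selfing(g: int) -> tuple[float, float, float]:
    """Fate of a mutation after ``g`` selfing rounds since M1.

    Returns ``(hom, het, lost)`` fractions. A mutation heterozygous in M1
    stays heterozygous with probability ``(1/2)**g``; the remainder splits
    evenly between fixation (hom) and segregating away (lost).

    At g=4 (M5) the homozygous share among *retained* mutations is
    15/17 ~= 88%, with 2/17 ~= 12% heterozygous.
    """
    if g < 0 or int(g) != g:
        raise ValueError("selfing rounds g must be a non-negative integer")
    het = 0.5 ** g
    hom = (1.0 - het) / 2.0
    return hom, het, hom


def retained_fraction(g: int) -> float:
    """Fraction of induced mutations still present after ``g`` selfings.

    Closed form ``(1 + 2**-g) / 2``: g=0 -> 1, g=4 -> 17/32, limit 1/2.
    """
    hom, het, _ = zygosity_after_selfing(g)
    return hom + het


def convert_rate(rate: RateSpec, target_generation: int) -> float:
    """Convert a per-Mb mutation rate between selfing generations.

    A rate observed in generation ``s`` reflects only the retained
    mutations, so the rate at another generation ``t`` is
    ``rate * retained_fraction(t) / retained_fraction(s)``.
    E.g. 24/Mb observed at M5 (g=4) converts to 33.88 ~ 34/Mb at M2 (g=1).
    """
    if target_generation < 0:
        raise ValueError("target generation must be >= 0")
    return rate.rate_per_mb * retained_fraction(target_generation) / retained_fraction(rate.generation)


def dilution_af(
    true_af: float,
    copies_in_ref: int,
    copies_total: int = 3,
    equal_coverage: bool = True,
) -> float:
    """Expected observed allele frequency with an incomplete reference.

    When homoeologous copies are missing from the mapping reference, their
    wild-type reads mis-map onto the retained copy carrying the mutation
    (worst case: all of them), diluting the variant allele frequency to
    ``true_af / (1 + copies_missing)`` under equal per-copy coverage.

    A heterozygous mutation (true AF 0.5) with one of three homoeologues in
    the reference is observed at 0.5/3 = 0.1667 (0.16 truncated to 2 dp).
    """
    if not 1 <= copies_in_ref <= copies_total:
        raise ValueError("copies_in_ref must be between 1 and copies_total")
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must lie in [0, 1]")
    if not equal_coverage:
        raise NotImplementedError("only the equal-coverage model is implemented")
    missing = copies_total - copies_in_ref
    return true_af / (1.0 + missing)


def null_probability(arch: GeneArchitecture, rate_per_mb: float) -> float:
    """Probability that one line carries a null mutation in a given gene.

    Null (loss-of-function) target space per gene = coding sites whose
    mutation creates a stop (``cds_len * stop_fraction``) plus the essential
    splice G residues (``introns_per_gene * essential_g_per_intron``),
    multiplied by the per-bp mutation rate.

    With the default architecture and 34 mutations/Mb this is
    34e-6 * (55 + 4.5) = 2.02e-3.
    """
    if rate_per_mb <= 0:
        raise ValueError("rate_per_mb must be positive")
    null_sites = arch.cds_len * arch.stop_fraction + arch.introns_per_gene * arch.essential_g_per_intron
    return rate_per_mb * 1e-6 * null_sites


def lines_for_confidence(p: float, confidence: float = 0.95) -> tuple[float, int]:
    """Population size needed to find >=1 null mutation with given confidence.

    Solves ``1 - (1-p)**n = confidence`` for n; returns the raw value
    ``ln(1-confidence)/ln(1-p)`` and the same rounded up to a whole hundred
    lines, the granularity such populations are planned at
    (p = 2.02e-3 at 95% -> raw ~1479 -> ~1,500 lines).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    raw = math.log(1.0 - confidence) / math.log(1.0 - p)
    rounded = int(math.ceil(raw / 100.0) * 100)
    return raw, rounded


def targeted_space(cds_mb: float, homoeologues: int = 3) -> float:
    """Genomic megabases targeted when every CDS has ``homoeologues`` copies.

    1.9 Mb of coding design space targets 5.7 Mb in a hexaploid.
    """
    if cds_mb <= 0 or homoeologues <= 0:
        raise ValueError("inputs must be positive")
    return cds_mb * homoeologues
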