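"""Functional classification of point mutations against gene models.

A deliberately small consequence predictor for single-transcript gene
models: every substitution gets exactly one category — intergenic, intron,
splice donor/acceptor (the essential G of the GT donor or AG acceptor),
5'/3' UTR, start codon gained in the 5' UTR, and within the CDS the
codon-level verdicts (stop gained, start lost, synonymous, missense).
Strand-aware throughout; codons are read on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .genomes import GeneModel, STOP_CODONS, revcomp

__all__ = ["CATEGORIES", "EffectCall", "annotate", "effect_summary", "TRUNCATION_CATEGORIES"]

CATEGORIES = [
    "5_prime_UTR",
    "start_gained_5_prime_UTR",
    "stop_gained",
    "missense",
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "synonymous",
    "intron",
    "3_prime_UTR",
    "intergenic",
]

TRUNCATION_CATEGORIES = {"stop_gained", "splice_donor", "splice_acceptor"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_COMP = str.maketrans("ACGT", "TGCA")


def _translate(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class EffectCall:
    """Predicted consequence of one substitution."""

    contig_id: str
    pos: int
    ref_base: str
    alt_base: str
    gene_id: str | None
    category: str
    codon_old: str | None = None
    codon_new: str | None = None
    aa_old: str | None = None
    aa_new: str | None = None


def annotate(
    contig_id: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    models: Sequence[GeneModel],
    sequences: Mapping[str, str],
) -> EffectCall:
    """Classify a substitution at ``pos`` (0-based, forward-strand bases).

    ``models`` may span many contigs; the first gene (by coordinate) whose
    exon-chain span contains the position wins.  Raises if the stated ref
    base disagrees with the sequence.
    """
    seq = sequences[contig_id]
    if seq[pos] != ref_base:
        raise ValueError(f"ref base mismatch at {contig_id}:{pos + 1}: "
                         f"sequence has {seq[pos]}, mutation says {ref_base}")
    genes = sorted((m for m in models if m.contig_id == contig_id and m.span[0] <= pos < m.span[1]),
                   key=lambda m: m.span)
    if not genes:
        return EffectCall(contig_id, pos, ref_base, alt_base, None, "intergenic")
    model = genes[0]
    model.validate(seq)

    # intron?
    for ia, ib in model.introns():
        if ia <= pos < ib:
            if model.strand == "+":
                donor_g, acceptor_g = ia, ib - 1
            else:
                donor_g, acceptor_g = ib - 1, ia
            if pos == donor_g:
                return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, "splice_donor")
            if pos == acceptor_g:
                return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, "splice_acceptor")
            return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, "intron")

    spos = model.contig_to_spliced(pos)
    assert spos is not None
    # bases on the coding strand
    if model.strand == "+":
        old_b, new_b = ref_base, alt_base
    else:
        old_b, new_b = ref_base.translate(_COMP), alt_base.translate(_COMP)
    cds_a, cds_b = model.cds_span
    spliced = model.spliced_sequence(seq)

    if spos < cds_a:
        utr = spliced[:cds_a]
        mutated = utr[:spos] + new_b + utr[spos + 1:]
        for w in range(max(0, spos - 2), min(len(utr) - 2, spos) + 1):
            if mutated[w:w + 3] == "ATG" and utr[w:w + 3] != "ATG":
                return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id,
                                  "start_gained_5_prime_UTR")
        return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, "5_prime_UTR")
    if spos >= cds_b:
        return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, "3_prime_UTR")

    cds_off = spos - cds_a
    ci, cj = divmod(cds_off, 3)
    codon_old = spliced[cds_a + 3 * ci: cds_a + 3 * ci + 3]
    codon_new = codon_old[:cj] + new_b + codon_old[cj + 1:]
    aa_old, aa_new = _translate(codon_old), _translate(codon_new)
    if ci == 0 and codon_old == "ATG" and codon_new != "ATG":
        cat = "start_lost"
    elif aa_new == "*" and aa_old != "*":
        cat = "stop_gained"
    elif aa_new == aa_old:
        cat = "synonymous"
    else:
        # includes loss of the annotated stop, which the category set folds
        # into missense
        cat = "missense"
    return EffectCall(contig_id, pos, ref_base, alt_base, model.gene_id, cat,
                      codon_old, codon_new, aa_old, aa_new)


def effect_summary(effects: Iterable[EffectCall]) -> tuple[pd.DataFrame, int]:
    """Tabulate counts and percentages per category.

    Returns (table, truncation_count) where truncations = stop gained +
    splice donor + splice acceptor — the loss-of-function class.
    Percentages are of the total, to one decimal.
    """
    effects = list(effects)
    total = len(effects)
    counts = {c: 0 for c in CATEGORIES}
    for e in effects:
        counts[e.category] += 1
    rows = [(c, n, round(100.0 * n / total, 1) if total else 0.0) for c, n in counts.items()]
    rows.append(("total", total, 100.0 if total else 0.0))
    table = pd.DataFrame(rows, columns=["category", "count", "percent"])
    truncations = sum(counts[c] for c in TRUNCATION_CATEGORIES)
    return table, truncations
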