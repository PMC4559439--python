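"""Effect classification: codon cases, splice-site Gs, strand symmetry and a
full-CDS retranslation oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from polytill import effects, genomes
from polytill.effects import annotate, effect_summary
from polytill.genomes import GeneModel, SimConfig, revcomp, simulate_gene_model


def spliced_to_contig(model):
    m = []
    for a, b in model.exons:
        m.extend(range(a, b))
    return m[::-1] if model.strand == "-" else m


def coding_to_forward(model, base):
    return base if model.strand == "+" else revcomp(base)


def mutate_at_spliced(model, seq, spos, new_coding_base):
    """Contig position + forward-strand ref/alt for a coding-strand change."""
    cmap = spliced_to_contig(model)
    pos = cmap[spos]
    ref = seq[pos]
    alt = coding_to_forward(model, new_coding_base)
    return pos, ref, alt


def brute_force_category(model, seq, pos, alt):
    """Independent reclassification by rebuilding the gene around the change.

    Re-extracts UTRs/CDS from the mutated contig and retranslates the whole
    CDS; splice calls come from direct inspection of the invariant G
    positions of each intron.
    """
    a, b = model.span
    if not (a <= pos < b):
        return "intergenic"
    for ia, ib in model.introns():
        if ia <= pos < ib:
            donor_g = ia if model.strand == "+" else ib - 1
            acceptor_g = ib - 1 if model.strand == "+" else ia
            if pos == donor_g:
                return "splice_donor"
            if pos == acceptor_g:
                return "splice_acceptor"
            return "intron"
    mutated = seq[:pos] + alt + seq[pos + 1:]
    old_spliced = model.spliced_sequence(seq)
    new_spliced = model.spliced_sequence(mutated)
    ca, cb = model.cds_span
    spos = next(i for i in range(len(old_spliced))
                if old_spliced[i] != new_spliced[i])
    if spos < ca:
        utr_old, utr_new = old_spliced[:ca], new_spliced[:ca]
        atg_old = {i for i in range(len(utr_old) - 2) if utr_old[i:i + 3] == "ATG"}
        atg_new = {i for i in range(len(utr_new) - 2) if utr_new[i:i + 3] == "ATG"}
        return "start_gained_5_prime_UTR" if atg_new - atg_old else "5_prime_UTR"
    if spos >= cb:
        return "3_prime_UTR"
    old_prot = str(Seq(old_spliced[ca:cb]).translate())
    new_prot = str(Seq(new_spliced[ca:cb]).translate())
    if new_spliced[ca:ca + 3] != "ATG" and old_spliced[ca:ca + 3] == "ATG":
        return "start_lost"
    ci = (spos - ca) // 3
    if new_prot[ci] == "*" and old_prot[ci] != "*":
        return "stop_gained"
    if new_prot == old_prot:
        return "synonymous"
    return "missense"


@pytest.fixture(scope="module")
def gene_plus():
    models, contigs = simulate_gene_model(
        1, rng_seed=71,
        config=SimConfig(exon_len_dist={"kind": "fixed", "values": [300, 300, 300]},
                         intron_len_dist={"kind": "fixed", "values": [150, 150]},
                         strands="+"))
    m = models[0]
    return m, contigs[m.contig_id]


class TestCodonCases:
    def find_codon(self, model, seq, predicate):
        ca, cb = model.cds_span
        spliced = model.spliced_sequence(seq)
        for ci in range((cb - ca) // 3):
            codon = spliced[ca + 3 * ci: ca + 3 * ci + 3]
            hit = predicate(ci, codon)
            if hit is not None:
                cj, new_base = hit
                return ca + 3 * ci + cj, codon, cj, new_base
        raise AssertionError("no codon matching predicate in fixture gene")

    def test_tgg_to_tga_is_stop_gained(self, gene_plus):
        m, seq = gene_plus
        spos, codon, cj, nb = self.find_codon(
            m, seq, lambda ci, c: (2, "A") if (c == "TGG" and ci > 0) else None)
        pos, ref, alt = mutate_at_spliced(m, seq, spos, nb)
        e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
        assert e.category == "stop_gained"
        assert (e.codon_old, e.codon_new) == ("TGG", "TGA")

    def test_missense_g_to_a(self, gene_plus):
        m, seq = gene_plus
        spos, codon, cj, nb = self.find_codon(
            m, seq, lambda ci, c: (1, "A") if (c == "GGT" and ci > 0) else None)
        pos, ref, alt = mutate_at_spliced(m, seq, spos, nb)
        e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
        assert e.category == "missense"
        assert (e.aa_old, e.aa_new) == ("G", "D")  # Gly -> Asp

    def test_synonymous_third_position(self, gene_plus):
        m, seq = gene_plus
        # CTG -> CTA both Leu
        spos, codon, cj, nb = self.find_codon(
            m, seq, lambda ci, c: (2, "A") if (c == "CTG" and ci > 0) else None)
        pos, ref, alt = mutate_at_spliced(m, seq, spos, nb)
        e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
        assert e.category == "synonymous"

    def test_start_codon_lost(self, gene_plus):
        m, seq = gene_plus
        ca, _ = m.cds_span
        pos, ref, alt = mutate_at_spliced(m, seq, ca + 2, "A")  # ATG -> ATA
        e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
        assert e.category == "start_lost"


class TestSpliceAndNoncoding:
    def test_donor_gt_first_g(self, gene_plus):
        m, seq = gene_plus
        ia, ib = m.introns()[0]
        assert seq[ia:ia + 2] == "GT"
        e = annotate(m.contig_id, ia, "G", "A", [m], {m.contig_id: seq})
        assert e.category == "splice_donor"

    def test_acceptor_ag_last_g(self, gene_plus):
        m, seq = gene_plus
        ia, ib = m.introns()[0]
        assert seq[ib - 2:ib] == "AG"
        e = annotate(m.contig_id, ib - 1, "G", "A", [m], {m.contig_id: seq})
        assert e.category == "splice_acceptor"

    def test_interior_intron_base(self, gene_plus):
        m, seq = gene_plus
        ia, ib = m.introns()[1]
        pos = (ia + ib) // 2
        e = annotate(m.contig_id, pos, seq[pos], "A" if seq[pos] != "A" else "T",
                     [m], {m.contig_id: seq})
        assert e.category == "intron"

    def test_intergenic_and_utrs(self, gene_plus):
        m, seq = gene_plus
        e = annotate(m.contig_id, 10, seq[10], "A" if seq[10] != "A" else "C",
                     [m], {m.contig_id: seq})
        assert e.category == "intergenic"
        # a 5'UTR base that cannot create ATG: pick one where no window forms ATG
        ca, cb = m.cds_span
        utr = m.spliced_sequence(seq)[:ca]
        for spos in range(3, ca - 3):
            pos, ref, alt = mutate_at_spliced(m, seq, spos, "C")
            if seq[pos] == ref and ref != "C":
                e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
                assert e.category in ("5_prime_UTR", "start_gained_5_prime_UTR")
                assert e.category == brute_force_category(m, seq, pos, alt)
                break
        spos = m.spliced_len - m.utr3_len // 2
        pos, ref, alt = mutate_at_spliced(m, seq, spos, "A")
        if ref != alt:
            e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
            assert e.category == "3_prime_UTR"

    def test_start_gained_in_utr(self, gene_plus):
        m, seq = gene_plus
        ca, _ = m.cds_span
        utr = m.spliced_sequence(seq)[:ca]
        # find an A_G window one base from ATG
        for i in range(len(utr) - 2):
            if utr[i] == "A" and utr[i + 2] == "G" and utr[i + 1] != "T":
                pos, ref, alt = mutate_at_spliced(m, seq, i + 1, "T")
                e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
                assert e.category == "start_gained_5_prime_UTR"
                return
        pytest.skip("fixture UTR lacks an A?G window")


class TestStrandSymmetry:
    def test_mirrored_gene_identical_categories(self, gene_plus):
        m, seq = gene_plus
        L = len(seq)
        mirror_seq = revcomp(seq)
        mirror = GeneModel(gene_id=m.gene_id, contig_id=m.contig_id, strand="-",
                           exons=tuple((L - b, L - a) for a, b in reversed(m.exons)),
                           utr5_len=m.utr5_len, utr3_len=m.utr3_len)
        rng = np.random.default_rng(72)
        a0, b0 = m.span
        for _ in range(100):
            pos = int(rng.integers(a0 - 20, b0 + 20))
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            e1 = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
            mpos = L - 1 - pos
            e2 = annotate(m.contig_id, mpos, revcomp(ref), revcomp(alt),
                          [mirror], {m.contig_id: mirror_seq})
            assert e1.category == e2.category, (pos, e1.category, e2.category)


class TestOracle:
    def test_500_random_mutations_match_retranslation_oracle(self):
        models, contigs = simulate_gene_model(8, rng_seed=73)
        rng = np.random.default_rng(74)
        n = 0
        while n < 500:
            m = models[int(rng.integers(len(models)))]
            seq = contigs[m.contig_id]
            a, b = m.span
            pos = int(rng.integers(max(0, a - 50), min(len(seq), b + 50)))
            ref = seq[pos]
            alt = str(rng.choice([x for x in "ACGT" if x != ref]))
            e = annotate(m.contig_id, pos, ref, alt, [m], {m.contig_id: seq})
            assert e.category == brute_force_category(m, seq, pos, alt), \
                (m.gene_id, m.strand, pos, ref, alt)
            n += 1

    def test_genic_ems_truth_never_intergenic(self, tiny_population):
        sets, lines = tiny_population
        seqs = {hs.contig_id(g): hs.seqs[g] for hs in sets for g in genomes.GENOMES}
        models = [hs.models[g] for hs in sets for g in genomes.GENOMES]
        checked = 0
        for line in lines:
            for mut in line.mutations:
                model = next(mo for mo in models if mo.contig_id == mut.contig_id)
                a, b = model.span
                if a <= mut.position < b:
                    e = annotate(mut.contig_id, mut.position, mut.ref_base,
                                 mut.alt_base, models, seqs)
                    assert e.category != "intergenic"
                    checked += 1
        assert checked > 5


class TestSummary:
    def test_truncation_count(self):
        calls = ([effects.EffectCall("c", i, "G", "A", "g", "stop_gained") for i in range(8)]
                 + [effects.EffectCall("c", i, "G", "A", "g", "splice_donor") for i in range(3)]
                 + [effects.EffectCall("c", 0, "G", "A", "g", "splice_acceptor")]
                 + [effects.EffectCall("c", i, "G", "A", "g", "missense") for i in range(20)])
        table, truncations = effect_summary(calls)
        assert truncations == 12
        assert int(table[table.category == "total"]["count"].iloc[0]) == 32

    def test_percentages_sum_and_empty(self):
        table, truncations = effect_summary([])
        assert truncations == 0
        calls = [effects.EffectCall("c", i, "G", "A", "g", c)
                 for i, c in enumerate(effects.CATEGORIES)]
        table, _ = effect_summary(calls)
        body = table[table.category != "total"]
        assert int(body["count"].sum()) == len(effects.CATEGORIES)
        assert abs(body["percent"].sum() - 100.0) < 0.5
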