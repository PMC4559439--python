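"""Bait tiling, repeat screening and capture-biased read simulation."""

import math

import numpy as np
import pytest
from Bio import SeqIO

from polytill import capture, genomes
from polytill.capture import (Fragment, KmerIndex, ReadSimConfig, capture_weight,
                              filter_repetitive_baits, gc_factor, simulate_reads,
                              tile_baits)


def brute_force_coverage(baits, L):
    cov = np.zeros(L, dtype=int)
    for b in baits:
        cov[b.offset:b.offset + len(b.sequence)] += 1
    return cov


def rand_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestTiling:
    @pytest.mark.parametrize("L,n_expected", [(600, 9), (120, 1), (121, 2), (180, 2),
                                              (240, 3), (1200, 19)])
    def test_bait_counts(self, L, n_expected):
        baits = tile_baits({"c": rand_seq(L, L)})
        assert len(baits) == n_expected
        # formula the counts follow for grid-aligned lengths
        if (L - 120) % 60 == 0:
            assert len(baits) == (L - 120) // 60 + 1
        assert len(baits) == math.ceil((L - 120) / 60) + 1

    @pytest.mark.parametrize("L", [120, 121, 179, 180, 300, 599, 600, 601])
    def test_coverage_oracle(self, L):
        baits = tile_baits({"c": rand_seq(L, L + 1)})
        cov = brute_force_coverage(baits, L)
        assert (cov >= 1).all()
        # interior double coverage when bait_len = 2*step and length on grid
        if L >= 240 and (L - 120) % 60 == 0:
            assert (cov[60:-60] == 2).all()

    def test_right_anchored_final_bait(self):
        baits = tile_baits({"c": rand_seq(121, 2)})
        assert baits[-1].offset + 120 == 121

    def test_short_cds_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            baits = tile_baits({"short": rand_seq(80, 3), "ok": rand_seq(200, 4)})
        assert all(b.source_cds_id == "ok" for b in baits)
        assert "short" in caplog.text

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            tile_baits({"c": rand_seq(300, 5)}, bait_len=60, step=60)


class TestRepeatFilter:
    def test_single_copy_in_three_homoeologues_retained(self, tiny_population):
        sets, _ = tiny_population
        hs = sets[0]
        idx = KmerIndex(genomes.reference_seqs(sets), k=31)
        cds = {f"{hs.family_id}": hs.models["A"].cds_sequence(hs.seqs["A"])}
        baits = tile_baits(cds)
        kept, removed = filter_repetitive_baits(baits, idx, max_hits=50)
        assert removed == []
        # each bait's k-mers occur about 3x (one per homoeologue)
        assert all(0 < b.repeat_hits <= 4 for b in kept)

    def test_injected_repeat_removed(self):
        unit = rand_seq(200, 77)
        genome = {"rep": unit * 60, "bg": rand_seq(5000, 78)}
        idx = KmerIndex(genome, k=31)
        baits = tile_baits({"r": unit[:40] + unit[:80] + rand_seq(0, 1) or unit[:120]})
        baits = tile_baits({"r": unit[:120], "clean": rand_seq(150, 79)})
        kept, removed = filter_repetitive_baits(baits, idx, max_hits=50)
        assert {b.source_cds_id for b in removed} == {"r"}
        assert {b.source_cds_id for b in kept} == {"clean"}

    def test_max_hits_zero_removes_everything(self):
        g = {"c": rand_seq(2000, 80)}
        idx = KmerIndex(g, k=31)
        baits = tile_baits({"b": g["c"][100:400]})
        kept, removed = filter_repetitive_baits(baits, idx, max_hits=0)
        assert kept == [] and len(removed) == len(baits)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex({"c": "ACGT"}, k=31)


def test_bait_bed_is_zero_based_half_open(tmp_path, tiny_population):
    sets, _ = tiny_population
    hs = sets[0]
    baits = tile_baits({hs.models["A"].gene_id:
                        hs.models["A"].cds_sequence(hs.seqs["A"])})
    intervals = capture.bait_target_intervals(hs, baits, "A")
    path = tmp_path / "targets.bed"
    capture.write_bait_bed(intervals, path)
    total = 0
    for line in path.read_text().splitlines():
        cid, a, b = line.split("\t")
        assert int(b) > int(a) >= 0
        total += int(b) - int(a)
    # bed interval span equals the spliced CDS length, per copy
    assert total == 3 * hs.models["A"].cds_len


class TestWeights:
    def test_gc_plateau_shape(self):
        cfg = ReadSimConfig()
        assert gc_factor(0.48, cfg) == 1.0 == gc_factor(0.60, cfg)
        assert gc_factor(0.54, cfg) == 1.0
        assert gc_factor(0.25, cfg) == pytest.approx(cfg.gc_floor)
        assert gc_factor(0.80, cfg) == pytest.approx(cfg.gc_floor)
        assert gc_factor(0.10, cfg) == pytest.approx(cfg.gc_floor)
        mid_lo = gc_factor(0.40, cfg)
        assert cfg.gc_floor < mid_lo < 1.0

    def test_on_vs_off_target_ratio(self):
        cfg = ReadSimConfig()
        ivals = {"ctg_A": [(0, 1000)], "ctg_B": [(0, 1000)]}
        fa = Fragment("l", "ctg_A", "A", 100, 450)
        fb = Fragment("l", "ctg_B", "B", 100, 450)
        wa = capture_weight(fa, ivals, 0.50, "A", cfg)
        wb = capture_weight(fb, ivals, 0.50, "A", cfg)
        assert wa == pytest.approx(cfg.on_target_share)
        assert wb / wa == pytest.approx(28 / 44)

    def test_zero_overlap_zero_weight(self):
        f = Fragment("l", "c", "A", 5000, 5350)
        assert capture_weight(f, {"c": [(0, 1000)]}, 0.5, "A") == 0.0


def _study_materials(n_families, seed, identity=0.97, **sim_kw):
    cfg = genomes.SimConfig(identity=identity, **sim_kw)
    sets, lines = genomes.simulate_population(n_families, 1, rng_seed=seed, config=cfg)
    cds = {hs.models["A"].gene_id: hs.models["A"].cds_sequence(hs.seqs["A"]) for hs in sets}
    baits = tile_baits(cds)
    intervals = {}
    for hs in sets:
        intervals.update(capture.bait_target_intervals(hs, baits, "A"))
    targets = {hs.family_id: "A" for hs in sets}
    return sets, lines, intervals, targets


class TestReadSimulation:
    def test_error_free_reads_match_source(self, tmp_path):
        sets, lines, intervals, targets = _study_materials(2, 31)
        line = genomes.LineGenome(line_id=lines[0].line_id, generation=4, mutations=[])
        cfg = ReadSimConfig(base_error=0.0, tail_fraction=0.0)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        simulate_reads(line, sets, intervals, targets, 300, r1, r2, rng_seed=5, cfg=cfg)
        seqs = {hs.contig_id(g): hs.seqs[g] for hs in sets for g in genomes.GENOMES}
        for rec1, rec2 in zip(SeqIO.parse(str(r1), "fastq"), SeqIO.parse(str(r2), "fastq")):
            contig, span, _g = rec1.description.split()[-1].rsplit("/", 1)[0].split(":")
            a, b = map(int, span.split("-"))
            frag = seqs[contig][a:b]
            for rec in (rec1, rec2):
                s = str(rec.seq)
                assert s == frag[:len(s)] or s == genomes.revcomp(frag[-len(s):])

    def test_fastq_round_trip(self, tmp_path):
        sets, lines, intervals, targets = _study_materials(1, 32)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        simulate_reads(lines[0], sets, intervals, targets, 100, r1, r2, rng_seed=6)
        recs = list(SeqIO.parse(str(r1), "fastq"))
        assert len(recs) == 100
        out = tmp_path / "rt.fq"
        SeqIO.write(recs, str(out), "fastq")
        rt = list(SeqIO.parse(str(out), "fastq"))
        assert [str(r.seq) for r in rt] == [str(r.seq) for r in recs]
        assert [r.letter_annotations["phred_quality"] for r in rt] == \
               [r.letter_annotations["phred_quality"] for r in recs]

    def test_on_target_share_near_44_percent(self, tmp_path):
        sets, lines, intervals, targets = _study_materials(6, 33)
        stats = simulate_reads(lines[0], sets, intervals, targets, 20_000,
                               tmp_path / "r1.fq", tmp_path / "r2.fq", rng_seed=7)
        share = stats["per_genome"]["A"] / stats["fragments"]
        assert abs(share - 0.44) < 0.02
        # and sampled genome frequencies match the 44:28:28 weight ratio
        from scipy.stats import chisquare
        obs = np.array([stats["per_genome"][g] for g in genomes.GENOMES])
        exp = np.array([0.44, 0.28, 0.28]) * obs.sum()
        assert chisquare(obs, exp).pvalue > 1e-4

    def test_small_exons_with_large_introns_capture_poorly(self, tmp_path):
        # two architectures competing in one capture: tiny exons in 2-kb
        # introns vs large exons in short introns; exon depth ratio > 2
        def one_family(fam, seed, exons, introns):
            cfg = genomes.SimConfig(exon_len_dist={"kind": "fixed", "values": exons},
                                    intron_len_dist={"kind": "fixed", "values": introns})
            models, contigs = genomes.simulate_gene_model(1, rng_seed=seed, config=cfg)
            m = models[0]
            return genomes.diverge_homoeologs(m, contigs[m.contig_id], 0.97,
                                              rng_seed=seed, family_id=fam)

        sets = [one_family("small", 34, [40, 40, 40], [2000, 2000]),
                one_family("large", 35, [500, 500, 500], [100, 100])]
        cds = {hs.models["A"].gene_id: hs.models["A"].cds_sequence(hs.seqs["A"])
               for hs in sets}
        baits = tile_baits(cds)
        intervals = {}
        for hs in sets:
            intervals.update(capture.bait_target_intervals(hs, baits, "A"))
        targets = {hs.family_id: "A" for hs in sets}
        line = genomes.LineGenome(line_id="l0", generation=4, mutations=[])
        r1 = tmp_path / "r1.fq"
        simulate_reads(line, sets, intervals, targets, 4000, r1,
                       tmp_path / "r2.fq", rng_seed=8)
        cov = {"small": 0, "large": 0}
        exonic = {hs.family_id: sum(b - a for a, b in hs.models["A"].exons) * 3
                  for hs in sets}
        contig_to_fam = {hs.contig_id(g): hs for hs in sets for g in genomes.GENOMES}
        for rec in SeqIO.parse(str(r1), "fastq"):
            contig, span, _ = rec.description.split()[-1].rsplit("/", 1)[0].split(":")
            a, b = map(int, span.split("-"))
            hs = contig_to_fam[contig]
            for ea, eb in hs.models["A"].exons:
                cov[hs.family_id] += max(0, min(eb, b) - max(ea, a))
        depth = {f: cov[f] / exonic[f] for f in cov}
        assert depth["large"] / max(depth["small"], 1e-9) > 2

    def test_all_zero_weights_error(self, tmp_path):
        sets, lines, _, targets = _study_materials(1, 36)
        with pytest.raises(ValueError, match="no capturable"):
            simulate_reads(lines[0], sets, {}, targets, 10,
                           tmp_path / "a.fq", tmp_path / "b.fq", rng_seed=9)

    def test_deterministic_under_seed(self, tmp_path):
        sets, lines, intervals, targets = _study_materials(1, 37)
        for tag in ("x", "y"):
            simulate_reads(lines[0], sets, intervals, targets, 50,
                           tmp_path / f"{tag}1.fq", tmp_path / f"{tag}2.fq", rng_seed=11)
        assert (tmp_path / "x1.fq").read_text() == (tmp_path / "y1.fq").read_text()
        assert (tmp_path / "x2.fq").read_text() == (tmp_path / "y2.fq").read_text()
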