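"""Simulation of a polyploid, EMS-mutagenised gene space.

Builds the truth set the rest of the pipeline is screened against:

* wheat-like gene models (multi-exon genes with GT..AG introns, ATG..stop
  CDS, configurable UTRs) each on its own contig island with intergenic
  flanks wide enough for any sequencing insert;
* three homoeologous copies (A/B/D subgenomes) of every gene, diverged to a
  target pairwise identity with the start/stop/splice signals protected and
  every differing site recorded;
* EMS mutations — exclusively G:C -> A:T transitions — placed at a per-Mb
  rate in independent mutant lines, then driven toward homozygosity by a
  configurable number of selfing rounds (single-seed descent).

Coordinates are 0-based half-open internally; GFF3 output is 1-based.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design_calc import zygosity_after_selfing

GENOMES = ("A", "B", "D")
STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

__all__ = [
    "GeneModel",
    "HomoeologSet",
    "Mutation",
    "LineGenome",
    "SimConfig",
    "simulate_gene_model",
    "diverge_homoeologs",
    "apply_ems",
    "assign_zygosity",
    "simulate_population",
    "revcomp",
    "write_fasta",
    "write_gff3",
    "write_truth_tsv",
    "write_line_fasta",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def child_rng(root_seed: int, *identifiers: str) -> np.random.Generator:
    """Derive a child RNG stream from a root seed and string identifiers.

    Streams depend only on the identifiers (CRC32-hashed), not on iteration
    order, so per-gene/per-line simulation is reproducible under reordering
    or parallelism.
    """
    keys = [zlib.crc32(ident.encode()) for ident in identifiers]
    return np.random.default_rng([int(root_seed)] + keys)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model on a contig.

    ``exons`` are sorted, non-overlapping 0-based half-open intervals in
    contig coordinates.  The spliced transcript (coding-strand orientation)
    is the concatenation of exon sequences, reverse-complemented and
    reversed for minus-strand genes; ``utr5_len``/``utr3_len`` delimit the
    CDS within it.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr5_len: int
    utr3_len: int

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_span(self) -> tuple[int, int]:
        """CDS interval in spliced (coding-strand) coordinates."""
        return self.utr5_len, self.spliced_len - self.utr3_len

    @property
    def cds_len(self) -> int:
        a, b = self.cds_span
        return b - a

    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def spliced_sequence(self, contig_seq: str) -> str:
        s = "".join(contig_seq[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def cds_sequence(self, contig_seq: str) -> str:
        a, b = self.cds_span
        return self.spliced_sequence(contig_seq)[a:b]

    def contig_to_spliced(self, pos: int) -> int | None:
        """Map a contig position to its spliced coordinate, or None if intronic/outside."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                plus_coord = off + (pos - a)
                if self.strand == "+":
                    return plus_coord
                return self.spliced_len - 1 - plus_coord
            off += b - a
        return None

    def validate(self, contig_seq: str) -> None:
        """Raise ValueError if structural invariants do not hold."""
        prev_end = None
        for a, b in self.exons:
            if b - a < 1:
                raise ValueError(f"{self.gene_id}: empty exon [{a},{b})")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = b
        if self.cds_len < 6 or self.cds_len % 3:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_len} not a codon multiple >= 6")
        cds = self.cds_sequence(contig_seq)
        if cds[:3] != "ATG":
            raise ValueError(f"{self.gene_id}: CDS does not begin ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: CDS does not end in a stop codon")
        for a, b in self.introns():
            intron = contig_seq[a:b]
            if self.strand == "-":
                intron = revcomp(intron)
            if not (intron.startswith("GT") and intron.endswith("AG")):
                raise ValueError(f"{self.gene_id}: intron lacks GT..AG on coding strand")


@dataclass
class HomoeologSet:
    """Three homoeologous copies (A/B/D) of one gene family.

    All copies share identical gene structure and coordinates (divergence is
    substitution-only), so ``homoeo_sites`` positions apply to every copy.
    """

    family_id: str
    models: dict[str, GeneModel]
    seqs: dict[str, str]
    homoeo_sites: list[tuple[int, dict[str, str]]]
    pairwise_identity: dict[tuple[str, str], float]

    def contig_id(self, genome: str) -> str:
        return self.models[genome].contig_id


@dataclass(frozen=True)
class Mutation:
    """One induced G:C -> A:T transition in one mutant line."""

    line_id: str
    genome: str
    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    zygosity: str = "het"
    generation_induced: int = 1

    def __post_init__(self):
        if (self.ref_base, self.alt_base) not in {("G", "A"), ("C", "T")}:
            raise ValueError("EMS mutations are G>A or C>T on the forward strand")


@dataclass
class LineGenome:
    """One mutant line: its retained mutations after selfing.

    ``generation`` counts selfing rounds since M1 (M5 -> 4).  ``lost``
    holds mutations that segregated away, kept for truth-table audit.
    """

    line_id: str
    generation: int
    mutations: list[Mutation] = field(default_factory=list)
    lost: list[Mutation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# length samplers

WHEAT_EXON_DIST = {"kind": "lognormal", "median": 154, "sigma": 0.75, "min": 24, "max": 3000}
WHEAT_INTRON_DIST = {"kind": "lognormal", "median": 140, "sigma": 0.60, "min": 60, "max": 3000}


def _make_sampler(spec: Mapping):
    kind = spec.get("kind", "lognormal")
    if kind == "fixed":
        values = [int(v) for v in spec["values"]]
        if any(v < 1 for v in values):
            raise ValueError(f"fixed length sampler contains non-positive lengths: {values}")
        def sample(rng, i):
            return values[i % len(values)]
        return sample, len(values)
    if kind == "lognormal":
        median, sigma = float(spec["median"]), float(spec["sigma"])
        lo, hi = int(spec.get("min", 1)), int(spec.get("max", 10 ** 6))
        if median <= 0 or lo < 1:
            raise ValueError("lognormal length sampler needs positive median and min >= 1")
        mu = np.log(median)
        def sample(rng, i):
            return int(np.clip(round(rng.lognormal(mu, sigma)), lo, hi))
        return sample, None
    if kind == "uniform":
        lo, hi = int(spec["low"]), int(spec["high"])
        if lo < 1 or hi < lo:
            raise ValueError("uniform length sampler needs 1 <= low <= high")
        def sample(rng, i):
            return int(rng.integers(lo, hi + 1))
        return sample, None
    raise ValueError(f"unknown length distribution kind {kind!r}")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons-2) random non-stop codons + one stop codon."""
    body = []
    while len(body) < n_codons - 2:
        c = _random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            body.append(c)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(body) + stop


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated gene space and mutagenesis.

    Defaults describe the wheat-like study conditions: median exon ~154 bp,
    median intron ~140 bp, ~2.25 introns per gene, homoeologue identity
    94-99%, EMS at 34 mutations/Mb, M5 material (4 selfing rounds).
    """

    exon_len_dist: Mapping = field(default_factory=lambda: dict(WHEAT_EXON_DIST))
    intron_len_dist: Mapping = field(default_factory=lambda: dict(WHEAT_INTRON_DIST))
    mean_introns: float = 2.25
    max_introns: int = 8
    gc_target: float = 0.48
    utr5_len: int = 120
    utr3_len: int = 180
    min_cds_codons: int = 40
    flank_len: int = 800  # >= 2x max insert (400 bp)
    identity: float = 0.97
    exon_divergence_weight: float = 1 / 3
    ems_rate_per_mb: float = 34.0
    generation: int = 4
    strands: str = "both"  # "both", "+" or "-"


def simulate_gene_model(
    n_genes: int,
    exon_len_dist: Mapping | None = None,
    intron_len_dist: Mapping | None = None,
    gc_target: float | None = None,
    rng_seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Simulate ``n_genes`` single-gene contigs.

    Returns the gene models and a dict contig_id -> sequence.  Exon and
    intron lengths follow the given distribution specs (wheat-like
    log-normals by default); each CDS starts ATG, ends with a stop, has no
    premature stop, and every intron is GT..AG on the coding strand.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    cfg = config or SimConfig()
    if exon_len_dist is not None:
        cfg = replace(cfg, exon_len_dist=exon_len_dist)
    if intron_len_dist is not None:
        cfg = replace(cfg, intron_len_dist=intron_len_dist)
    if gc_target is not None:
        cfg = replace(cfg, gc_target=gc_target)

    exon_sampler, n_fixed_exons = _make_sampler(cfg.exon_len_dist)
    intron_sampler, n_fixed_introns = _make_sampler(cfg.intron_len_dist)

    models: list[GeneModel] = []
    contigs: dict[str, str] = {}
    for gi in range(n_genes):
        gene_id = f"gene{gi:05d}"
        rng = child_rng(rng_seed, "gene_model", gene_id)
        if n_fixed_introns is not None:
            n_introns = n_fixed_introns
        else:
            n_introns = min(int(rng.poisson(cfg.mean_introns)), cfg.max_introns)
        n_exons = n_introns + 1
        if n_fixed_exons is not None and n_fixed_exons != n_exons:
            n_exons = n_fixed_exons
            n_introns = n_exons - 1
        exon_lens = [exon_sampler(rng, i) for i in range(n_exons)]
        intron_lens = [max(intron_sampler(rng, i), 4) for i in range(n_introns)]

        # fit UTRs + a codon-multiple CDS; shrink UTRs on short transcripts
        # rather than padding exons, so sampled length distributions survive
        spliced = sum(exon_lens)
        min_cds = 3 * cfg.min_cds_codons
        if spliced < min_cds:
            exon_lens[-1] += min_cds - spliced
            spliced = min_cds
        utr5, utr3 = cfg.utr5_len, cfg.utr3_len
        allowed_utr = spliced - min_cds
        if utr5 + utr3 > allowed_utr:
            scale = allowed_utr / max(utr5 + utr3, 1)
            utr5 = int(utr5 * scale)
            utr3 = int(utr3 * scale)
        cds_len = spliced - utr5 - utr3
        pad = (-cds_len) % 3
        exon_lens[-1] += pad
        spliced += pad
        cds_len += pad

        cds = _random_cds(rng, cds_len // 3, cfg.gc_target)
        transcript = (
            _random_seq(rng, utr5, cfg.gc_target)
            + cds
            + _random_seq(rng, utr3, cfg.gc_target)
        )

        # interleave exon slices of the transcript with GT..AG introns
        parts, exon_ivals = [], []
        pos = cfg.flank_len
        toff = 0
        parts.append(_random_seq(rng, cfg.flank_len, cfg.gc_target))
        for i, elen in enumerate(exon_lens):
            parts.append(transcript[toff:toff + elen])
            exon_ivals.append((pos, pos + elen))
            toff += elen
            pos += elen
            if i < n_introns:
                ilen = intron_lens[i]
                parts.append("GT" + _random_seq(rng, ilen - 4, cfg.gc_target) + "AG")
                pos += ilen
        parts.append(_random_seq(rng, cfg.flank_len, cfg.gc_target))
        contig_seq = "".join(parts)

        if cfg.strands == "both":
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            strand = cfg.strands
        if strand == "-":
            L = len(contig_seq)
            contig_seq = revcomp(contig_seq)
            exon_ivals = [(L - b, L - a) for a, b in reversed(exon_ivals)]

        contig_id = f"ctg_{gene_id}"
        model = GeneModel(
            gene_id=gene_id,
            contig_id=contig_id,
            strand=strand,
            exons=tuple(exon_ivals),
            utr5_len=utr5,
            utr3_len=utr3,
        )
        model.validate(contig_seq)
        models.append(model)
        contigs[contig_id] = contig_seq
    return models, contigs


def _protected_positions(model: GeneModel) -> set[int]:
    """Contig positions whose bases carry structural signals: start, stop, splice GT/AG."""
    prot: set[int] = set()
    # start & stop codons via spliced coords
    a, b = model.cds_span
    spliced_protected = list(range(a, a + 3)) + list(range(b - 3, b))
    splice_map = _spliced_to_contig_map(model)
    prot.update(splice_map[i] for i in spliced_protected)
    for ia, ib in model.introns():
        prot.update((ia, ia + 1, ib - 2, ib - 1))
    return prot


def _spliced_to_contig_map(model: GeneModel) -> list[int]:
    m: list[int] = []
    for a, b in model.exons:
        m.extend(range(a, b))
    if model.strand == "-":
        m = m[::-1]
    return m


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _substitute(rng: np.random.Generator, base: str, ts_weight: float = 2.0) -> str:
    """Random substitution with transition:transversion odds ts_weight:1."""
    if rng.random() < ts_weight / (ts_weight + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def diverge_homoeologs(
    model: GeneModel,
    seq: str,
    identities: float | Mapping[tuple[str, str], float],
    rng_seed: int = 0,
    family_id: str | None = None,
    exon_weight: float = 1 / 3,
) -> HomoeologSet:
    """Diverge one gene into three homoeologous copies (A/B/D).

    Substitutions are placed on a star phylogeny: each copy receives private
    substitutions at disjoint sites, so the realised pairwise distance is
    the exact sum of the two branch counts.  Per-pair identity targets
    (``identities`` as a single float or a dict keyed by genome pairs) are
    honoured to within rounding over the whole contig.  Sites are drawn
    with relative density ``exon_weight`` inside exons versus elsewhere
    (default 1/3): coding sequence is under purifying selection, so
    homoeologues are markedly more conserved in exons than in introns and
    intergenic flanks — the property that lets one bait capture all three
    copies and lets reads mis-map across homoeologues.  Start/stop codons
    and splice GT/AG dinucleotides are never touched; substitutions use a
    2:1 transition:transversion mix.
    """
    if isinstance(identities, Mapping):
        ident = {tuple(sorted(k)): float(v) for k, v in identities.items()}
        d = {k: 1.0 - v for k, v in ident.items()}
    else:
        if not 0.5 < identities <= 1.0:
            raise ValueError("identity must lie in (0.5, 1.0]")
        d = {p: 1.0 - float(identities) for p in (("A", "B"), ("A", "D"), ("B", "D"))}
    for v in d.values():
        if not 0.0 <= v < 0.5:
            raise ValueError("pairwise identities must lie in (0.5, 1.0]")
    # star decomposition: branch length per copy
    branch = {
        "A": (d[("A", "B")] + d[("A", "D")] - d[("B", "D")]) / 2,
        "B": (d[("A", "B")] + d[("B", "D")] - d[("A", "D")]) / 2,
        "D": (d[("A", "D")] + d[("B", "D")] - d[("A", "B")]) / 2,
    }
    if any(v < -1e-12 for v in branch.values()):
        raise ValueError("pairwise identity targets violate the triangle inequality")

    fam = family_id or model.gene_id
    rng = child_rng(rng_seed, "diverge", fam)
    L = len(seq)
    protected = _protected_positions(model)
    free = np.array(sorted(set(range(L)) - protected))
    counts = {g: int(round(max(b, 0.0) * L)) for g, b in branch.items()}
    total = sum(counts.values())
    if total > len(free):
        raise ValueError(
            f"gene {model.gene_id}: identity targets need {total} substitutions "
            f"but only {len(free)} unprotected sites exist"
        )
    exonic = np.zeros(L, dtype=bool)
    for a, b in model.exons:
        exonic[a:b] = True
    weights = np.where(exonic[free], exon_weight, 1.0)
    chosen = rng.choice(free, size=total, replace=False, p=weights / weights.sum())
    seqs = {}
    site_alts: dict[int, dict[str, str]] = {}
    off = 0
    base_arr = np.array(list(seq))
    for g in GENOMES:
        sites = np.sort(chosen[off:off + counts[g]])
        off += counts[g]
        arr = base_arr.copy()
        for p in sites:
            arr[p] = _substitute(rng, seq[p])
            site_alts.setdefault(int(p), {})[g] = str(arr[p])
        seqs[g] = "".join(arr)

    homoeo_sites = []
    for p in sorted(site_alts):
        bases = {g: site_alts[p].get(g, seq[p]) for g in GENOMES}
        if len(set(bases.values())) > 1:
            homoeo_sites.append((p, bases))

    models = {}
    out_seqs = {}
    for g in GENOMES:
        cid = f"{fam}_{g}"
        models[g] = replace(model, contig_id=cid, gene_id=f"{fam}_{g}")
        out_seqs[g] = seqs[g]
        models[g].validate(seqs[g])

    pid = {}
    for x, y in (("A", "B"), ("A", "D"), ("B", "D")):
        diff = sum(1 for a, b in zip(seqs[x], seqs[y]) if a != b)
        pid[(x, y)] = 1.0 - diff / L
    return HomoeologSet(family_id=fam, models=models, seqs=out_seqs,
                        homoeo_sites=homoeo_sites, pairwise_identity=pid)


def apply_ems(
    sets: Sequence[HomoeologSet],
    rate_per_mb: float,
    n_lines: int,
    rng_seed: int = 0,
    generation: int = 4,
    line_prefix: str = "line",
) -> list[LineGenome]:
    """Mutagenise ``n_lines`` independent lines at ``rate_per_mb``.

    EMS alkylates G residues, so mutations are placed only at G or C sites
    (G>A on the strand carrying the G; recorded as G>A or C>T on the
    forward strand).  The per-site probability is scaled by genome length /
    G+C count so the genome-wide expectation equals ``rate_per_mb`` per Mb
    of sequence regardless of GC content.  Mutations start heterozygous
    (M1); run :func:`assign_zygosity` to segregate them.
    """
    if rate_per_mb < 0:
        raise ValueError("rate_per_mb must be >= 0")
    contigs: list[tuple[str, str, str, np.ndarray]] = []  # (contig_id, genome, seq, gc_positions)
    total_len = 0
    total_gc = 0
    for hs in sets:
        for g in GENOMES:
            seq = hs.seqs[g]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            gc_pos = np.flatnonzero((arr == ord("G")) | (arr == ord("C")))
            contigs.append((hs.contig_id(g), g, seq, gc_pos))
            total_len += len(seq)
            total_gc += len(gc_pos)
    if total_gc == 0:
        raise ValueError("genome contains no G or C sites; EMS has no substrate")
    p_site = rate_per_mb * 1e-6 * (total_len / total_gc)

    lines = []
    for li in range(n_lines):
        line_id = f"{line_prefix}{li:03d}"
        rng = child_rng(rng_seed, "ems", line_id)
        muts: list[Mutation] = []
        for contig_id, g, seq, gc_pos in contigs:
            k = rng.poisson(p_site * len(gc_pos))
            k = min(k, len(gc_pos))
            if k == 0:
                continue
            picks = rng.choice(gc_pos, size=k, replace=False)
            for p in np.sort(picks):
                ref = seq[p]
                alt = "A" if ref == "G" else "T"
                muts.append(Mutation(line_id=line_id, genome=g, contig_id=contig_id,
                                     position=int(p), ref_base=ref, alt_base=alt))
        lines.append(LineGenome(line_id=line_id, generation=generation, mutations=muts))
    return lines


def assign_zygosity(line: LineGenome, rng_seed: int = 0) -> LineGenome:
    """Segregate a line's mutations through its selfing generations.

    Each mutation independently becomes homozygous, stays heterozygous, or
    is lost, with probabilities from the single-seed-descent closed form at
    ``line.generation``.  Lost mutations are retained in ``.lost`` for the
    truth table.
    """
    hom, het, lost = zygosity_after_selfing(line.generation)
    rng = child_rng(rng_seed, "zygosity", line.line_id)
    kept: list[Mutation] = []
    dropped: list[Mutation] = []
    for m in line.mutations:
        u = rng.random()
        if u < hom:
            kept.append(replace(m, zygosity="hom"))
        elif u < hom + het:
            kept.append(replace(m, zygosity="het"))
        else:
            dropped.append(replace(m, zygosity="lost"))
    return LineGenome(line_id=line.line_id, generation=line.generation,
                      mutations=kept, lost=dropped)


def simulate_population(
    n_families: int,
    n_lines: int,
    rng_seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[list[HomoeologSet], list[LineGenome]]:
    """End-to-end truth-set construction: genes -> homoeologues -> EMS lines."""
    cfg = config or SimConfig()
    models, contigs = simulate_gene_model(n_families, rng_seed=rng_seed, config=cfg)
    sets = []
    for i, m in enumerate(models):
        fam = f"fam{i:05d}"
        sets.append(diverge_homoeologs(m, contigs[m.contig_id], cfg.identity,
                                       rng_seed=rng_seed, family_id=fam,
                                       exon_weight=cfg.exon_divergence_weight))
    lines = apply_ems(sets, cfg.ems_rate_per_mb, n_lines, rng_seed=rng_seed,
                      generation=cfg.generation)
    lines = [assign_zygosity(l, rng_seed=rng_seed) for l in lines]
    return sets, lines


# ---------------------------------------------------------------------------
# I/O


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=cid, description="") for cid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reference_seqs(sets: Iterable[HomoeologSet], genomes: Iterable[str] = GENOMES) -> dict[str, str]:
    out = {}
    gset = set(genomes)
    for hs in sets:
        for g in GENOMES:
            if g in gset:
                out[hs.contig_id(g)] = hs.seqs[g]
    return out


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS/UTR features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            ga, gb = m.span
            rows = [(ga, gb, "gene", m.gene_id, None), (ga, gb, "mRNA", f"{m.gene_id}.1", m.gene_id)]
            sc_map = _spliced_to_contig_map(m)
            ca, cb = m.cds_span
            cds_contig = sorted(sc_map[ca:cb])
            utr5_contig = sorted(sc_map[:ca])
            utr3_contig = sorted(sc_map[cb:])
            for a, b in m.exons:
                rows.append((a, b, "exon", None, f"{m.gene_id}.1"))
            for typ, positions in (("five_prime_UTR", utr5_contig), ("three_prime_UTR", utr3_contig)):
                for a, b in _runs(positions):
                    rows.append((a, b, typ, None, f"{m.gene_id}.1"))
            # CDS needs phase, accumulated in transcription order
            cds_runs = _runs(cds_contig)
            if m.strand == "-":
                cds_runs = cds_runs[::-1]
            cum = 0
            cds_rows = []
            for a, b in cds_runs:
                cds_rows.append((a, b, "CDS", None, f"{m.gene_id}.1", (3 - cum % 3) % 3))
                cum += b - a
            for a, b, typ, fid, parent in rows:
                attrs = []
                if fid:
                    attrs.append(f"ID={fid}")
                if parent:
                    attrs.append(f"Parent={parent}")
                fh.write(f"{m.contig_id}\tpolytill\t{typ}\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                         + (";".join(attrs) or ".") + "\n")
            for a, b, typ, _fid, parent, phase in cds_rows:
                fh.write(f"{m.contig_id}\tpolytill\t{typ}\t{a + 1}\t{b}\t.\t{m.strand}\t{phase}\t"
                         f"Parent={parent}\n")


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse sorted positions into maximal half-open runs."""
    out: list[tuple[int, int]] = []
    for p in positions:
        if out and out[-1][1] == p:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def write_truth_tsv(lines: Iterable[LineGenome], path: str | Path) -> None:
    """Truth table: every induced mutation with its segregation fate (1-based pos)."""
    with open(path, "w") as fh:
        fh.write("line_id\tcontig\tpos\tref\talt\tgenome\tzygosity\tfate\n")
        for line in lines:
            for m in line.mutations:
                fh.write(f"{m.line_id}\t{m.contig_id}\t{m.position + 1}\t{m.ref_base}\t"
                         f"{m.alt_base}\t{m.genome}\t{m.zygosity}\tretained\n")
            for m in line.lost:
                fh.write(f"{m.line_id}\t{m.contig_id}\t{m.position + 1}\t{m.ref_base}\t"
                         f"{m.alt_base}\t{m.genome}\t{m.zygosity}\tlost\n")


def write_line_fasta(line: LineGenome, sets: Sequence[HomoeologSet], path: str | Path) -> None:
    """Write the two haplotypes of a mutant line (het mutations on hap1 only)."""
    ref = reference_seqs(sets)
    by_contig: dict[str, list[Mutation]] = {}
    for m in line.mutations:
        by_contig.setdefault(m.contig_id, []).append(m)
    out = {}
    for cid, seq in ref.items():
        h1 = list(seq)
        h2 = list(seq)
        for m in by_contig.get(cid, []):
            h1[m.position] = m.alt_base
            if m.zygosity == "hom":
                h2[m.position] = m.alt_base
        out[f"{cid}|{line.line_id}|hap1"] = "".join(h1)
        out[f"{cid}|{line.line_id}|hap2"] = "".join(h2)
    write_fasta(out, path)
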