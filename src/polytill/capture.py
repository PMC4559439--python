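"""Bait design and capture-biased paired-end read simulation.

The capture array is tiled from spliced CDS sequences with 120-mer baits
overlapping by 60 bases (2x tiling of the target).  Baits whose k-mers are
too abundant in the simulated genome are dropped, standing in for the
BLAST-against-survey-reads repeat screen of a real design.  Sequencing is
then simulated by drawing 300-400 bp fragments genome-wide and accepting
them with probability proportional to a capture weight that encodes the
three biases such data shows: overlap with a bait target, the on-target
homoeologue advantage (44% vs 28% of mapped reads), and a GC plateau
(fragments of 48-60% GC capture best).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomes import (GENOMES, HomoeologSet, LineGenome, Mutation, child_rng,
                      _spliced_to_contig_map, _runs)

logger = logging.getLogger(__name__)

__all__ = [
    "Bait",
    "Fragment",
    "ReadSimConfig",
    "tile_baits",
    "KmerIndex",
    "filter_repetitive_baits",
    "bait_target_intervals",
    "gc_factor",
    "capture_weight",
    "simulate_reads",
    "write_bait_fasta",
    "write_bait_bed",
]


@dataclass(frozen=True)
class Bait:
    bait_id: str
    source_cds_id: str
    offset: int  # 0-based start within the CDS
    sequence: str
    repeat_hits: float = 0.0


@dataclass
class Fragment:
    line_id: str
    contig_id: str
    genome: str
    start: int
    end: int
    capture_weight: float = 0.0


# ---------------------------------------------------------------------------
# bait tiling


def tile_baits(
    cds: Mapping[str, str],
    bait_len: int = 120,
    step: int = 60,
) -> list[Bait]:
    """Tile each CDS with overlapping baits.

    Baits start at multiples of ``step``; when the CDS length is not on the
    step grid a final bait is right-anchored at the CDS end so terminal
    bases keep full coverage.  CDS shorter than one bait are skipped with a
    warning.  With ``bait_len == 2*step`` every interior base is covered
    exactly twice.
    """
    if not bait_len > step > 0:
        raise ValueError("require bait_len > step > 0")
    baits: list[Bait] = []
    for cds_id, seq in cds.items():
        L = len(seq)
        if L < bait_len:
            logger.warning("CDS %s (%d bp) shorter than bait length %d; skipped", cds_id, L, bait_len)
            continue
        offsets = list(range(0, L - bait_len + 1, step))
        if offsets[-1] + bait_len < L:
            offsets.append(L - bait_len)
        for j, off in enumerate(offsets):
            baits.append(Bait(bait_id=f"{cds_id}.b{j:03d}", source_cds_id=cds_id,
                              offset=off, sequence=seq[off:off + bait_len]))
    return baits


# ---------------------------------------------------------------------------
# k-mer repeat screen

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit k-mer codes for every k-mer of ``seq`` (k <= 31)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= arr[j:j + n].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
        rev |= (3 - arr[j:j + n]).astype(np.uint64) << np.uint64(2 * j)
    return np.minimum(fwd, rev)


class KmerIndex:
    """Multiset of canonical k-mers of a genome, queryable in bulk."""

    def __init__(self, seqs: Mapping[str, str] | Iterable[str], k: int = 31):
        self.k = k
        chunks = []
        values = seqs.values() if isinstance(seqs, Mapping) else seqs
        for s in values:
            chunks.append(_encode_kmers(s, k))
        if not chunks or sum(len(c) for c in chunks) == 0:
            raise ValueError("empty k-mer index: no sequence of length >= k provided")
        allk = np.concatenate(chunks)
        self.codes, self.counts = np.unique(allk, return_counts=True)

    def occurrences(self, seq: str) -> np.ndarray:
        """Genome occurrence count of each k-mer of ``seq``."""
        q = _encode_kmers(seq, self.k)
        idx = np.searchsorted(self.codes, q)
        idx = np.clip(idx, 0, len(self.codes) - 1)
        hit = self.codes[idx] == q
        out = np.where(hit, self.counts[idx], 0)
        return out


def filter_repetitive_baits(
    baits: Sequence[Bait],
    reference_kmers: KmerIndex,
    max_hits: float = 50,
) -> tuple[list[Bait], list[Bait]]:
    """Drop baits targeting repetitive sequence.

    A bait is removed iff the mean genome occurrence of its k-mers exceeds
    ``max_hits`` — the in-silico analogue of discarding baits with too many
    BLAST hits against a genome survey.  Returns (retained, removed).
    """
    if reference_kmers.k > min((len(b.sequence) for b in baits), default=reference_kmers.k):
        raise ValueError("k-mer length exceeds bait length")
    retained, removed = [], []
    for b in baits:
        mean_occ = float(np.mean(reference_kmers.occurrences(b.sequence)))
        b = Bait(b.bait_id, b.source_cds_id, b.offset, b.sequence, repeat_hits=mean_occ)
        (removed if mean_occ > max_hits else retained).append(b)
    return retained, removed


# ---------------------------------------------------------------------------
# capture weights


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing and capture-bias parameters.

    Defaults are the study conditions: 110-bp paired ends from 300-400 bp
    size-selected inserts, on/off-target homoeologue read shares 44%/28%,
    GC capture plateau at 48-60%, and a small fraction of reads carrying a
    low-quality (Q10) 3' tail so downstream quality clipping is exercised.
    """

    read_len: int = 110
    insert_min: int = 300
    insert_max: int = 400
    base_error: float = 0.001
    on_target_share: float = 0.44
    off_target_share: float = 0.28
    gc_plateau: tuple[float, float] = (0.48, 0.60)
    gc_limits: tuple[float, float] = (0.25, 0.80)
    gc_floor: float = 0.10
    qual_hi: int = 35
    qual_tail: int = 10
    tail_fraction: float = 0.15
    tail_geom_p: float = 0.25
    tail_error: float = 0.05


def gc_factor(gc: float | np.ndarray, cfg: ReadSimConfig = ReadSimConfig()) -> np.ndarray:
    """Piecewise-linear capture efficiency vs fragment GC.

    1.0 on the plateau, decaying linearly to ``gc_floor`` at the outer
    limits and flat beyond them.
    """
    gc = np.asarray(gc, dtype=float)
    p_lo, p_hi = cfg.gc_plateau
    l_lo, l_hi = cfg.gc_limits
    f = np.ones_like(gc)
    lo = gc < p_lo
    hi = gc > p_hi
    f = np.where(lo, cfg.gc_floor + (1 - cfg.gc_floor) * np.clip((gc - l_lo) / (p_lo - l_lo), 0, 1), f)
    f = np.where(hi, cfg.gc_floor + (1 - cfg.gc_floor) * np.clip((l_hi - gc) / (l_hi - p_hi), 0, 1), f)
    return f


def bait_target_intervals(
    hs: HomoeologSet,
    baits: Sequence[Bait],
    target_genome: str,
) -> dict[str, list[tuple[int, int]]]:
    """Project retained baits for a family onto genomic intervals.

    Baits live in spliced-CDS coordinates of the target copy; the projected
    contig intervals apply identically to all three homoeologues because
    divergence is substitution-only.  Returns contig_id -> intervals.
    """
    model = hs.models[target_genome]
    cds_id = model.gene_id
    covered = np.zeros(model.spliced_len, dtype=bool)
    a0, _ = model.cds_span
    for b in baits:
        if b.source_cds_id != cds_id:
            continue
        covered[a0 + b.offset: a0 + b.offset + len(b.sequence)] = True
    sc_map = _spliced_to_contig_map(model)
    positions = sorted(sc_map[i] for i in np.flatnonzero(covered))
    intervals = _runs(positions)
    return {hs.contig_id(g): list(intervals) for g in GENOMES}


def capture_weight(
    fragment: Fragment,
    target_intervals: Mapping[str, Sequence[tuple[int, int]]],
    gc: float,
    target_genome: str,
    cfg: ReadSimConfig = ReadSimConfig(),
) -> float:
    """Relative probability that a fragment survives capture.

    weight = overlap_factor * homoeologue_factor * gc_factor, where
    overlap_factor is the fraction of the insert overlapping any
    bait-homologous interval (0 -> weight 0), homoeologue_factor is the
    on/off-target share, and gc_factor the plateau curve.
    """
    ivals = target_intervals.get(fragment.contig_id, ())
    ov = 0
    for a, b in ivals:
        ov += max(0, min(b, fragment.end) - max(a, fragment.start))
    if ov == 0:
        return 0.0
    overlap_factor = ov / (fragment.end - fragment.start)
    hom_factor = cfg.on_target_share if fragment.genome == target_genome else cfg.off_target_share
    return float(overlap_factor * hom_factor * gc_factor(gc, cfg))


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class _ContigCtx:
    contig_id: str
    genome: str
    family: str
    seq_arr: np.ndarray      # uint8 bases
    target_mask_cum: np.ndarray  # prefix sum of bait-target mask
    gc_cum: np.ndarray           # prefix sum of G/C indicator
    on_target: bool
    muts: list[Mutation] = field(default_factory=list)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    line: LineGenome,
    sets: Sequence[HomoeologSet],
    target_intervals: Mapping[str, Sequence[tuple[int, int]]],
    target_genomes: Mapping[str, str],
    n_fragments: int,
    out_r1: str | Path,
    out_r2: str | Path,
    rng_seed: int = 0,
    cfg: ReadSimConfig = ReadSimConfig(),
) -> dict:
    """Simulate captured paired-end reads for one mutant line.

    Fragments are drawn uniformly over the genome and kept with probability
    proportional to :func:`capture_weight` (rejection sampling).  Mutations
    of the line are planted in every fragment (homozygous) or per-fragment
    with probability 1/2 (heterozygous); sequencing errors are added at
    ``base_error`` (elevated within low-quality tails).  Read names carry
    the truth locus after a space, so they drop off in SAM.

    Returns simple bookkeeping counts (fragments drawn/accepted per genome).
    """
    if cfg.read_len > cfg.insert_min:
        raise ValueError("read length must not exceed the minimum insert size")
    rng = child_rng(rng_seed, "reads", line.line_id)

    ctxs: list[_ContigCtx] = []
    for hs in sets:
        tg = target_genomes.get(hs.family_id, "A")
        for g in GENOMES:
            cid = hs.contig_id(g)
            seq = hs.seqs[g]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = np.zeros(len(seq), dtype=np.int32)
            for a, b in target_intervals.get(cid, ()):
                mask[a:b] = 1
            gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
            ctxs.append(_ContigCtx(
                contig_id=cid, genome=g, family=hs.family_id, seq_arr=arr,
                target_mask_cum=np.concatenate([[0], np.cumsum(mask)]),
                gc_cum=np.concatenate([[0], np.cumsum(gc)]),
                on_target=(g == tg),
            ))
    by_cid = {c.contig_id: i for i, c in enumerate(ctxs)}
    for m in line.mutations:
        if m.contig_id in by_cid:
            ctxs[by_cid[m.contig_id]].muts.append(m)

    # one global coordinate space: uniform fragment starts weight contigs by length
    lens = np.array([len(c.seq_arr) for c in ctxs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    total_len = int(offsets[-1])
    glob_mask_cum = np.concatenate([[0]] + [np.diff(c.target_mask_cum) for c in ctxs]).cumsum()
    glob_gc_cum = np.concatenate([[0]] + [np.diff(c.gc_cum) for c in ctxs]).cumsum()
    hom_factors = np.array([cfg.on_target_share if c.on_target else cfg.off_target_share for c in ctxs])
    w_max = max(cfg.on_target_share, cfg.off_target_share)

    accepted = 0
    drawn = 0
    per_genome = {g: 0 for g in GENOMES}
    on_count = 0
    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    batch = int(max(4096, min(4 * n_fragments, 2_000_000)))
    max_draws = 1000 * n_fragments + 100_000
    while accepted < n_fragments and drawn < max_draws:
        gstart = rng.integers(0, total_len, size=batch)
        ins = rng.integers(cfg.insert_min, cfg.insert_max + 1, size=batch)
        ci = np.searchsorted(offsets, gstart, side="right") - 1
        gend = gstart + ins
        ok = gend <= offsets[ci + 1]  # fragment contained in one contig
        gend = np.minimum(gend, offsets[ci + 1])
        overlap_factor = (glob_mask_cum[gend] - glob_mask_cum[gstart]) / ins
        gcfrac = (glob_gc_cum[gend] - glob_gc_cum[gstart]) / ins
        w = overlap_factor * hom_factors[ci] * gc_factor(gcfrac, cfg)
        w = np.where(ok, w, 0.0)
        drawn += batch
        keep = rng.random(batch) * w_max < w
        idxs = np.flatnonzero(keep)
        for j in idxs:
            if accepted >= n_fragments:
                break
            c = ctxs[ci[j]]
            s = int(gstart[j] - offsets[ci[j]])
            e = s + int(ins[j])
            frag = c.seq_arr[s:e].copy()
            # plant line mutations
            for m in c.muts:
                if s <= m.position < e:
                    if m.zygosity == "hom" or rng.random() < 0.5:
                        frag[m.position - s] = ord(m.alt_base)
            r1_seq, r1_q = _one_read(rng, frag[:cfg.read_len], cfg)
            r2_seq, r2_q = _one_read(rng, _rc_arr(frag[-cfg.read_len:]), cfg)
            if rng.random() < 0.5:
                r1_seq, r1_q, r2_seq, r2_q = r2_seq, r2_q, r1_seq, r1_q
            name = f"{line.line_id}.f{accepted:08d}"
            tag = f"{c.contig_id}:{s}-{e}:{c.genome}"
            r1_chunks.append(f"@{name} {tag}/1\n{r1_seq}\n+\n{r1_q}\n")
            r2_chunks.append(f"@{name} {tag}/2\n{r2_seq}\n+\n{r2_q}\n")
            per_genome[c.genome] += 1
            on_count += int(c.on_target)
            accepted += 1
    if accepted == 0:
        raise ValueError("no capturable fragments: all capture weights are zero")
    Path(out_r1).write_text("".join(r1_chunks))
    Path(out_r2).write_text("".join(r2_chunks))
    return {"fragments": accepted, "drawn": drawn, "per_genome": per_genome,
            "on_target": on_count}


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    return comp[arr][::-1]


def _one_read(rng: np.random.Generator, tmpl: np.ndarray, cfg: ReadSimConfig) -> tuple[str, str]:
    """Apply the error/quality model to a template and render seq+qual strings."""
    seq = tmpl.copy()
    n = len(seq)
    qual = np.full(n, cfg.qual_hi, dtype=np.int32)
    if rng.random() < cfg.tail_fraction:
        tail = min(int(rng.geometric(cfg.tail_geom_p) + 2), n)
        qual[n - tail:] = cfg.qual_tail
    err_rate = np.where(qual >= 15, cfg.base_error, cfg.tail_error)
    errs = np.flatnonzero(rng.random(n) < err_rate)
    for p in errs:
        choices = _BASES[_BASES != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    return seq.tobytes().decode(), "".join(chr(q + 33) for q in qual)


def write_bait_fasta(baits: Sequence[Bait], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in baits:
            fh.write(f">{b.bait_id} cds={b.source_cds_id} offset={b.offset}\n{b.sequence}\n")


def write_bait_bed(
    target_intervals: Mapping[str, Sequence[tuple[int, int]]],
    path: str | Path,
) -> None:
    """BED (0-based half-open) of bait-homologous genomic intervals."""
    with open(path, "w") as fh:
        for cid in sorted(target_intervals):
            for a, b in target_intervals[cid]:
                fh.write(f"{cid}\t{a}\t{b}\n")
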