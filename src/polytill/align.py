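"""A minimal seed-and-extend read mapper for substitution-only alignment.

Reproduces exactly the mapping behaviours mutation screening in a polyploid
depends on, with nothing else: a fixed mismatch budget (default 2 per
read), hard clipping of low-quality 3' tails (Q15), a three-level mapping
quality separating unique from ambiguous placements, proper-pair flagging,
and — crucially — homoeologous mis-mapping: a read whose true source contig
is absent still maps to a close homoeologue when it fits the budget.

Alignments are ungapped (EMS induces substitutions, not indels).  Output is
plain coordinate-sortable SAM with hard-clip (H) CIGAR operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomes import revcomp

__all__ = ["Alignment", "SeedIndex", "build_index", "hard_clip", "map_read_pair",
           "map_fastq_pair", "write_sam"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class Alignment:
    """One read placement (or an unmapped record)."""

    read_id: str
    contig_id: str | None
    pos: int                 # 0-based leftmost on the reference
    strand: str              # '+' or '-'
    mismatches: int
    clipped_len: int         # 3'-tail bases hard-clipped before alignment
    mapq: int                # 60 unique / 37 close runner-up / 0 tied
    paired_proper: bool
    seq: str = ""            # clipped read, reference orientation
    qual: str = ""
    flag: int = 0
    mate_contig: str | None = None
    mate_pos: int = 0
    tlen: int = 0

    @property
    def mapped(self) -> bool:
        return self.contig_id is not None

    @property
    def aligned_len(self) -> int:
        return len(self.seq)


class SeedIndex:
    """Exact-match index of every ``seed_len``-mer position in a reference.

    Contigs are concatenated (in sorted name order, which makes the
    smallest global coordinate the lexicographically smallest (contig, pos)
    — the deterministic tie-break) and all seed start positions are stored
    as a sorted array of 2-bit hashes.
    """

    def __init__(self, reference: Mapping[str, str], seed_len: int = 20):
        if seed_len < 10 or seed_len > 31:
            raise ValueError("seed_len must be in [10, 31]")
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("cannot index an empty reference")
        self.seed_len = seed_len
        self.names = sorted(reference)
        self.seqs = {n: reference[n] for n in self.names}
        lens = np.array([len(self.seqs[n]) for n in self.names], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lens)])
        self.glob = _CODE[np.frombuffer("".join(self.seqs[n] for n in self.names).encode(),
                                        dtype=np.uint8)]
        # seed hash at every in-contig position
        starts = []
        for i, n in enumerate(self.names):
            L = lens[i]
            if L >= seed_len:
                starts.append(np.arange(self.offsets[i], self.offsets[i] + L - seed_len + 1))
        pos = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        h = np.zeros(len(pos), dtype=np.uint64)
        for j in range(seed_len):
            h = (h << np.uint64(2)) | self.glob[pos + j].astype(np.uint64)
        order = np.argsort(h, kind="stable")
        self._hashes = h[order]
        self._pos = pos[order]

    def encode(self, seq: str) -> np.ndarray:
        return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]

    def seed_hash(self, codes: np.ndarray) -> int:
        h = 0
        for c in codes:
            h = (h << 2) | int(c)
        return h

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Global start positions of one exact seed (codes of length seed_len)."""
        h = np.uint64(self.seed_hash(codes))
        lo = np.searchsorted(self._hashes, h, side="left")
        hi = np.searchsorted(self._hashes, h, side="right")
        return self._pos[lo:hi]

    def lookup(self, seed: str) -> list[tuple[str, int]]:
        """Occurrences of a seed as (contig_id, 0-based position) pairs."""
        if len(seed) != self.seed_len:
            raise ValueError("seed length mismatch")
        out = []
        for g in self.lookup_codes(self.encode(seed)):
            ci = int(np.searchsorted(self.offsets, g, side="right") - 1)
            out.append((self.names[ci], int(g - self.offsets[ci])))
        return out

    def locate(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.names[ci], int(gpos - self.offsets[ci])

    def contig_bounds(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return int(self.offsets[ci]), int(self.offsets[ci + 1])


def build_index(reference: Mapping[str, str], seed_len: int = 20) -> SeedIndex:
    """Build the exact-seed index over a reference (see :class:`SeedIndex`)."""
    return SeedIndex(reference, seed_len=seed_len)


def hard_clip(seq: str, qual: str, q_threshold: int = 15) -> tuple[str, str, int]:
    """Remove the longest 3' suffix in which every base is below Q15.

    Returns (clipped_seq, clipped_qual, n_clipped).  Clipping stops at the
    last base with quality >= threshold; a fully low-quality read clips to
    nothing (and is treated as unmapped downstream).
    """
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
    keep = np.flatnonzero(q >= q_threshold)
    if len(keep) == 0:
        return "", "", len(seq)
    end = int(keep[-1]) + 1
    return seq[:end], qual[:end], len(seq) - end


def _candidates(index: SeedIndex, codes: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    """(mismatches, global_start) of every locus fitting the budget, via multi-seed lookup."""
    L = len(codes)
    k = index.seed_len
    if L < k:
        return []
    offs = list(range(0, L - k + 1, k))
    if offs[-1] != L - k:
        offs.append(L - k)
    starts: set[int] = set()
    for o in offs:
        sub = codes[o:o + k]
        if (sub == 255).any():
            continue
        for g in index.lookup_codes(sub):
            starts.add(int(g) - o)
    out = []
    for s in starts:
        if s < 0:
            continue
        lo, hi = index.contig_bounds(s)
        if s + L > hi or s < lo:
            continue
        mm = int(np.count_nonzero(index.glob[s:s + L] != codes))
        if mm <= max_mismatch:
            out.append((mm, s))
    return out


def _best(cands: list[tuple[int, int, str]]) -> tuple[tuple[int, int, str] | None, int]:
    """Pick the best candidate and its MAPQ.

    Best = fewest mismatches, ties broken by smallest global position (i.e.
    lexicographically smallest (contig, pos)) then '+' strand.  MAPQ: 60 if
    the runner-up is >=2 mismatches worse (or absent), 37 if exactly 1
    worse, 0 on a tie.
    """
    if not cands:
        return None, 0
    ranked = sorted(cands, key=lambda t: (t[0], t[1], t[2] != "+"))
    best = ranked[0]
    if len(ranked) == 1:
        return best, 60
    gap = ranked[1][0] - best[0]
    return best, 60 if gap >= 2 else (37 if gap == 1 else 0)


def map_single(read_id: str, seq: str, qual: str, index: SeedIndex,
               max_mismatch: int = 2, clip_q: int = 15) -> Alignment:
    """Map one read: hard-clip, seed both strands, extend by Hamming distance."""
    cseq, cqual, nclip = hard_clip(seq, qual, clip_q)
    if len(cseq) < index.seed_len:
        return Alignment(read_id, None, 0, "+", 0, nclip, 0, False, seq=cseq, qual=cqual, flag=4)
    cands: list[tuple[int, int, str]] = []
    fwd = index.encode(cseq)
    for mm, s in _candidates(index, fwd, max_mismatch):
        cands.append((mm, s, "+"))
    rev_seq = revcomp(cseq)
    rev = index.encode(rev_seq)
    for mm, s in _candidates(index, rev, max_mismatch):
        cands.append((mm, s, "-"))
    best, mapq = _best(cands)
    if best is None:
        return Alignment(read_id, None, 0, "+", 0, nclip, 0, False, seq=cseq, qual=cqual, flag=4)
    mm, gpos, strand = best
    contig, pos = index.locate(gpos)
    if strand == "+":
        oseq, oqual = cseq, cqual
    else:
        oseq, oqual = rev_seq, cqual[::-1]
    return Alignment(read_id, contig, pos, strand, mm, nclip, mapq, False,
                     seq=oseq, qual=oqual, flag=0x10 if strand == "-" else 0)


def map_read_pair(
    r1: tuple[str, str, str],
    r2: tuple[str, str, str],
    index: SeedIndex,
    max_mismatch: int = 2,
    clip_q: int = 15,
    insert_bounds: tuple[int, int] = (200, 600),
) -> tuple[Alignment, Alignment]:
    """Map a read pair and set SAM flags, including proper-pair status.

    A pair is proper when both mates map to the same contig on opposite
    strands, converging, with an outer insert inside ``insert_bounds``.
    MAPQ is per-mate; low-MAPQ alignments are still reported (downstream
    filters decide).
    """
    a1 = map_single(r1[0], r1[1], r1[2], index, max_mismatch, clip_q)
    a2 = map_single(r2[0], r2[1], r2[2], index, max_mismatch, clip_q)
    proper = False
    if a1.mapped and a2.mapped and a1.contig_id == a2.contig_id and a1.strand != a2.strand:
        left, right = (a1, a2) if a1.pos <= a2.pos else (a2, a1)
        insert = (right.pos + right.aligned_len) - left.pos
        if left.strand == "+" and insert_bounds[0] <= insert <= insert_bounds[1]:
            proper = True
            left_tlen, right_tlen = insert, -insert
            left.tlen, right.tlen = left_tlen, right_tlen
    for a, mate, first in ((a1, a2, True), (a2, a1, False)):
        flag = 0x1 | (0x40 if first else 0x80)
        if not a.mapped:
            flag |= 0x4
        elif a.strand == "-":
            flag |= 0x10
        if not mate.mapped:
            flag |= 0x8
        elif mate.strand == "-":
            flag |= 0x20
        if proper:
            flag |= 0x2
        a.flag = flag
        a.paired_proper = proper
        a.mate_contig = mate.contig_id
        a.mate_pos = mate.pos
    return a1, a2


def map_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    index: SeedIndex,
    max_mismatch: int = 2,
    clip_q: int = 15,
    insert_bounds: tuple[int, int] = (200, 600),
) -> list[Alignment]:
    """Map all pairs of two FASTQ files (names matched positionally)."""
    out: list[Alignment] = []
    for (n1, s1, q1), (n2, s2, q2) in zip(_iter_fastq(r1_path), _iter_fastq(r2_path)):
        if n1 != n2:
            raise ValueError(f"read-name mismatch between mates: {n1!r} vs {n2!r}")
        a1, a2 = map_read_pair((n1, s1, q1), (n2, s2, q2), index, max_mismatch,
                               clip_q, insert_bounds)
        out.extend((a1, a2))
    return out


def _iter_fastq(path: str | Path):
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].split()[0], seq, qual


def write_sam(alignments: Sequence[Alignment], reference: Mapping[str, str],
              path: str | Path) -> None:
    """Write alignments as SAM 1.6 with hard-clip CIGARs and 1-based POS."""
    names = sorted(reference)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for n in names:
            fh.write(f"@SQ\tSN:{n}\tLN:{len(reference[n])}\n")
        fh.write("@PG\tID:polytill\tPN:polytill\n")
        for a in alignments:
            if a.mapped and a.contig_id not in reference:
                raise ValueError(f"alignment references unknown contig {a.contig_id}")
            if not a.mapped:
                fh.write(f"{a.read_id}\t{a.flag}\t*\t0\t0\t*\t*\t0\t0\t"
                         f"{a.seq or '*'}\t{a.qual or '*'}\n")
                continue
            m = a.aligned_len
            if a.clipped_len:
                cigar = (f"{a.clipped_len}H{m}M" if a.strand == "-" else f"{m}M{a.clipped_len}H")
            else:
                cigar = f"{m}M"
            if a.mate_contig is None:
                rnext, pnext = "*", 0
            elif a.mate_contig == a.contig_id:
                rnext, pnext = "=", a.mate_pos + 1
            else:
                rnext, pnext = a.mate_contig, a.mate_pos + 1
            fh.write(f"{a.read_id}\t{a.flag}\t{a.contig_id}\t{a.pos + 1}\t{a.mapq}\t{cigar}\t"
                     f"{rnext}\t{pnext}\t{a.tlen}\t{a.seq}\t{a.qual}\tNM:i:{a.mismatches}\n")
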