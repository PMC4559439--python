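"""Pileup and threshold-based variant calling.

Mirrors the classical mpileup-then-filter route used for mutation
screening: per-site base counts from paired, confidently mapped reads
(MAPQ >= 20) and confidently called bases (baseQ >= 20), followed by
purely threshold-based calls — minimum total depth 8, a minimum number of
variant-supporting reads (3..8 depending on stringency), and a minimum
allele frequency of 5%.  No genotype-likelihood model: allele frequency is
simply variant reads / passing depth, which is the quantity the
cross-sample screen reasons about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = ["SiteCounts", "PileupCounts", "pileup", "call_variants", "vcf_write", "vcf_read",
           "merge_samples", "CALL_COLUMNS"]

_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i
BASES = "ACGT"

CALL_COLUMNS = ["sample_id", "contig", "pos", "ref", "alt", "var_reads", "depth", "af",
                "is_transition"]
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class SiteCounts:
    """Filtered base counts at one reference site."""

    contig_id: str
    pos: int
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.counts)


class PileupCounts:
    """Per-contig (length x 4) filtered base-count matrices."""

    def __init__(self, counts: dict[str, np.ndarray], reference: Mapping[str, str]):
        self.counts = counts
        self.reference = reference

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=1)

    def depth_at(self, contig: str, pos: int) -> int:
        if contig not in self.counts:
            return 0
        return int(self.counts[contig][pos].sum())

    def site(self, contig: str, pos: int) -> SiteCounts:
        c = self.counts[contig][pos]
        return SiteCounts(contig, pos, self.reference[contig][pos], tuple(int(x) for x in c))

    def sites(self, min_depth: int = 1):
        """Yield SiteCounts for every site with depth >= min_depth."""
        for contig, arr in self.counts.items():
            ref = self.reference[contig]
            for p in np.flatnonzero(arr.sum(axis=1) >= min_depth):
                c = arr[p]
                yield SiteCounts(contig, int(p), ref[p], tuple(int(x) for x in c))


def pileup(
    sam_path: str | Path,
    reference: Mapping[str, str],
    min_baseq: int = 20,
    min_mapq: int = 20,
    paired_only: bool = True,
) -> PileupCounts:
    """Count bases per site from a SAM file under the screening filters.

    Only mapped reads with MAPQ >= ``min_mapq`` (and, with ``paired_only``,
    the proper-pair flag) contribute; within a read only bases with quality
    >= ``min_baseq`` are counted.  Hard-clipped bases are absent from SEQ
    and therefore never counted.  Alignments are ungapped so each read
    covers ``pos .. pos+len(SEQ)``.
    """
    counts = {cid: np.zeros((len(seq), 4), dtype=np.int32) for cid, seq in reference.items()}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in reference:
                raise ValueError(f"SAM contig {name} missing from reference FASTA")
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if paired_only and not read.is_proper_pair:
                continue
            contig = read.reference_name
            arr = counts[contig]
            seq = read.query_sequence
            quals = read.query_qualities
            codes = _BASE_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
            q = np.asarray(quals, dtype=np.int32)
            pos = read.reference_start
            idx = np.arange(pos, pos + len(seq))
            keep = (q >= min_baseq) & (codes >= 0) & (idx < arr.shape[0])
            np.add.at(arr, (idx[keep], codes[keep].astype(np.int64)), 1)
    return PileupCounts(counts, reference)


def call_variants(
    piles: PileupCounts,
    sample_id: str,
    min_depth: int = 8,
    min_var_reads: int = 5,
    min_af: float = 0.05,
) -> pd.DataFrame:
    """Threshold-based variant calls from filtered site counts.

    One row per (site, alt) with depth >= ``min_depth``, variant reads >=
    ``min_var_reads`` and AF = var/depth >= ``min_af``.  Transitions
    (A<->G, C<->T) are flagged.  Multi-allelic sites yield one row per alt.
    """
    if min_var_reads > min_depth:
        logger.warning("min_var_reads (%d) exceeds min_depth (%d)", min_var_reads, min_depth)
    rows = []
    for contig, arr in piles.counts.items():
        depth = arr.sum(axis=1)
        refseq = piles.reference[contig]
        ref_codes = _BASE_IDX[np.frombuffer(refseq.encode(), dtype=np.uint8)]
        for alt_i in range(4):
            var = arr[:, alt_i]
            with np.errstate(invalid="ignore", divide="ignore"):
                af = np.where(depth > 0, var / np.maximum(depth, 1), 0.0)
            hit = (depth >= min_depth) & (var >= min_var_reads) & (af >= min_af) \
                & (ref_codes != alt_i) & (ref_codes >= 0)
            for p in np.flatnonzero(hit):
                ref_b = refseq[p]
                alt_b = BASES[alt_i]
                rows.append((sample_id, contig, int(p), ref_b, alt_b, int(var[p]),
                             int(depth[p]), float(af[p]), (ref_b, alt_b) in _TRANSITIONS))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["contig", "pos", "alt"], ignore_index=True)


def merge_samples(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample call tables, preserving per-sample support columns."""
    frames = []
    for sid, df in tables.items():
        d = df.copy()
        d["sample_id"] = sid
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def vcf_write(calls: pd.DataFrame, path: str | Path, reference: Mapping[str, str] | None = None) -> None:
    """Write calls to a minimal VCF 4.2 (INFO: DP, AD, AF; 1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        fh.write('##INFO=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample/line id">\n')
        if reference:
            for cid in sorted(reference):
                fh.write(f"##contig=<ID={cid},length={len(reference[cid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in calls.itertuples():
            ref_reads = r.depth - r.var_reads
            fh.write(f"{r.contig}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                     f"DP={r.depth};AD={ref_reads},{r.var_reads};AF={r.af:.4f};"
                     f"SAMPLE={r.sample_id}\n")


def vcf_read(path: str | Path) -> pd.DataFrame:
    """Parse a VCF written by :func:`vcf_write` back into a call table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"malformed VCF record: {line!r}")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            depth = int(info["DP"])
            var = int(info["AD"].split(",")[1])
            rows.append((info.get("SAMPLE", ""), f[0], int(f[1]) - 1, f[3], f[4], var,
                         depth, float(info["AF"]), (f[3], f[4]) in _TRANSITIONS))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
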