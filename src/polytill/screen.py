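"""Cross-sample mutation identification and reporting.

Induced mutations are private to one mutant line, while homoeologous and
varietal differences from the reference appear in every line.  The screen
therefore keeps a site as a candidate mutation only when exactly one
(focal) sample shows the variant at >= 5% allele frequency and every other
sample stays <= 2% — provided the other samples actually had the depth to
be assessed.  Candidates are then classified as EMS-type (G>A / C>T on the
forward reference strand) or not, binned by allele frequency, and
summarised across a grid of minimum-variant-read thresholds.

Also here: the homoeologue-dropout experiment (re-map one line's reads
against references missing one or more homoeologues of a focal gene and
watch the truth-site allele frequency dilute or the mutation mis-assign to
another copy), and the arithmetic of validation-rate tables.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from . import calls as _calls
from .genomes import GENOMES, HomoeologSet, Mutation

__all__ = [
    "AF_BIN_EDGES", "AF_BIN_LABELS", "af_bin", "classify_ems",
    "cross_sample_filter", "af_bin_report", "ems_confidence_curve",
    "homoeolog_dropout", "validation_summary",
]

AF_BIN_EDGES = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
AF_BIN_LABELS = [f"{a:g}-{b:g}" for a, b in zip(AF_BIN_EDGES[:-1], AF_BIN_EDGES[1:])]


def af_bin(af: float) -> str | None:
    """Allele-frequency bin label; edges are left-open/right-closed.

    (0.05, 0.1], (0.1, 0.2], ..., (0.9, 1.0]; AF <= 0.05 or > 1 is None.
    """
    if af > AF_BIN_EDGES[-1] or af <= AF_BIN_EDGES[0]:
        # AF exactly 0.05 sits on the lowest edge; calling uses >= 0.05 so
        # treat it as the first bin rather than dropping it.
        if math.isclose(af, AF_BIN_EDGES[0]):
            return AF_BIN_LABELS[0]
        return None
    for a, b, lab in zip(AF_BIN_EDGES[:-1], AF_BIN_EDGES[1:], AF_BIN_LABELS):
        if a < af <= b:
            return lab
    return None


def classify_ems(ref_base: str, alt_base: str) -> bool:
    """True iff the change is an EMS-type transition: G>A or C>T (forward strand)."""
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise ValueError("bases must be A/C/G/T")
    return (ref_base, alt_base) in {("G", "A"), ("C", "T")}


def cross_sample_filter(
    per_sample_calls: Mapping[str, pd.DataFrame],
    depth_of: Mapping[str, _calls.PileupCounts] | None = None,
    min_focal_af: float = 0.05,
    max_other_af: float = 0.02,
    min_depth: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Keep variants private to exactly one sample.

    A site/alt passes when exactly one sample has AF >= ``min_focal_af``
    and every other sample is <= ``max_other_af``.  A sample without a call
    at the site counts as AF 0 only if it had assessable coverage
    (depth >= ``min_depth``, looked up in ``depth_of``); otherwise the site
    is unassessable and excluded (counted in the returned stats).  With
    ``depth_of=None`` absent calls are taken as AF 0 (useful for
    pre-tabulated AF matrices).

    Returns (candidates, stats): candidates carry the focal sample's call
    plus ``ems_type``, ``af_bin`` and the other samples' AFs.
    """
    if len(per_sample_calls) < 2:
        raise ValueError("cross-sample filtering needs at least two samples")
    samples = list(per_sample_calls)
    af_by_key: dict[tuple, dict[str, float]] = {}
    row_by_key: dict[tuple, dict[str, pd.Series]] = {}
    for sid, df in per_sample_calls.items():
        for r in df.itertuples():
            key = (r.contig, r.pos, r.alt)
            af_by_key.setdefault(key, {})[sid] = r.af
            row_by_key.setdefault(key, {})[sid] = r
    candidates = []
    stats = {"sites": len(af_by_key), "unassessable": 0, "rejected_multi": 0,
             "rejected_other_af": 0}
    for key, afs in af_by_key.items():
        contig, pos, alt = key
        full = {}
        unassessable = False
        for sid in samples:
            if sid in afs:
                full[sid] = afs[sid]
            elif depth_of is None:
                full[sid] = 0.0
            elif depth_of[sid].depth_at(contig, pos) >= min_depth:
                full[sid] = 0.0
            else:
                unassessable = True
                break
        if unassessable:
            stats["unassessable"] += 1
            continue
        over = [sid for sid, af in full.items() if af >= min_focal_af]
        if len(over) != 1:
            stats["rejected_multi"] += int(len(over) > 1)
            continue
        focal = over[0]
        if any(af > max_other_af for sid, af in full.items() if sid != focal):
            stats["rejected_other_af"] += 1
            continue
        r = row_by_key[key][focal]
        candidates.append({
            "line_id": focal, "contig": contig, "pos": pos, "ref": r.ref, "alt": alt,
            "var_reads": r.var_reads, "depth": r.depth, "af": r.af,
            "ems_type": classify_ems(r.ref, alt), "af_bin": af_bin(r.af),
            "af_in_others": ";".join(f"{sid}:{full[sid]:.4f}" for sid in samples if sid != focal),
        })
    cols = ["line_id", "contig", "pos", "ref", "alt", "var_reads", "depth", "af",
            "ems_type", "af_bin", "af_in_others"]
    df = pd.DataFrame(candidates, columns=cols)
    return df.sort_values(["contig", "pos", "alt"], ignore_index=True), stats


def af_bin_report(
    candidates: pd.DataFrame,
    min_var_reads_grid: Iterable[int] = range(3, 9),
) -> pd.DataFrame:
    """Count candidates per AF bin, EMS class and variant-read threshold.

    One row per (min_var_reads, ems class) with the ten AF-bin counts, a
    total, and a total restricted to AF > 0.1 — the layout mutation-screen
    comparisons are reported in.
    """
    rows = []
    for mvr in min_var_reads_grid:
        sub = candidates[candidates["var_reads"] >= mvr]
        for ems in (True, False):
            s = sub[sub["ems_type"] == ems]
            bin_counts = s["af_bin"].value_counts()
            counts = [int(bin_counts.get(lab, 0)) for lab in AF_BIN_LABELS]
            rows.append([mvr, "EMS" if ems else "NON-EMS", *counts, sum(counts),
                         sum(counts[1:])])
    return pd.DataFrame(rows, columns=["min_var_reads", "snp_type", *AF_BIN_LABELS,
                                       "total", "total_af_gt_0.1"])


def ems_confidence_curve(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMS fraction per AF bin and per variant-read count.

    Returns (by_af_bin, by_var_reads); strata with no candidates have NaN
    fraction (undefined), never 0.
    """
    by_bin_rows = []
    for lab in AF_BIN_LABELS:
        s = candidates[candidates["af_bin"] == lab]
        n = len(s)
        ems = int(s["ems_type"].sum())
        by_bin_rows.append([lab, ems, n - ems, ems / n if n else np.nan])
    by_bin = pd.DataFrame(by_bin_rows, columns=["af_bin", "ems", "non_ems", "ems_fraction"])
    by_vr_rows = []
    if len(candidates):
        for vr in sorted(candidates["var_reads"].unique()):
            s = candidates[candidates["var_reads"] == vr]
            n = len(s)
            ems = int(s["ems_type"].sum())
            by_vr_rows.append([int(vr), ems, n - ems, ems / n if n else np.nan])
    by_vr = pd.DataFrame(by_vr_rows, columns=["var_reads", "ems", "non_ems", "ems_fraction"])
    return by_bin, by_vr


# ---------------------------------------------------------------------------
# homoeologue dropout


def _subset_label(subset: Sequence[str]) -> str:
    return "".join(g for g in GENOMES if g in subset)


def homoeolog_dropout(
    r1_path,
    r2_path,
    sets: Sequence[HomoeologSet],
    focal_family: str,
    truth: Sequence[Mutation],
    subsets: Iterable[Sequence[str]] | None = None,
    min_depth: int = 8,
    min_var_reads: int = 3,
    min_af: float = 0.05,
    max_mismatch: int = 2,
    min_mapq: int = 20,
    misassign_window: int = 150,
) -> pd.DataFrame:
    """Re-map one line's reads against references missing homoeologues.

    For every non-empty subset of {A, B, D} the focal family keeps only
    those copies in the reference (all other families stay complete); reads
    are re-mapped and re-piled, and the truth mutations are measured: depth
    and variant AF at the truth site on each present copy, plus any variant
    call within ``misassign_window`` bp on a *different* homoeologue with
    the same alt base (a mis-assignment event).

    Homoeologous copies share coordinates, so a truth position applies
    directly to every copy's contig.
    """
    if subsets is None:
        subsets = [("A",), ("B",), ("D",), ("A", "B"), ("A", "D"), ("B", "D"),
                   ("A", "B", "D")]
    focal = next(hs for hs in sets if hs.family_id == focal_family)
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        ref = {}
        for hs in sets:
            for g in GENOMES:
                if hs.family_id == focal_family and g not in subset:
                    continue
                ref[hs.contig_id(g)] = hs.seqs[g]
        index = _align.build_index(ref)
        alns = _align.map_fastq_pair(r1_path, r2_path, index, max_mismatch=max_mismatch)
        piles = pileup_alignments(alns, ref, min_mapq=min_mapq)
        calls_df = _calls.call_variants(piles, "dropout", min_depth=min_depth,
                                        min_var_reads=min_var_reads, min_af=min_af)
        for m in truth:
            source_present = m.genome in subset
            for g in subset:
                cid = focal.contig_id(g)
                depth = piles.depth_at(cid, m.position)
                alt_i = "ACGT".index(m.alt_base)
                var = int(piles.counts[cid][m.position, alt_i]) if cid in piles.counts else 0
                af = var / depth if depth else 0.0
                mis = (g != m.genome)
                near = calls_df[(calls_df["contig"] == cid)
                                & (abs(calls_df["pos"] - m.position) <= misassign_window)
                                & (calls_df["alt"] == m.alt_base)]
                rows.append({
                    "subset": _subset_label(subset), "line_id": m.line_id,
                    "truth_contig": m.contig_id, "truth_pos": m.position,
                    "truth_genome": m.genome, "measured_genome": g,
                    "measured_contig": cid, "source_in_reference": source_present,
                    "coverage": depth, "var_reads": var, "af": af,
                    "mis_assigned_call": bool(len(near)) and mis,
                })
    return pd.DataFrame(rows)


def pileup_alignments(
    alignments: Sequence[_align.Alignment],
    reference: Mapping[str, str],
    min_baseq: int = 20,
    min_mapq: int = 20,
    paired_only: bool = True,
) -> _calls.PileupCounts:
    """Pileup directly from in-memory alignments (same filters as calls.pileup)."""
    counts = {cid: np.zeros((len(seq), 4), dtype=np.int32) for cid, seq in reference.items()}
    for a in alignments:
        if not a.mapped or a.mapq < min_mapq or (paired_only and not a.paired_proper):
            continue
        arr = counts[a.contig_id]
        codes = _calls._BASE_IDX[np.frombuffer(a.seq.encode(), dtype=np.uint8)]
        q = np.frombuffer(a.qual.encode(), dtype=np.uint8).astype(np.int32) - 33
        idx = np.arange(a.pos, a.pos + len(a.seq))
        keep = (q >= min_baseq) & (codes >= 0) & (idx < arr.shape[0])
        np.add.at(arr, (idx[keep], codes[keep].astype(np.int64)), 1)
    return _calls.PileupCounts(counts, reference)


def validation_summary(assay_counts: pd.DataFrame) -> pd.DataFrame:
    """Percent of candidate mutations validated by an independent assay.

    Input: one row per class with columns ``assays`` and ``validated``
    (plus any identifying columns).  Adds ``validated_pct`` =
    100*validated/assays rounded to the nearest integer; classes with zero
    assays get NaN (undefined), never 0.
    """
    if not {"assays", "validated"} <= set(assay_counts.columns):
        raise ValueError("assay table must have 'assays' and 'validated' columns")
    out = assay_counts.copy()
    pct = []
    for r in out.itertuples():
        if r.assays == 0:
            pct.append(np.nan)
        else:
            pct.append(int(math.floor(100.0 * r.validated / r.assays + 0.5)))
    out["validated_pct"] = pct
    return out
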