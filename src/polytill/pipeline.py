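"""End-to-end orchestration: truth simulation -> capture -> mapping ->
calling -> cross-sample screen -> effect annotation.

This is the screening experiment in one call, so a study — how well does a
capture-based screen recover known mutations under given conditions — is a
single configured function invocation.  Heavy intermediates (FASTQ, SAM)
go to a working directory; results come back as dataframes plus recovery
metrics measured against the simulated truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, calls, capture, effects, genomes, screen

__all__ = ["ScreenStudy", "run_screen_study", "recovery_metrics"]


@dataclass
class ScreenStudy:
    """Everything a simulated screening run produced."""

    sets: list
    lines: list
    baits: list
    target_intervals: dict
    target_genomes: dict
    reference: dict
    per_sample_calls: dict
    piles: dict
    candidates: pd.DataFrame
    filter_stats: dict
    read_stats: dict
    metrics: dict = field(default_factory=dict)


def run_screen_study(
    workdir: str | Path,
    n_families: int = 40,
    n_lines: int = 3,
    mean_target_depth: float = 30.0,
    seed: int = 0,
    sim_config: genomes.SimConfig | None = None,
    read_config: capture.ReadSimConfig | None = None,
    min_depth: int = 8,
    min_var_reads: int = 3,
    min_af: float = 0.05,
    max_mismatch: int = 2,
    keep_sam: bool = False,
) -> ScreenStudy:
    """Simulate and screen a mutant population end to end.

    ``mean_target_depth`` sets the sequencing effort: the number of
    fragments per line is chosen so the bait-covered space reaches roughly
    that mean filtered read depth.  Calling runs at the loosest variant-read
    threshold (``min_var_reads``); stricter thresholds are applied when
    reporting, so one run supports the whole threshold grid.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    scfg = sim_config or genomes.SimConfig()
    rcfg = read_config or capture.ReadSimConfig()

    sets, lines = genomes.simulate_population(n_families, n_lines, rng_seed=seed, config=scfg)

    # bait design from the target copy of each family
    rng = genomes.child_rng(seed, "target_choice")
    target_genomes = {hs.family_id: genomes.GENOMES[rng.integers(3)] for hs in sets}
    cds = {}
    for hs in sets:
        tg = target_genomes[hs.family_id]
        m = hs.models[tg]
        cds[m.gene_id] = m.cds_sequence(hs.seqs[tg])
    baits = capture.tile_baits(cds)
    kidx = capture.KmerIndex(genomes.reference_seqs(sets), k=31)
    baits, _removed = capture.filter_repetitive_baits(baits, kidx)

    target_intervals: dict = {}
    for hs in sets:
        target_intervals.update(capture.bait_target_intervals(hs, baits, target_genomes[hs.family_id]))
    target_bp = sum(b - a for iv in target_intervals.values() for a, b in iv)

    reference = genomes.reference_seqs(sets)
    index = align.build_index(reference)

    # fragments per line so that filtered depth over targets ~ mean_target_depth;
    # the 0.35 factor absorbs partial bait overlap and MAPQ/pair/baseq losses
    # (ambiguously-placed reads in conserved exons are dropped at MAPQ 0)
    n_fragments = int(math.ceil(mean_target_depth * target_bp / (2 * rcfg.read_len) / 0.35))

    per_sample_calls = {}
    piles = {}
    read_stats = {}
    for line in lines:
        r1 = workdir / f"{line.line_id}_R1.fastq"
        r2 = workdir / f"{line.line_id}_R2.fastq"
        read_stats[line.line_id] = capture.simulate_reads(
            line, sets, target_intervals, target_genomes, n_fragments,
            r1, r2, rng_seed=seed, cfg=rcfg)
        alns = align.map_fastq_pair(r1, r2, index, max_mismatch=max_mismatch)
        sam_path = workdir / f"{line.line_id}.sam"
        if keep_sam:
            align.write_sam(alns, reference, sam_path)
            pc = calls.pileup(sam_path, reference)
        else:
            pc = screen.pileup_alignments(alns, reference)
        piles[line.line_id] = pc
        per_sample_calls[line.line_id] = calls.call_variants(
            pc, line.line_id, min_depth=min_depth, min_var_reads=min_var_reads, min_af=min_af)

    candidates, fstats = screen.cross_sample_filter(
        per_sample_calls, depth_of=piles, min_depth=min_depth)

    study = ScreenStudy(sets=sets, lines=lines, baits=baits,
                        target_intervals=target_intervals, target_genomes=target_genomes,
                        reference=reference, per_sample_calls=per_sample_calls,
                        piles=piles, candidates=candidates, filter_stats=fstats,
                        read_stats=read_stats)
    study.metrics = recovery_metrics(study, min_depth=min_depth)
    return study


def recovery_metrics(study: ScreenStudy, min_depth: int = 8,
                     recover_var_reads: int = 8, recover_af: float = 0.9) -> dict:
    """Measure the screen against the simulated truth.

    * ``hom_recovery``: fraction of homozygous truth mutations at screenable
      sites (filtered depth >= ``min_depth`` in every line, which is what
      the cross-sample rule needs to assess a site) recovered as candidates
      with >= ``recover_var_reads`` variant reads and AF > ``recover_af``.
    * ``ems_purity_strict``: EMS-type fraction among candidates with >= 8
      variant reads and AF > 0.1.
    * ``rate_estimate_per_mb`` vs ``rate_truth_per_mb``: strict-candidate
      density vs retained-truth-mutation density, both over the screenable
      space (sites with depth >= ``min_depth`` in every line), so the two
      are densities of the same observable population.
    * ``mean_target_depth``: achieved filtered depth over bait targets.
    """
    cand_key = {(r.line_id, r.contig, r.pos, r.alt): r
                for r in study.candidates.itertuples()}
    hom_callable = 0
    hom_recovered = 0
    truth_at_callable = 0
    all_piles = list(study.piles.values())
    for line in study.lines:
        for m in line.mutations:
            screenable = all(p.depth_at(m.contig_id, m.position) >= min_depth
                             for p in all_piles)
            if screenable:
                truth_at_callable += 1
            if m.zygosity != "hom" or not screenable:
                continue
            hom_callable += 1
            r = cand_key.get((m.line_id, m.contig_id, m.position, m.alt_base))
            if r is not None and r.var_reads >= recover_var_reads and r.af > recover_af:
                hom_recovered += 1

    strict = study.candidates[(study.candidates["var_reads"] >= 8)
                              & (study.candidates["af"] > 0.1)]
    ems_purity = float(strict["ems_type"].mean()) if len(strict) else float("nan")

    callable_bp = 0
    depth_sum = 0
    target_bp = 0
    for cid in study.reference:
        depths = [p.counts[cid].sum(axis=1) for p in all_piles]
        shared = np.minimum.reduce([d >= min_depth for d in depths])
        callable_bp += int(shared.sum()) * len(all_piles)
        for a, b in study.target_intervals.get(cid, ()):
            depth_sum += sum(int(d[a:b].sum()) for d in depths)
            target_bp += (b - a) * len(all_piles)
    callable_mb = callable_bp / 1e6
    rate_est = len(strict) / callable_mb if callable_mb else float("nan")
    rate_truth = truth_at_callable / callable_mb if callable_mb else float("nan")

    on_frac = float("nan")
    tot = sum(s["fragments"] for s in study.read_stats.values())
    if tot:
        on_frac = sum(s["on_target"] for s in study.read_stats.values()) / tot

    return {
        "hom_truth_callable": hom_callable,
        "hom_recovered": hom_recovered,
        "hom_recovery": hom_recovered / hom_callable if hom_callable else float("nan"),
        "n_candidates_strict": int(len(strict)),
        "ems_purity_strict": ems_purity,
        "rate_estimate_per_mb": rate_est,
        "rate_truth_per_mb": rate_truth,
        "callable_mb": callable_mb,
        "mean_target_depth": depth_sum / target_bp if target_bp else float("nan"),
        "on_target_fragment_share": on_frac,
    }


def annotate_candidates(study: ScreenStudy) -> pd.DataFrame:
    """Effect-classify every candidate against the simulated gene models."""
    models = [m for hs in study.sets for m in hs.models.values()]
    rows = []
    for r in study.candidates.itertuples():
        e = effects.annotate(r.contig, r.pos, r.ref, r.alt, models, study.reference)
        rows.append({"line_id": r.line_id, "contig": r.contig, "pos": r.pos,
                     "ref": r.ref, "alt": r.alt, "category": e.category,
                     "codon_old": e.codon_old, "codon_new": e.codon_new})
    return pd.DataFrame(rows)
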