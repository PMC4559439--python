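# polytill

In-silico exon-capture TILLING for polyploid genomes.

Reverse-genetics screens of EMS-mutagenised wheat identify induced point
mutations by capturing coding sequence with oligonucleotide baits,
sequencing, mapping, and filtering variants across mutant lines. Doing
this in hexaploid bread wheat is hard for one central reason: every gene
exists as three homoeologous copies (A, B, D subgenomes) at 94–99%
identity, so reads cross-hybridise to the bait, cross-map between copies,
and — when the reference genome is missing a copy — mis-map onto the wrong
one, diluting or relocating the signal of a real mutation.

`polytill` implements that whole screen as a tested, reusable pipeline on
simulated (or real FASTA/GFF3/FASTQ) inputs, for people designing or
debugging capture-based mutation screens in polyploids:

* **genomes** — wheat-like gene models (median exon ~154 bp, median intron
  ~140 bp), triplicated into homoeologues with exon-conserved divergence,
  EMS G:C→A:T mutations at a per-Mb rate, and selfing segregation
  (het fraction 2⁻ᵍ after g selfing rounds) with full truth tracking.
* **capture** — 120-mer baits tiled at 60-bp steps over CDS, a k-mer
  repeat screen, and paired-end 110-bp read simulation with capture bias
  (insert–bait overlap × 44:28 on/off-target homoeologue shares × a GC
  plateau over 48–60%).
* **align** — a minimal seed-and-extend mapper: ≤2 mismatches, Q15 hard
  clipping, MAPQ 60/37/0 (unique/close/tied), proper-pair flags, SAM out.
  Homoeologous mis-mapping emerges rather than being scripted.
* **calls** — pileup under the screening filters (proper pairs, MAPQ ≥ 20,
  baseQ ≥ 20) and threshold calling (depth ≥ 8, variant reads 3–8,
  AF ≥ 0.05), VCF/TSV out.
* **screen** — the cross-sample rule (AF ≥ 5% in exactly one line, ≤ 2% in
  all others), EMS-spectrum classification, AF-bin reports, the
  homoeologue-dropout experiment, and validation-rate arithmetic.
* **effects** — a small strand-aware consequence classifier (stop gained,
  splice donor/acceptor G, start lost/gained, synonymous/missense, UTRs,
  intron, intergenic).
* **design_calc** — closed forms for selfing zygosity, cross-generation
  rate conversion, reference-incompleteness AF dilution, null-mutation
  probability and required population size.

## Worked example

The population-design arithmetic, from the command line:

```bash
$ polytill calc zygosity -g 4
{"g": 4, "hom": 0.46875, "het": 0.0625, "lost": 0.46875,
 "retained": 0.53125, "hom_share_retained": 0.8823529411764706}
```

After four selfing rounds (an M₅ line) only 53% of induced mutations
remain, and 88% of those are homozygous — so most true mutations should
appear at allele frequency 1.0, the rest at 0.5.

```bash
$ polytill calc rate --rate 24 --from-g 4 --to-g 1
{"rate_in": 24.0, "from_g": 4, "to_g": 1,
 "rate_out": 33.88235294117647, "rate_out_rounded": 34}

$ polytill calc null-prob
{"p": 0.002023, "p_3sf": 0.00202}

$ polytill calc lines --p 0.002023
{"raw": 1479.3381451546097, "rounded": 1500}

$ polytill calc dilution --true-af 0.5 --copies-in-ref 1
{"true_af": 0.5, "observed_af": 0.16666666666666666, "observed_af_2dp": 0.16}
```

A rate of 24 mutations/Mb measured at M₅ is 34/Mb expressed at M₂; at that
rate an average gene (1,100 bp CDS, 2.25 introns) suffers a truncating
(null) mutation in a given line with probability 2.02×10⁻³, so ~1,500
lines give 95% confidence of finding one. And if the mapping reference
carries only one of the three homoeologues, a heterozygous mutation's
observed allele frequency can fall from 0.5 to 0.16 — below many callers'
radar — purely from wild-type homoeologous reads mis-mapping onto it.

The full simulated screen, from Python:

```python
from polytill import pipeline

study = pipeline.run_screen_study("workdir", n_families=200, n_lines=3,
                                  mean_target_depth=30, seed=1)
print(study.metrics)
```

which mutagenises three M₅ lines over 200 triplicated gene families at
34 mutations/Mb, captures and sequences them, maps, calls, cross-sample
filters, and scores against the simulated truth. With seed 1 this prints
(abridged):

```
hom_recovery            1.0     # all 17 screenable homozygous truths found
ems_purity_strict       1.0     # candidates (≥8 var reads, AF>0.1) all G>A/C>T
rate_estimate_per_mb    14.7    # vs 15.4/Mb of retained truth in the same space
mean_target_depth       29.6
on_target_fragment_share 0.4391 # the designed 44% on-target bias
```

`screen.homoeolog_dropout` re-maps one line's reads against references
missing homoeologues of a focal gene: with all three copies present the
homozygous truth site reads AF 1.0; with only its own copy present the AF
dilutes to ~0.34; with the source copy absent entirely, the variant reads
mis-map to a sister copy and are called there (a logged mis-assignment).

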