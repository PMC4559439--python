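# Methods

`polytill` models a mutation screen by exon capture in hexaploid bread
wheat: an EMS-mutagenised population propagated by self-fertilisation is
sequenced after hybridisation capture of coding sequence, reads are mapped
to a (possibly incomplete) reference containing up to three homoeologous
copies of every gene, and induced mutations are identified by a
two-threshold cross-sample filter. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Selfing genetics

Every EMS-induced mutation starts heterozygous in the treated (M1)
generation. Under single-seed descent each selfing round leaves a mutation
heterozygous with probability 1/2 and otherwise fixes or loses it with
equal probability, so after `g` rounds

    het(g)  = 2^-g
    hom(g)  = lost(g) = (1 - 2^-g) / 2
    retained(g) = hom + het = (1 + 2^-g) / 2.

Generation indexing is the one place an off-by-one silently corrupts
everything downstream: `g` counts selfing rounds **after** M1, so M2 means
`g = 1` and M5 means `g = 4`. At M5 the homozygous share among retained
mutations is 15/17 ≈ 88% (12% heterozygous), and a mutation rate observed
in generation `s` converts to generation `t` by the ratio of retained
fractions — 24 mutations/Mb observed at M5 is 34/Mb expressed at M2.

The population-design calculators build on this: with an average gene of
1,100 bp coding sequence, 2.25 introns (each with two essential splice G
residues) and ~5% of coding changes creating a stop, a rate of 34/Mb gives
a per-line null-mutation probability of `34e-6 × (55 + 4.5) = 2.02e-3`,
hence `ln(0.05)/ln(1-p) ≈ 1479` — round 1,500 — lines for 95% confidence.
`lines_for_confidence` rounds **up** to a whole hundred (nearest-100
rounding would return zero lines for tiny raw values); the raw value is
always returned alongside.

## Synthetic gene space

`genomes.simulate_gene_model` builds each gene on its own contig island
with 800 bp intergenic flanks (≥ 2× the largest sequencing insert). Exon
and intron lengths are log-normal with medians 154 bp and 140 bp — the
wheat-like regime in which most introns are shorter than a sequencing
insert — and intron count is Poisson(2.25). CDSs begin ATG, end with a
stop, contain no premature stop, and every intron is GT..AG on the coding
strand; genes are placed on either strand. UTR lengths (defaults 120/180
bp) are a configurable choice, not calibrated to any dataset; they shrink
proportionally on short transcripts so the sampled exon-length
distribution is not distorted.

`diverge_homoeologs` creates the A/B/D copies on a star phylogeny with
substitutions at disjoint sites, so realised pairwise identity hits the
target (default 97%, band 94–99%) essentially exactly; start/stop codons
and splice dinucleotides are protected, and substitutions use a 2:1
transition:transversion mix, so homoeologous variation overlaps the EMS
spectrum only partially, as in real data. Substitution density is 3× lower
inside exons than in introns/flanks (`exon_divergence_weight = 1/3`).
This exonic conservation is deliberate and load-bearing: it is what lets
one bait capture all three homoeologues and what lets 110-bp reads cross
homoeologues within a 2-mismatch budget. With divergence spread uniformly,
essentially no homoeologous read fits the budget and the mis-mapping and
allele-frequency-dilution phenomenology this package exists to reproduce
cannot occur.

EMS mutagenesis places G>A / C>T transitions (forward-strand notation)
only at G/C sites, with per-site probability scaled by genome-length /
G+C-count so that the genome-wide expectation equals the configured rate
per Mb of sequence (rates are quoted per Mb, not per G:C site). The
default 34/Mb is the M2-expressed rate of the emulated population.
Segregation fates are then drawn from the closed form above; "lost"
mutations revert to wild type but remain in the truth table for audit.

## Capture and sequencing model

Baits are 120-mers tiled at 60-bp steps over each family's target-copy
CDS (2× interior coverage); when the CDS length is off-grid the final bait
is right-anchored so terminal bases stay covered; CDS shorter than one
bait are skipped with a warning. The repeat screen drops any bait whose
31-mers occur on average more than 50 times in the simulated genome — a
deterministic k-mer surrogate for BLASTing baits against genome survey
reads, with the same intent (discard multi-copy targets) and threshold.

Sequencing draws 300–400 bp fragments uniformly over the genome and keeps
them by rejection sampling with weight

    overlap_factor × homoeologue_factor × gc_factor

where `overlap_factor` is the fraction of the insert overlapping any
bait-homologous interval, `homoeologue_factor` is 0.44 for the bait-design
copy and 0.28 for each sister copy (the observed on/off-target mapped-read
shares), and `gc_factor` is a piecewise-linear plateau: 1.0 for fragment
GC in [0.48, 0.60], decaying to a floor of 0.1 at GC 0.25 and 0.80. The
plateau is a stand-in for an observed trend, not a fitted curve; its
breakpoints and floor are configurable. Reads are 110 bp paired ends with
uniform 0.001 base error; 15% of reads carry a Q10 3' tail of geometric
length (elevated 5% error inside the tail) so that quality clipping has
something to do. Heterozygous mutations enter each fragment with
probability 1/2; homozygous ones always.

## Mapping, calling and screening

The mapper is seed-and-extend with exact 20-mer seeds at every read offset
multiple of 20 (plus a right-anchored seed), ungapped Hamming extension,
and a fixed budget of 2 mismatches — matching the stringency the emulated
screen ran at; EMS induces substitutions, so indels are out of model.
3' tails in which every base is below Q15 are hard-clipped first. MAPQ is
deliberately coarse: 60 for a unique best ≥2 mismatches clear of the
runner-up, 37 for a gap of 1, 0 for a tie; only the ≥20 filter matters
downstream, so the scale just needs to separate unique from ambiguous.
Ties are reported at the lexicographically smallest (contig, position) for
determinism. Pairs are proper when convergent on one contig with an outer
insert in [200, 600] bp. Output is plain SAM with hard-clip CIGARs.

Pileup counts only proper-pair reads with MAPQ ≥ 20 and bases with quality
≥ 20; both overlapping mates count. Calling is purely threshold-based:
depth ≥ 8, variant reads ≥ 3..8 (stringency grid), allele frequency =
variant/passing-depth ≥ 0.05. The screen then keeps a site when **exactly
one** line shows AF ≥ 0.05 and every other line is ≤ 0.02 — homoeologous
and varietal variants appear in all lines and are removed by this rule. A
line without a call counts as AF 0 only where it has depth ≥ 8; otherwise
the site is unassessable and excluded (counted, because stochastic
low-coverage behaviour is the known failure mode of the rule). The
published wording oscillates between "greater than 5%" and "at least 5%";
we use ≥ 0.05, configurably, at both calling and screening. AF bins are
left-open/right-closed, (0.05,0.1] … (0.9,1.0], with AF exactly 0.05
assigned to the first bin rather than dropped.

Effect annotation is a minimal single-transcript classifier: intergenic /
intron / splice donor / splice acceptor / UTRs / start-gained-in-5'UTR /
start-lost / stop-gained / synonymous / missense, strand-aware, with only
the two invariant G residues per intron (donor G of GT, acceptor G of AG)
yielding splice categories — the same accounting the null-probability
arithmetic uses. Loss of the annotated stop codon, unreachable by EMS
transitions, folds into missense rather than extending the category set.

## The dropout experiment

`screen.homoeolog_dropout` rebuilds the reference with each non-empty
subset of {A, B, D} for a focal family, re-maps, re-piles and measures the
truth sites. Because divergence is substitution-only, coordinates carry
across copies. A candidate within 150 bp of a truth site on a *different*
homoeologue with the same alt base is flagged a mis-assignment. The
packaged fixture emulates the kind of gene this experiment needs: a truth
site deep in a large conserved exon, flanked by homoeologue-distinguishing
SNPs, with homoeologue-neutral capture shares for the focal family. Each
choice matters: if the site's neighbourhood is identical between two
copies, variant reads tie at MAPQ 0 and vanish whenever both copies are in
the reference; if covering reads span diverged introns their mates fail
the mismatch budget and the proper-pair filter discards them; and under
the population-average 44:28 capture bias the sister-copy read supply
caps the one-copy dilution at ~0.44 rather than the ~1/3 equal-coverage
value the experiment demonstrates. The dilution calculator's worst-case
closed form (`true_af / (1 + copies_missing)`) assumes exactly this
equal-coverage, full-mis-mapping regime.

## Problem sizes and what the tests show

The end-to-end acceptance run screens 3 M5 lines over 200 families
(600 genes, ~0.6 Mb of genic sequence on ~2.3 Mb of contigs) at 34
mutations/Mb with a complete reference and ~30× filtered target depth,
then measures: recovery of homozygous truth mutations (denominator:
truth sites with depth ≥ 8 in *every* line — the sites the cross-sample
rule can assess at all), EMS purity of candidates at ≥ 8 variant reads and
AF > 0.1, and the candidate density against the truth density over the
callable space. Fragment count is set from the nominal depth with a 0.35
efficiency factor absorbing partial bait overlap and MAPQ/pair/base-quality
losses (ambiguous placements in conserved exons cost real coverage, as
they do in real polyploid data).

What passing does **not** show about real data: the simulator has no PCR
duplicates, no optical/indel errors, no reference mis-assembly, uniform
insert sizes, a schematic GC response, and divergence that is homogeneous
within compartments; real capture screens face all of these. The
measured quantities (on-target share, dilution, recovery) are emulations
whose *mechanisms* — spectrum filtering, cross-sample privacy,
homoeologous mis-mapping — are the tested content.

## Numerical conventions

0-based half-open coordinates internally; 1-based in GFF3/VCF/SAM output.
One top-level seed; every gene/line/stage derives a child stream by stable
hashing of its identifier, so results are independent of iteration order.
Rounding follows the conventions of the quantities reported: rates to the
nearest integer, probabilities to 3 significant figures, the dilution AF
truncated at 2 decimals, line counts up to a whole hundred; raw values are
always available. Degenerate inputs (empty k-mer index, all-zero capture
weights, genomes without G/C, malformed length distributions) raise with
explicit messages rather than propagating NaNs.
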