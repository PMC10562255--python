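# Methods

`rloopkat` implements the somatic-mutation analyses used to connect
APOBEC3B activity to R-loop mutagenesis: per-sample APOBEC motif
enrichment, SBS96 signature refitting, simulation-calibrated kataegis
detection, R-loop/strand association of kataegic events, expression-bin
mutation-density analysis, and cohort-level contingency and resampling
tests. A synthetic-cohort generator with a planted-truth manifest gives
every stage a recovery test.

## Conventions

Mutations are 1-based (VCF/MAF convention); every interval is 0-based
half-open (BED convention); conversion happens only at I/O boundaries,
so a VCF position p corresponds to the BED interval [p-1, p). Every
single-base substitution is strand-normalized to pyrimidine notation:
when the reference base is a purine both alleles are complemented and
the ±2 bp context is read 5'→3' on the reverse strand. Motif names
(TCW, RTCA, YTCA, RTCW, YTCW; W=A/T, R=A/G, Y=C/T) always refer to the
strand carrying the mutated pyrimidine. Duplicate records (same sample,
chromosome, position, alt) are collapsed with a warning so no artificial
zero intermutational distances enter the cluster caller.

## APOBEC enrichment score

For the C>T/C>G substitutions of one sample,

    E = (m_TCW × c_C) / (m_C × c_TCW)

where m_C and m_TCW count cytosine mutations and their TCW subset and
c_C, c_TCW count cytosines and TCW motifs on either strand within
±20 bp of each counted mutation. E ≈ 1 when TCW cytosines are mutated no
more often than local availability predicts. Significance is a
one-sided Fisher's exact test on [[m_TCW, m_C−m_TCW], [c_TCW,
c_C−c_TCW]] with Benjamini–Hochberg correction across the cohort;
"enriched" means q < 0.05 and E > 1. The same ratio with RTCA or YTCA in
place of TCW scores individual kataegic events; an event "skews RTCA"
when E_RTCA strictly exceeds E_YTCA with both defined, which separates
A3B-like from A3A-like tetranucleotide preference.

E is undefined (reported missing) when m_C = 0 or c_TCW = 0; windows at
chromosome ends are clipped rather than dropped, and N bases never
count.

## Signature refitting

Per-sample SBS96 catalogs (96 pyrimidine-substitution × flank channels)
are fit to a user-supplied signature matrix by nonnegative least
squares on the frequency scale; signatures with normalized weight below
`prune_threshold` (default 0.06) are dropped and the fit repeated until
the retained set is stable; weights are renormalized to sum to one. A
sample is "APOBEC-positive" when weight(SBS2) + weight(SBS13) reaches
`detect_threshold` (default 0.06, matching the pruning convention of
widely used refitting tools). The signature matrix is always an input
file, never bundled, to avoid pinning a catalog version; synthetic
tests use generator-defined signatures.

## Kataegis detection

Clusters are called with a sample-dependent intermutational-distance
(IMD) cutoff calibrated against context-preserving background
simulations.

*Background model.* Each simulation reassigns every observed SBS to a
position drawn uniformly, without replacement within the simulation,
from all genomic positions sharing its pyrimidine-normalized
pentanucleotide; mutations inside a gene are restricted to genes of the
same strand, preserving transcriptional strand coordination. A context
class with too few eligible positions falls back to trinucleotide
matching with a warning. The genome-wide context index is built once
per reference and reused across samples.

*Cutoff.* For each candidate cutoff c in the grid {2^4 … 2^16} bp,
obs(c) counts observed mutations whose nearest-neighbor IMD is below c
and exp(c) is the simulation mean of the same count. The cutoff is the
largest c with (obs−exp)/obs ≥ 0.90 — at least 90% of sub-cutoff
mutations in excess of chance — and a BH-corrected one-sided empirical
p (plus-one corrected, so p ≥ 1/(n_sims+1)) below 0.01 across the grid;
"none" when no candidate qualifies. The default is 200 simulations: the
plus-one floor combined with BH over the 13-candidate grid makes
q < 0.01 unreachable at 100 simulations, while 200 gives a floor near
0.005 and attainable q ≈ 0.007 at desk scale.

*Regional correction and VAF filter.* Within each 10 Mbp window the
cutoff is multiplied by min(1, global density / window density) — dense
windows shrink it, sparse windows never loosen it. Runs of consecutive
same-chromosome mutations below the corrected cutoff form candidate
clusters; any adjacent pair differing in VAF by ≥ 0.10 splits the run
(clonality control). Runs of ≥3 are "clustered", ≥5 additionally
"kataegis"; two-member runs are reported as subthreshold. A cluster is
APOBEC-flagged when every member is a TCW-context C>T or C>G. Distance
to the nearest same-sample structural-variant breakpoint (same
chromosome, nearest member) partitions events at 10 kbp into
SV-proximal (recombination-associated) and SV-distal sets; strand
coordination is reported but not enforced as a call criterion, since
the size-based definition does not require it.

## R-loop association

R-loop intervals (BED, e.g. from DRIP–seq peak calls) are padded by
1 kbp on each side and merged before overlap. Each strand-normalized
mutation is labeled NTS (pyrimidine on the gene's annotated/coding
strand — the strand displaced as ssDNA in an R-loop), TS (opposite),
intergenic, or ambiguous (covered by genes on both strands; kept in
totals, excluded from strand statistics). A cluster's region label is
the majority label of its members, ties ambiguous. Kataegic events
(APOBEC-flagged, size ≥3 by default) are compared per region and motif
to nonclustered control mutations scored with the same per-mutation
window enrichment, using a two-sided Mann–Whitney U test, BH across the
region × motif family, and Cohen's d. Members of *any* called run —
including subthreshold pairs — are excluded from the control group: a
two-member fragment of a split kataegic tract is clustered, not
dispersed, and leaving such fragments among controls biases the
comparison toward the null.

## Expression and cohort associations

Fold changes are tumor expression over the mean of designated normal
samples. Seven bins: G1 Exp=0; G2 FC<0.8; G3 0.8≤FC≤1.2; G4 1.2<FC≤4;
G5 4<FC≤8; G6 8<FC≤16; G7 FC>16 (G3 closed on both sides, the others
half-open upward — one consistent closure is declared because prose
ranges are ambiguous at the edges). Per tumor and bin, the APOBEC rate
is TCW C>T/C>G mutations per megabase of the bin's summed exon length;
mutations anywhere in the gene body count by default, with an
exonic-only option. All twelve lowest-three × highest-four bin pairs
are compared by Welch's t-test with BH correction. A five-group variant
bins genes by baseline expression (nonexpressed plus quartiles) and
reports the TCW count, its fraction of all SBS, and the count per
megabase of gene body (tx span, exons plus introns). Strand bias is a
two-sided Wilcoxon rank-sum test on per-tumor NTS vs TS TCW counts.

The deleterious-mutation filter keeps nonsense, splice-site and
frameshift-indel consequences (the MAF classes Nonsense_Mutation,
Splice_Site, Frame_Shift_Del/Ins). Splice-factor association builds
three contrasts: two-sided Fisher on APOBEC-positivity × splice-factor
mutation; two-sided Fisher on RTCW-absence × splice-factor mutation
among APOBEC-positive tumors; and Welch t-tests on APOBEC-attributed
fraction and total burden. The housekeeping null redraws k genes
(default 119) from a pool without replacement, recording per iteration
the mutated-gene and mutated-tumor counts and a Fisher test of APOBEC
positivity against carrying a mutation in the drawn set, BH-corrected
across iterations; the iteration count scales down without changing
code paths.

## Synthetic cohort generator

The generator emulates the statistical structure of an
APOBEC-mutagenized breast-tumor cohort at desk scale, with every draw
from one seeded RNG (identical configs are bit-identical, truth
manifest included). Defaults: a 10 Mbp genome (2 × 5 Mbp) at GC 0.45;
120 non-overlapping genes of 6–20 kbp with 2–6 exons; 60 R-loop
intervals of 800 bp placed inside genes with a 5′-end bias (Beta(1,6)
positional draw for 80% of intervals), matching the promoter-proximal
skew of DRIP–seq peaks; 10 samples at 5 dispersed SBS/Mbp — the burden
density of breast whole genomes — of which a fraction f = 0.2 is forced
onto TCW cytosines as C>T/C>G; 3 planted clusters per sample, sizes
5–8, span ≤ 2 kbp, strand-coordinated, founder VAF ~ U(0.2, 0.6) with
members jittered at sd 0.02 (dispersed VAFs U(0.1, 0.9), so the <0.10
adjacency filter is testable in both directions); 17% of clusters
placed inside R-loops on the host gene's coding strand with a
RTCA:YTCA member mix of 0.7, the published skew, while clusters planted
elsewhere draw TCW sites motif-neutrally; 5 SV breakpoints per sample;
splice-factor and housekeeping gene labels; and an expression table
with per-gene fold-change bins shaped like the observed per-bin gene
counts (the 0.8–1.2 bin dominating), plus a coupling that plants ~2
extra TCW mutations per >16-fold-overexpressed gene per sample so the
expression association is recoverable.

What the generator does not emulate: chromatin state, replication
timing, copy number, clonal structure beyond the VAF jitter, indel
realism beyond consequence labels, and germline variation. Passing
recovery tests therefore demonstrate that the algorithms detect what
they claim under their stated assumptions — not that real tumors
satisfy those assumptions.

## Numerical and design choices

- The IMD grid is powers of two from 16 bp to 65,536 bp; the empirical
  p uses the plus-one correction; BH runs over grid candidates with
  obs > 0.
- Inter-chromosome gaps of 10^9 bp in the global coordinate system make
  cross-chromosome neighbor distances unreachable by any candidate
  cutoff.
- A pair of consecutive mutations is linked using the corrected cutoff
  of the window containing the earlier mutation.
- Sampling without replacement within a simulation is per context
  class; collisions across classes are impossible for pentamer-exact
  matches (distinct contexts occupy distinct positions).
- Degenerate statistics are pinned: zero-margin Fisher tables give
  p = 1; identical groups give Welch p = 1 (flagged) and Cohen's d = 0;
  all-tied rank tests give p = 1.
- Boundary windows are clipped; mutations whose ±2 bp window leaves the
  chromosome or contains N are skipped with a warning and counted.

## Problem sizes

Recovery and calibration checks run at the sizes the package's tests
use by choice: 20 samples × 3,000 mutations on 10 Mbp for the
dispersed-only null calibration; the default cohort (10 samples,
~50 SBS each, 30 planted clusters) for kataegis recall; cohorts of
2,500 mutations per sample for the enrichment null; 10,000-mutation
catalogs for refit recovery; and ten 6 Mbp six-sample cohorts for the
planted R-loop/NTS effect. The planted-effect cohorts use 1 kbp cluster
spans so member gaps sit comfortably below the derived cutoffs;
detection still runs blind to the truth manifest.

## Known limitations

The enrichment-score availability window (±20 bp) makes E a local
measure; it is not comparable across references with very different
motif composition. The cutoff derivation needs tens of sub-cutoff
mutations to clear the 90%-excess rule, so samples with very few
clustered mutations are conservatively assigned no cutoff. The
housekeeping null's BH correction across iterations is extremely
conservative by construction (it mirrors the published procedure); its
minimum q is informative only at large iteration counts. CLI
subcommands cover the common paths; compound workflows are expected to
go through the Python API, as in `examples/`.
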