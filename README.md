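# rloopkat

Analysis toolkit for linking APOBEC3 mutagenesis to R-loops in somatic
mutation catalogs. It is written for cancer genomicists who have SBS
catalogs (VCF or MAF-like TSV), a reference FASTA, gene models, R-loop
intervals (BED, typically DRIP–seq peaks), SV breakpoints and
expression tables, and want to reproduce the computational backbone of
an R-loop mutagenesis study on their own cohort:

- **APOBEC enrichment** — per-sample score
  `E = (m_TCW · c_C) / (m_C · c_TCW)`, comparing TCW-motif mutation
  counts (m) against motif availability (c) within ±20 bp of each
  C>T/C>G mutation, with one-sided Fisher's exact tests and
  Benjamini–Hochberg correction across the cohort.
- **SBS96 signature refitting** — nonnegative least squares with
  iterative pruning; a sample is APOBEC-positive when
  weight(SBS2) + weight(SBS13) clears a detection threshold.
- **Kataegis detection** — sample-dependent intermutational-distance
  cutoffs calibrated against background simulations that preserve each
  mutation's ±2 bp sequence context and genic strand, with a 10 Mbp
  regional density correction, a <0.10 adjacent-VAF coherence filter,
  ≥3/≥5 size classes and SV-breakpoint partitioning at 10 kbp.
- **R-loop / strand association** — NTS/TS/intergenic labels against
  1 kbp-padded R-loop intervals, per-event RTCA vs YTCA enrichment
  (A3B-like vs A3A-like), and Mann–Whitney U comparisons of kataegic
  events against nonclustered controls with Cohen's d.
- **Cohort associations** — seven expression fold-change bins with
  APOBEC mutations per megabase of exon, Welch t-tests across bins,
  Wilcoxon strand-bias tests, splice-factor contingency statistics and
  a resampling null over housekeeping gene sets.
- **Synthetic cohorts** — a seeded generator that plants all of the
  above (TCW spectrum strength, kataegic tracts with RTCA:YTCA mix and
  VAF coherence, R-loops at gene 5′ ends, expression coupling, gene-set
  labels) with a truth manifest, so every stage has an exact recovery
  test.

## Worked example

```python
import rloopkat as rk

cfg = rk.SyntheticConfig(seed=3, n_samples=3)
ref, records, expression, truth = rk.simulate(cfg)

models, clusters = rk.detect_kataegis(records, ref.reference, ref.genes,
                                      ref.breakpoints, seed=4)
for sid, m in sorted(models.items()):
    print(sid, "IMD cutoff =", m.cutoff_bp, "bp")
for c in clusters:
    if c.size >= 5:
        print(c.sample_id, f"{c.chrom}:{c.positions[0]}", "size", c.size,
              c.size_class, "apobec", c.apobec_flag)
```

prints

```
S000 IMD cutoff = 1024 bp
S001 IMD cutoff = 1024 bp
S002 IMD cutoff = 2048 bp
S000 chr1:766192 size 7 kataegis_ge5 apobec True
S000 chr2:28115 size 5 kataegis_ge5 apobec True
S000 chr2:1055216 size 8 kataegis_ge5 apobec True
...
```

Each sample's cutoff (1–2 kbp at this mutation burden) is the largest
candidate at which ≥90% of sub-cutoff mutations exceed the
context-preserving simulated expectation with BH q < 0.01; the nine
planted tracts are recovered exactly, and `apobec True` means every
member is a TCW-context C>T or C>G. The scripts in `examples/` walk
through each capability the same way (simulation, enrichment scoring
and refitting, kataegis detection, R-loop/strand comparison, expression
bins and gene-set statistics), each printing the numbers it computes
and what they mean.

A thin CLI mirrors the library for shell use:

```bash
rloopkat simulate --seed 1 --out cohort/
rloopkat kataegis --mutations cohort/mutations.tsv --reference cohort/reference.fa \
    --genes cohort/genes.tsv --svs cohort/sv_breakpoints.tsv --seed 1 --out calls/
```

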