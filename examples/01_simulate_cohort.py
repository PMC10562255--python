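"""Generate a small synthetic tumor cohort and inspect its planted truth.

The generator emits a reference genome, gene models, R-loop intervals,
SV breakpoints, a mutation catalog with planted kataegic clusters, an
expression table and a truth manifest — everything downstream stages
need, with known ground truth.
"""

import rloopkat as rk

cfg = rk.SyntheticConfig(seed=1, n_chroms=1, chrom_length_bp=2_000_000,
                         n_genes=40, rloop_count=25, n_samples=3)
ref, records, expression, truth = rk.simulate(cfg)

print(f"genome: {cfg.n_chroms} x {cfg.chrom_length_bp/1e6:.0f} Mbp, "
      f"{len(ref.genes)} genes, {len(ref.rloops)} R-loop intervals")
print(f"cohort: {cfg.n_samples} samples, {len(records)} mutations "
      f"({sum(m.is_sbs for m in records)} SBS)")
print(f"planted clusters: {len(truth.clusters)} "
      f"(sizes {sorted(c.size for c in truth.clusters)})")
for cl in truth.clusters[:3]:
    print(f"  {cl.sample_id} {cl.chrom}:{cl.positions[0]}-{cl.positions[-1]}"
          f" size={cl.size} in_rloop={cl.in_rloop}")
# Each planted cluster records its member positions and RTCA/YTCA make-up,
# so recovery by the kataegis caller can be scored exactly.
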