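"""Score per-sample APOBEC TCW enrichment and refit signature weights.

E = (m_TCW * c_C) / (m_C * c_TCW) compares how often C>T/C>G mutations
hit TCW motifs against the local (+/-20 bp) availability of those
motifs; E ~ 1 under the null, rising with planted APOBEC signal.
"""

import numpy as np
import pandas as pd

import rloopkat as rk
from rloopkat.context_engine import SBS96_CHANNELS, build_sbs96
from rloopkat.signature_enrichment import refit_signatures

cfg = rk.SyntheticConfig(seed=2, n_chroms=1, chrom_length_bp=3_000_000,
                         n_genes=50, rloop_count=25, n_samples=3,
                         dispersed_rate=300, apobec_fraction=0.3,
                         clusters_per_sample=0)
ref, records, _, _ = rk.simulate(cfg)

results = rk.cohort_enrichment(records, ref.reference)
for r in results:
    print(f"{r.sample_id}: E={r.E:.2f} fisher_p={r.fisher_p:.2e} "
          f"q={r.bh_q:.2e} enriched={r.enriched}")
# With 30% of dispersed SBS forced into TCW, E sits well above 1 and
# every sample is called enriched (q < 0.05).

# Refit a two-signature mixture on the SBS96 catalog of the cohort.
rng = np.random.default_rng(0)
a = np.zeros(96); a[:48] = rng.dirichlet(np.ones(48))
b = np.zeros(96); b[48:] = rng.dirichlet(np.ones(48))
signatures = pd.DataFrame({"SBS2": a, "SBS5": b},
                          index=list(SBS96_CHANNELS))
catalog = pd.Series(rng.multinomial(10_000, 0.6 * a + 0.4 * b),
                    index=list(SBS96_CHANNELS))
w = refit_signatures(catalog, signatures)
print(f"refit weights: {w.weights.round(3).to_dict()} "
      f"(planted 0.6/0.4); apobec_weight={w.apobec_weight:.3f}")
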