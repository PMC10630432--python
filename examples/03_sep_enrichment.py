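"""Flag summer-export-pulse intervals and test copiotroph enrichment.

Simulates a noisy (multinomial, 1e5 reads/sample) trap time series in which
eight planted copiotroph ASVs are pulsed five-fold during summer intervals,
flags SEP intervals from particulate C/N flux (both >= 150% of the annual
reference means), and runs Welch's t test per ASV.
"""

import sasvtrace as st
from sasvtrace.sep import enrichment_frame

cfg = st.SimConfig(months=((2015, 1),), reads_per_sample=100_000, seed=0)
sim = st.simulate_dataset(cfg)

calendar = st.flag_sep(sim.flux, sim.trap_samples)
print(f"trap intervals: {len(calendar.table)}  "
      f"SEP: {len(calendar.sep_ids)}  non-SEP: {len(calendar.nonsep_ids)}")

results = st.enriched_sasvs(st.to_relative(sim.trap), calendar, alpha=0.05)
table = enrichment_frame(results)
enriched = table[table["enriched"]].sort_values("p_value")

print(f"\n{len(enriched)} ASVs significantly enriched during the SEP "
      f"(p < 0.05, mean_SEP > mean_non-SEP):")
cols = ["asv_id", "mean_sep", "mean_nonsep", "t_stat", "p_value"]
print(enriched[cols].head(10).to_string(index=False,
                                        float_format=lambda v: f"{v:.4g}"))

planted = set(sim.truth.sep_enriched_asvs)
found = set(enriched["asv_id"])
print(f"\nplanted pulsed copiotrophs recovered: "
      f"{len(planted & found)} of {len(planted)}")
print("Each enriched ASV's trap share rises when deep particle flux")
print("pulses - the signature of copiotroph growth on fresh summer export.")
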