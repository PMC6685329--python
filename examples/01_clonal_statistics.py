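"""Simulate Confetti-labelled tissue and recover the headline clonal statistics.

Simulates 30 sections of healthy left ventricle and 30 sections of infarct
border, calls clones (connected same-fluorophore components), and prints the
summary statistics the clone caller recovers: mean clone size, the fraction of
labelled cells that never divided, founder events per section, vessel
clonality, and the EdU proliferation index.
"""

import cloneatlas as ca

for preset, label in (("healthy", "healthy LV"), ("mi", "infarct border")):
    params = ca.tissue_preset(preset, seed=1, n_sections=30)
    tissue = ca.simulate_tissue(params)
    clones = ca.call_clones(tissue)
    stats = ca.clonal_stats(clones, tissue)
    print(f"\n=== {label} ({tissue.n_sections} sections, {len(tissue.labelled)} labelled EC) ===")
    print(f"clones: {stats.n_clones}, singletons: {stats.n_singletons} "
          f"-> {stats.founder_events_per_section_mean:.1f} founder events/section")
    print(f"cells per clone: {stats.mean_clone_size:.2f} +- {stats.sd_clone_size:.2f}")
    print(f"labelled cells still single: {100 * stats.singleton_fraction:.1f}%")
    print(f"monoclonal vessels: {100 * stats.monoclonal_vessel_fraction:.1f}% of classified")
    print(f"Confetti+ EdU+ (S-phase) fraction: {100 * stats.edu_confetti_fraction:.1f}%")
    print(f"recovered Cre-recombination efficiency: "
          f"{100 * ca.estimate_recombination_efficiency(tissue):.1f}%")

# Larger clones, a higher EdU index and fewer polychromatic vessels in the
# infarct border -- with an unchanged founder-event count -- is the signature
# of clonal expansion by resident endothelial cells rather than recruitment.
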