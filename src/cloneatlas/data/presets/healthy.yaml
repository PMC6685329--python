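# Healthy left-ventricle condition: published summary constants of the
# Confetti lineage-tracing experiment (21 days post-induction, no injury).
name: healthy
recombination_efficiency: 0.466
colour_probs: [0.519, 0.257, 0.113, 0.118]   # YFP, RFP, nGFP, mCFP
founder_density: 72.3            # recombination events per section
division_law:
  name: shifted_negative_binomial
  mean: 4.0                      # cells per clone (clones have >= 2 cells)
  sd: 2.1
single_cell_fraction: 0.546      # labelled cells that never divided
edu_window_fraction: 0.285       # EdU+ fraction of Confetti+ cells
edu_total_target: 0.0009         # EdU+ fraction of all cardiac cells
monoclonal_vessel_target: 0.745  # classified vessels that are monoclonal
background_cells_per_section: 40000
region: healthy
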