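# Infarct-border condition at 7 days post-MI (21 days post-induction).
name: mi
recombination_efficiency: 0.466
colour_probs: [0.529, 0.188, 0.265, 0.088]   # YFP, RFP, nGFP, mCFP (injured heart)
founder_density: 67.3
division_law:
  name: shifted_negative_binomial
  mean: 10.3
  sd: 10.6
single_cell_fraction: 0.634
edu_window_fraction: 0.585
edu_total_target: 0.019
monoclonal_vessel_target: 0.907
background_cells_per_section: 40000
region: border
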