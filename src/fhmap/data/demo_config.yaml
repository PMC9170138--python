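# Demo mapping cross: contig_1 carries the causal frameshift deletion at
# 5 Mb; contig_2 is an unlinked control. Marker densities reproduce the
# ~1:3 mutant:mapping unique-SNP imbalance of the real cross.
simulator:
  n_contigs: 2
  contig_length: 10000000
  lvg_marker_density: 100.0
  bio_marker_density: 300.0
  shared_site_density: 20.0
  conflict_site_density: 5.0
  expected_crossovers: 0.1
  n_f2_total: 300
  pool_size: 45
  mean_pool_depth: 30.0
  mean_parent_depth: 30.0
  genotype_error_rate: 0.001
  causal_contig: contig_1
  causal_position: 5000000
scan:
  window_size: 100
  hi: 0.9
  lo: 0.1
  min_pool_depth: 5
  min_parent_depth: 5
  min_windows: 1
filter:
  cluster_radius: 50
  max_neighbors: 1
  neighbor_background: all
  min_stops_all_frames: 2
phenotype:
  mutant_tau_h: 22.73
  wildtype_tau_h: 24.04
  n_days: 21
  noise_sd_h: 0.25
seed: 1
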