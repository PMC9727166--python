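# Default pipeline configuration: simulate a 4-lineage community with ten
# planted novel families and analyse it end to end.
seed: 42
outdir: npfkit_out
simulation:
  n_lineages: 4
  genomes_per_lineage: 5
  scaffolds_per_genome: 3
  genes_per_scaffold: 17
  ref_db_families: 30
  mutation_rate: 0.10
  indel_rate: 0.01
  novel_family_count: 10
thresholds:
  cluster_min_identity: 0.30
  cluster_max_evalue: 1.0e-3
  cluster_min_query_cov: 0.50
  conserved_score_cutoff: 0.90
  marker_specificity_cutoff: 0.70
  marker_coverage_cutoff: 0.70
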