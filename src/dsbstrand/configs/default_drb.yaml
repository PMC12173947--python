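seed: 0
bin_size: 50
chrom: chrS
margin: 20000
genes:
  n_genes: 60
  length_min: 90000
  length_max: 110000
  fraction_silent: 0.0
  expr_mu: 1.0
  expr_sigma: 0.75
  gap_min: 40000
  gap_max: 60000
  exon_min: 150
  exon_max: 400
  intron_min: 800
  intron_max: 3000
dsbs:
  contexts: {}
  cleavage_min: 0.1
  cleavage_max: 0.4
qdrip:
  background: 0.5
  baseline_amp: 0.3
  baseline_span: 1500
  hybrid_gain: 10.0
  decay_bp: 800.0
endseq:
  amplitude: 5.0
  mean_length_4h: 1000.0
  mean_length_24h: 3000.0
rpa:
  amplitude: 2.0
  span_factor: 2.0
  beta: 1.0
  boost_span: 500
rnapii:
  background: 0.2
  tss_amp: 5.0
  tss_sigma: 150.0
  body_amp: 0.5
  repression_g: 0.7
  eviction_e: 0.5
ttseq:
  background: 0.1
  body_amp: 1.0
  attenuation: 0.3
drb:
  rate_kb_min: 2.0
  rate_sd: 0.25
  times_min:
  - 5.0
  - 10.0
  - 20.0
  - 30.0
  - 40.0
  plateau: 20.0
  crest_amp: 40.0
  crest_sigma: 1500.0
  bin_size: 100
noise:
  enabled: true
  depth: 20.0
spike:
  mean_reads: 1000000
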