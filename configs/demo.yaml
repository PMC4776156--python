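# Demonstration run: a miniature 20 Mb genome (5 x 4 Mb chromosomes digested
# every ~2 kb) with 20,000 reads per replicate — sparse enough that site
# profiles resemble real viewpoint data — sized so the full pipeline
# completes in well under a minute.  Statistical validation runs use the
# larger fixed conditions in fourc.experiments.
seed: 20260922
sim:
  n_chromosomes: 5
  chromosome_length: 4000000
  inter_site_spacing: 2000
  reads_per_replicate: 20000
  error_rate: 0.001
qc:
  n_random_sets: 10
association:
  flank: 100000
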