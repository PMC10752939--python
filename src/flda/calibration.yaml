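# Default generative settings for the factorial synthetic benchmark.
#
# effect_size is the per-gene mean shift (+/-) carried by each informative
# gene block; block_fractions split the genes evenly across the feature-i,
# feature-j, interaction and noise blocks.
#
# Genes in the noise block emulate the high-dispersion genes of real
# expression data that vary strongly but carry no phenotype information:
# their noise SD is sqrt(baseline^2 + (multiplier * sigma)^2) instead of
# sigma, so an unsupervised embedding is drawn toward them while
# variance-normalizing supervised methods are not.
effect_size: 1.2
block_fractions:
  feature_i: 0.25
  feature_j: 0.25
  interaction: 0.25
  noise: 0.25
noise_block_sd_baseline: 6.0
noise_block_sigma_multiplier: 1.45
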