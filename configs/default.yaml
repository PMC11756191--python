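# Default synthetic "transformation" run: condition 1 emulates the
# indolent (CLL-like) state, condition 2 the transformed (DLBCL-like)
# state with TAD fusions, compartment switches, TAD compaction, steeper
# distance decay and stronger B-B contacts.
chrom_names: [chr1, chr2, chr3, chr4]
chrom_lengths: [50000000, 50000000, 50000000, 50000000]
bin_size: 100000          # working resolution (compartments, TADs)
coarse_bin_size: 1000000  # whole-genome differential heatmap

n_tads_per_chrom: 10
compartment_block_len: 10
decay_exponent: 1.0
compartment_delta: 0.6
tad_delta: 1.0
depth: 10000000
compartment_min_dist_bins: 20
orientation_noise_sd: 0.3

n_fusions: 4
n_switches: 40
insulation_attenuation: 0.3
decay_increase: 0.25
bb_boost: 1.3

n_genes: 2000
frac_up: 0.5
enrichment_odds: 5.0

ice_tol: 1.0e-5
ice_max_iter: 200
mad_max: 5.0
bins_per_decade: 8
saddle_quantiles: 20
saddle_trim: 0.02
corner_frac: 0.2
insulation_window: 5
boundary_strength_min: 0.1
min_tad_bins: 3
fusion_tol_bins: 1
deg_flank_bins: 1
ata_target_size: 30
pseudocount: null
seed: 1
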