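# Bi-directional lifetime-smoking <-> schizophrenia analysis recipe.
#
# The GWAS summary statistics themselves are not redistributed here; download
# them from their consortium release pages (see README, "Reproducing the
# published analysis") and point the two paths below at the local files.
# Column names are auto-detected for common layouts; override with
# exposure_columns / outcome_columns if your files use different headers.
#
# Run with:
#   smokemr run --config examples/headline_analysis.yaml --out-dir results/headline

exposure_path: data/lifetime_smoking_gwas.tsv      # continuous smoking index GWAS
outcome_path: data/schizophrenia_gwas.tsv          # case-control psychiatric GWAS
exposure_type: continuous
outcome_type: binary
exposure_n: 462690
outcome_n: 77096
direction: both

# instrument selection
p_threshold: 5.0e-8
clump_distance_kb: 10000
clump_r2: 0.001
ld_path: null            # optional pairwise r2 table; distance-only clumping without it

# harmonisation
maf_limit: 0.3           # palindromic SNPs kept only when both frequencies < 0.3
proxy_path: null         # optional proxy table for SNPs missing from the outcome
r2_min: 0.8              # minimum proxy LD

# estimation / sensitivity
random_effects: true
i2_simex_trigger: 0.9    # SIMEX-corrected Egger added when I2_GX falls below this
n_boot: 1000
steiger: true
seed: 2024
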