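# Annotated pipeline configuration template for `scatdiet all -c config.yaml`.
# CLI flags override config values; everything not listed keeps the
# published default (shown in comments).

simulate: true        # true: generate data; false: read the input paths below
n_species: 26         # reference database size when simulating
seed: 1               # master seed; every stage derives substreams from it

# --- simulation (SimConfig) ------------------------------------------------
sim:
  n_samples: 50
  misid_rate: 0.2917              # probability a field label names the wrong host
  reads_per_sample_mu: 9.903      # log-normal depth, ln(20000)
  reads_per_sample_sigma: 0.5
  substitution_error_rate: 0.002  # per-base substitution probability
  chimera_rate: 0.005             # per-read bimera probability
  contamination_fraction: 0.01    # expected human-read fraction
  control_fraction: 0.005         # positive-control spike fraction

# --- inputs for non-simulated runs ----------------------------------------
# reads_dir: path/to/reads          # per-sample FASTA files
# reference_fasta: path/to/ref.fasta
# lineage_table: path/to/lineage.tsv
# manifest_path: path/to/manifest.tsv
# hits_dir: path/to/hits            # start from precomputed BLAST-tabular hits
#                                   # (must contain queries.csv with cluster sizes)

# --- stage parameters (published defaults) ---------------------------------
min_cluster_size: 3   # dereplicated clusters below this size are dropped

denoise:
  alpha: 2.0          # skew exponent of beta(d) = 1 / 2^(alpha*d + 1)
  max_distance: null  # optional cap on the merge edit distance

chimera:
  min_parent_skew: 16.0   # both bimera parents must be this many times larger

assignment:
  bitscore_window: 0.02   # keep hits within 2% of the best bit-score
  min_coverage: 90.0      # % query coverage, inclusive
  min_identity: 98.0      # % identity, inclusive
  agreement: 0.80         # fraction of unique lineages that must agree

filters:
  noise_fraction: 0.001   # per-sample noise threshold (0.1% of total reads)
  min_reads: 100          # per-sample per-taxon minimum read threshold
  min_host_reads: 10      # host-identification read floor
  # contaminant_taxa: ["Homo sapiens"]
  # control_taxa: ["Maylandia zebra"]
  # candidate_hosts: ["Vulpes vulpes", "Martes martes"]
  # ambiguous_groups:            # species the marker cannot separate
  #   Anatidae: ["Anas platyrhynchos", "Anas crecca"]
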