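# Annotated run configuration for `emcap run`.
#
# Three workflow modes:
#   SAMPLE_DMR     - DMRs between samples (CpG coverage floor >= 5)
#   HAPLOTYPE_DMR  - phase het SNPs, split reads by haplotype, DMRs
#                    between alleles (coverage floor >= 3)
#   SNV_DMR        - split reads by somatic-SNV carrier status, DMRs
#                    between SNV+ and SNV- pools (coverage floor >= 3)
mode: HAPLOTYPE_DMR

# Seed for every source of randomness in the run.
seed: 7

# All outputs (bedGraph CpG tables, dmrs.bed, merged/selected TSVs,
# qc.json, report.json) are written here.
out_dir: emcap_demo

# Synthetic input. Omitted fields take the generator defaults
# (5 Mb genome, 40 targets, 30x, 5 kb N50, conversion 0.995/0.005,
# errors 1%/0.5%/0.5%, duplicate rate 0.1).
simulate:
  genome_length: 500000
  n_targets: 12
  coverage: 40
  n_somatic_snvs: 0
  snv_vaf: 0.0
  # planted allele-specific methylation: 3 regions of 20 CpGs with an
  # 80% methylation difference between haplotypes
  asm: {n_regions: 3, n_cpgs: 20, diff: 0.8}

# Optional TSS annotation (TSV: gene, chrom, pos, strand - or BED);
# when set, selected DMRs are restricted to +/- tss_window of a TSS.
# tss_file: tss.tsv

params:
  # phasing
  min_link: 2              # minimum |cis - trans| support per phase edge
  haplotag_mode: PHASED_ONLY   # or WITH_UNPHASED_SNPS
  # DMR calling
  # min_cov: 3             # override the mode's coverage floor
  max_gap: 300             # split candidate runs at larger CpG gaps (bp)
  min_cpgs: 10             # minimum CpGs per DMR
  min_diff: 0.1            # minimum |mean rate difference| per window
  q_cut: 0.01              # BH-adjusted significance cut
  # filter cascade
  any_pair_diff: 0.5       # keep intervals with max pairwise diff >= this
  tss_window: 10000        # +/- bp around a TSS
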