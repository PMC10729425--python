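"""Simulate a complete toy study and write it to disk.

Generates a 1-Mb genome with 100 genes, plants accessible chromatin regions
with condition-specific patterns across the four desiccation stages
(C, D1, D2, D3), simulates ATAC-like fragments for 12 samples, an expression
table coupled to accessibility, and noisy OJIP fluorescence transients.
"""

from thstools.synthetic_data import SimulationConfig, write_fixture

cfg = SimulationConfig(seed=1)
outdir = write_fixture(cfg, "scratch/example_fixture")

print(f"fixture written to {outdir}")
print(f"  genome: {cfg.n_chroms} x {cfg.chrom_len:,} bp, {cfg.n_genes} genes")
print(f"  samples: {len(cfg.conditions)} conditions x "
      f"{cfg.replicates_per_condition} replicates, "
      f"~{cfg.fragments_per_sample:,} fragments each")
print(f"  planted: {cfg.n_accessible_genes} accessible promoters + "
      f"{cfg.n_decoy_regions} intergenic regions, "
      f"{cfg.enrichment_fold:.0f}x insertion enrichment")
# The planted regions and their condition patterns are recorded in
# truth.json, so every downstream result can be scored against them.
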