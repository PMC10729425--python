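"""Discriminative promoter motif enrichment and PWM matching.

Extracts 3-kb promoters (upstream of the start codon) of genes with
accessible promoters, builds dinucleotide-shuffled negatives, finds
discriminatively enriched short words, and matches them to the bundled
plant transcription-factor PWM library.
"""

from thstools.motif_enrich import (
    dreme_enrich, extract_promoters, load_builtin_pwms, match_known_motifs,
    shuffle_negatives,
)
from thstools.synthetic_data import SimulationConfig, simulate_genome_and_genes

cfg = SimulationConfig(seed=5)  # plants TTGACC in 80% of accessible promoters
genome, genes, truth = simulate_genome_and_genes(cfg)

pos_genes = sorted({g for g, _, _ in truth.motif_positions
                    if g in set(truth.coupled_genes)})
promoters = extract_promoters(pos_genes, genes, genome)
negatives = shuffle_negatives(promoters, seed=cfg.seed)

motifs = dreme_enrich(promoters, negatives, max_motifs=3)
matches = match_known_motifs(motifs, load_builtin_pwms(), seed=cfg.seed)

print(f"{len(promoters)} positive promoters vs shuffled negatives")
for mo, ma in zip(motifs, matches):
    print(f"  {mo.word:10s} hits {mo.pos_hits}/{mo.n_pos} vs "
          f"{mo.neg_hits}/{mo.n_neg}  E={mo.evalue:.2e}  "
          f"best match {ma.pwm.name} ({ma.pwm.tf_name}), p={ma.p:.3f}")
# The top word should be the planted W-box TTGACC (or its reverse
# complement GGTCAA - both strands are scanned), matching the WRKY PWM.
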