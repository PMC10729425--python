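"""ATAC <-> RNA bipartite correlation network.

Builds gene-level accessibility fold-change profiles from the consensus
THSs, joins them with the expression table, and connects ATAC and RNA nodes
whose per-stage profiles lie within a squared-Euclidean distance of 0.01
after unit normalization (only ATAC-RNA pairs are evaluated).
"""

from thstools.atac_qc import make_insertion_track
from thstools.formats_io import CONDITIONS
from thstools.peakcall import PeakCallParams, call_peaks
from thstools.rna_integration import (
    correlation_network, gene_level_atac_fc, join_ths_expression,
    network_edge_list,
)
from thstools.synthetic_data import (
    SimulationConfig, simulate_expression, simulate_fragments,
    simulate_genome_and_genes,
)
from thstools.ths_dynamics import (
    annotate_ths, build_consensus, count_matrix, fold_change_matrix,
    reproducible_peaks,
)

cfg = SimulationConfig(seed=6, expr_coupling=0.99)
genome, genes, truth = simulate_genome_and_genes(cfg)
tracks = [
    make_insertion_track(f, genome)
    for f in simulate_fragments(cfg, truth, genome)
]
sample_peaks = {
    t.sample_id: call_peaks(t, PeakCallParams(), genome.lengths)
    for t in tracks
}
thss = build_consensus({
    c: reproducible_peaks(
        [sample_peaks[t.sample_id] for t in tracks if t.condition == c]
    )
    for c in CONDITIONS
})
counts = count_matrix(thss, tracks)
fc = fold_change_matrix(counts, {t.sample_id: t.condition for t in tracks})
annotated = annotate_ths(thss, genes)

expr = simulate_expression(cfg, truth, genes)
joined = join_ths_expression(gene_level_atac_fc(annotated, fc), expr)
G = correlation_network(joined, threshold=0.01, normalization="unit")

edges = network_edge_list(G)
self_edges = edges[edges["atac_gene"] == edges["rna_gene"]]
print(f"{len(joined.table)} genes carry both ATAC and RNA profiles")
print(f"network: {G.number_of_nodes()} nodes, {len(edges)} edges "
      f"({len(self_edges)} self-edges)")
print(f"coupled genes planted: {len(truth.coupled_genes)}")
# Self-edges (a gene matching its own expression) indicate accessibility
# tracking transcription; cross-gene edges mark co-varying profiles.
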