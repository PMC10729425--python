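"""Consensus THSs, Venn partitioning and genomic annotation.

Applies the replicate-reproducibility rule (>=2 replicates, >=50% overlap)
per condition, merges everything into consensus transposase hypersensitive
sites, partitions them by the exact set of stages in which they are
accessible, and annotates each against its nearest gene.
"""

from collections import Counter

from thstools.atac_qc import make_insertion_track
from thstools.formats_io import CONDITIONS
from thstools.peakcall import PeakCallParams, call_peaks
from thstools.synthetic_data import (
    SimulationConfig, simulate_fragments, simulate_genome_and_genes,
)
from thstools.ths_dynamics import (
    annotate_ths, build_consensus, reproducible_peaks, venn_partition,
)

cfg = SimulationConfig(seed=4)
genome, genes, truth = simulate_genome_and_genes(cfg)
tracks = [
    make_insertion_track(f, genome)
    for f in simulate_fragments(cfg, truth, genome)
]
sample_peaks = {
    t.sample_id: call_peaks(t, PeakCallParams(), genome.lengths)
    for t in tracks
}
condition_peaks = {
    c: reproducible_peaks(
        [sample_peaks[t.sample_id] for t in tracks if t.condition == c]
    )
    for c in CONDITIONS
}
thss = build_consensus(condition_peaks)
venn = venn_partition(thss)

print(f"{len(thss)} consensus THSs")
groups = Counter(t.stage_group for t in thss)
for group, n in sorted(groups.items()):
    print(f"  {group:22s} {n}")
print("nonzero Venn partitions:",
      {"+".join(k): v for k, v in venn.items() if v})

annotated = annotate_ths(thss, genes)
cats = Counter(a.category for a in annotated)
print("feature categories:", dict(cats))
# Stage groups name the desiccation transitions (watered-unique,
# watered->moderate, watered->severe, severe->dry, constitutive); feature
# categories locate each THS relative to its nearest gene.
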