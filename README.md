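# thstools

Chromatin-accessibility dynamics across a staged desiccation time course.

Resurrection plants survive nearly complete dehydration, and the switch into
the protected state is driven by transcriptional reprogramming: regulatory
regions open and close as the leaf dries. ATAC-seq (Tn5 transposase
insertion into nucleosome-free DNA) reads this out as *transposase
hypersensitive sites* (THSs). `thstools` is a Python library for the
downstream analysis of such an experiment sampled at four physiological
stages — watered control (C) and moderate (D1, ~50% RWC), severe (D2, ~20%
RWC) and full (D3, ~6% RWC) desiccation — with three replicates per stage.
It is aimed at computational biologists who want every step of that analysis
as a testable, scriptable unit rather than a chain of external tools.

The pipeline covers:

- **Stage gating** of leaf samples from fast chlorophyll-*a* fluorescence
  (OJIP) transients with a two-layer hexagonal self-organizing map: a
  Kohonen prototype lattice plus a label layer with nodes assigned to the
  four stages.
- **QC surfaces**: Tn5-corrected insertion tracks (+4/−5 end offsets),
  fragment-length histograms (nucleosome periodicity), strand-oriented TSS
  enrichment profiles, and the replicate correlation clustergram
  (Pearson on log2(x+1) counts, average-linkage on 1−r).
- **Peak calling** per sample: each insertion is shifted and extended
  (shift −100, extsize 200) into a pileup; position-wise significance is the
  Poisson upper tail `p = P(X ≥ c)` against a local rate
  `λ_local = max(λ_genome, λ_1k, λ_5k, λ_10k)`, with Benjamini–Hochberg
  control over candidate positions.
- **Consensus THSs**: peaks kept only if reproducible in ≥2 replicates
  (≥50% overlap), merged across conditions; each THS carries per-condition
  presence, its exact Venn partition, and a named stage group
  (watered-unique, watered→moderate, watered→severe, severe→dry,
  constitutive).
- **Annotation** against gene models: nearest gene by strand-aware TSS
  distance, categories Promoter (≤1 kb / 1–2 kb / 2–3 kb), 5′UTR, exon,
  intron, downstream ≤1 kb, distal intergenic; plus a generic
  hypergeometric term over-representation test.
- **Promoter motif enrichment** (discriminative, DREME-style): exact words
  of 3–8 bp in 3-kb windows upstream of the start codon, one-sided Fisher
  exact on per-sequence hits versus dinucleotide-shuffled negatives, IUPAC
  generalization, E-value = p × words tested, iterative masking; discovered
  words are matched to a bundled plant TF PWM library (W-box/WRKY, ABRE,
  G-box, MYB, homeodomain, C2H2, GATA, NAC) by maximal ungapped log-odds
  alignment.
- **Expression integration**: a bipartite correlation network with one ATAC
  node and one RNA node per gene; nodes are connected when the squared
  Euclidean distance of their per-stage log2 fold-change profiles (unit
  normalized) is below 0.01. Only ATAC–RNA pairs are evaluated.
- **Synthetic data** with planted ground truth (accessible regions with
  condition patterns, nucleosome-periodic fragment lengths, planted promoter
  motifs, coupled expression, prototype OJIP transients), so every stage is
  scored against a known answer key.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_consensus_dynamics.py` (simulate → peaks →
reproducibility filter → consensus → annotation) prints:

```
60 consensus THSs
  constitutive           7
  other                  21
  severe_to_dry          8
  watered_to_moderate    8
  watered_to_severe      8
  watered_unique         8
nonzero Venn partitions: {'C': 8, 'D1': 7, 'D2': 7, 'D3': 7, 'C+D1': 8, 'D2+D3': 8, 'C+D1+D2': 8, 'C+D1+D2+D3': 7}
feature categories: {'DistalIntergenic': 7, 'Promoter<=1kb': 48, 'Promoter1-2kb': 5}
```

All 60 planted accessible regions (48 promoter-proximal + 12 intergenic)
are recovered, the Venn partition matches the planted condition patterns
(the "other" group collects the stage-unique D1/D2/D3 patterns that have no
named transition), and annotation places the promoter regions in the ≤1 kb
bin. `python examples/05_motif_enrichment.py` then recovers the planted
W-box element from those promoters:

```
38 positive promoters vs shuffled negatives
  AAGGTCAA   hits 38/38 vs 4/38  E=1.25e-12  best match WBOX_WRKY (WRKY24), p=0.017
```

(`AAGGTCAA` is the reverse complement of the planted `TTGACCTT`; both
strands are scanned and one spelling is reported.)

The same stages are available as a CLI for shell use — `thstools simulate`,
`classify-stage`, `qc`, `callpeaks`, `consensus`, `annotate`, `motifs`,
`integrate`, `enrich`, and `run-all` (single YAML config, manifest with
output checksums, deterministic reruns).

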