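# Methods

This note records the models implemented in `thstools`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that pin down edge cases.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention). GFF3 is
converted at the parsing boundary (1-based closed → half-open) and nowhere
else. The TSS is the gene span start on the + strand and `end − 1` on the −
strand; the start codon is anchored on the CDS features of the gene's first
mRNA (file order), and a gene without CDS is rejected rather than guessed.
narrowPeak stores p and q as −log10 values printed with 17 significant
digits, so scores round-trip exactly and q-values to ~1e-16 relative.

## Stage classification (OJIP SOM)

Fast-fluorescence transients are sampled on a log-time grid (10 µs – 1 s,
118 points). Curves are min–max normalized per curve before training —
fluorescence amplitude depends on leaf optics, so only transient shape is
classified. The map is a pointy-top hexagonal lattice (default 4×4) trained
with classical online Kohonen updates: Euclidean best-matching unit,
Gaussian neighbourhood on the lattice, learning rate decaying linearly
0.5 → 0.01 over 500 epochs, neighbourhood radius 2.0 → 0.5 for grids ≥3×3.
A minimal 2×2 map instead uses a sub-unit radius schedule (0.4 → 0.2): a
Gaussian wider than the whole lattice drags all four prototypes together
and leaves dead units. The "two layers" are the prototype lattice and the
label layer: after training, each node takes the majority stage of its
mapped training curves (ties toward the earlier stage in C < D1 < D2 < D3;
empty nodes inherit the nearest labelled prototype's stage). Classification
returns the BMU's label with deterministic (row, col) tie-breaking, and is
asserted in tests to agree with a brute-force nearest-prototype scan.
Supervised-before-training node labelling is a plausible alternative
reading of "predefined nodes"; post-hoc majority labelling was chosen as
the standard construction.

## Insertion tracks and QC

Each fragment yields two insertion events: `start + 4` and `end − 1 − 5`
(the standard Tn5 stagger correction). The +2/−2 convention is available
through the offset arguments, since observed read shifts are sometimes
reported that way; neither is asserted as the only valid correction.
Out-of-bounds events are clipped and counted. The TSS profile collects
insertions on strand-oriented coordinates (upstream negative) in a ±2 kb
window; the enrichment ratio is the mean over [−50, +50] divided by the
mean over the outer 100 bp of each flank — the flank width is a pinned
convention, not a measured quantity. The replicate clustergram computes
Pearson correlation on log2(x+1)-transformed per-THS counts ("log2
transformed Pearson correlation" is read as correlation *of logged counts*;
log2 of a negative correlation coefficient would be undefined) and orders
leaves by average-linkage clustering on 1 − r.

## Peak calling

Each insertion at position p contributes +1 over
`[p − 100, p + 100)` (shift −100, extsize 200), so coverage counts
insertions within 100 bp. Significance at a position with coverage c is the
Poisson upper tail `P(X ≥ c; λ_local)` with
`λ_local = max(λ_genome, λ_1kb, λ_5kb, λ_10kb)` estimated from the same
pileup (window means, edge-truncated; the genome-wide rate is always
included as a floor so empty regions never produce λ = 0). Multiple testing
is handled over *candidate positions* — the leftmost position of each
coverage run that is a strict local maximum — rather than every base: BH
over the m candidate p-values yields k passing candidates, and every
position with `p ≤ α·k/m` (the BH threshold line) is marked significant.
This is a desk-scale simplification of per-base FDR control; it is exact at
the candidates and conservative between them. Significant positions are
merged across gaps ≤30 bp, peaks shorter than extsize/2 are dropped, the
summit is the leftmost coverage argmax, the score is −log10 p at the summit
(capped at 999), and the summit q-value is read off the candidate BH step
function. The effective genome size is always the true (toy) genome length;
an organism preset would be meaningless here.

## Consensus THSs and dynamics

A peak is reproducible if ≥2 replicates support it, where a replicate
supports a peak when some peak there overlaps ≥50% *of the tested peak's
length* (asymmetric denominator — the weaker, more inclusive reading of a
bare "minimal overlap 50%"; a reciprocal mode is available). The retained
peaks together with their qualifying supporters are union-merged into
condition-level peaks, so a reproducible region spans all the evidence that
made it reproducible. Union-merge treats abutting half-open intervals as
one region (they are contiguous base runs). Consensus THSs are the
cross-condition union; presence in a condition requires ≥1 bp overlap with
that condition's peaks. Each THS is assigned its exact partition (one of
the 15 nonempty stage subsets; counts always sum to the THS total) and a
stage group: {C} watered-unique, {C,D1} watered→moderate, {C,D1,D2}
watered→severe, {D2,D3} severe→dry, all four constitutive, anything else
"other".

Counts are raw insertions within the THS interval per sample; fold changes
are computed on CPM-normalized counts, averaged within condition, as
`log2((x_cond + 1)/(x_C + 1))` (pseudocount 1; both normalization and
pseudocount are pinned conventions).

Annotation anchors each THS at its midpoint (consensus intervals have no
single summit), picks the nearest gene by strand-aware signed TSS distance
(negative = upstream; ties to the lexicographically smaller gene id), and
categorizes with priority: first-exon-upstream-of-start-codon → 5′UTR;
exon; intron; upstream bins (0,1], (1,2], (2,3] kb → the three promoter
categories; ≤1 kb past the strand-aware gene end → downstream; otherwise
distal intergenic.

Term enrichment is a plain hypergeometric upper tail per term with BH
across terms; term content is user-supplied (ontology databases are out of
scope).

## Motif enrichment

Promoters are the 3000 bp upstream of the start codon on the coding strand
(clipped at contig edges, with the clip recorded). Negatives default to
per-sequence dinucleotide shuffles (Altschul–Erickson Eulerian-path
shuffle; exact dinucleotide counts preserved, seeded). Candidate exact
words (3–8 bp, present in ≥2 positives, both strands by default) are scored
by the one-sided Fisher exact test on per-sequence binary hits, computed as
the hypergeometric tail of the 2×2 table. The best word is generalized one
position at a time over IUPAC codes, each step accepted only if p strictly
improves. The E-value multiplies p by the number of distinct exact words
actually tested that round (reported alongside, for transparency); motifs
are emitted while E < 0.05, matched sites are masked to N in the positives,
and the scan repeats (≤10 motifs). Matching against the bundled plant PWM
library maximizes the ungapped log-odds alignment score over offsets and
strands (PWM columns outside the overlap behave as background); the match
p-value is empirical, from 1000 seeded column-shuffles of the word matrix
scored against the same library.

With 3-kb windows and binary per-sequence hits, any 6-mer is present in
most sequences by chance, so a planted element must be ≥8 bp to be
discoverable at desk scale; the simulator therefore plants an 8-bp
W-box-containing word (`TTGACCTT`) by default.

## Expression integration

Gene-level ATAC profiles are the mean THS fold-change profile of each
nearest gene; the expression table carries log2 fold changes for D1–D3
versus C. After an inner join, every gene contributes an ATAC node and an
RNA node. Profiles are scaled to unit Euclidean norm by default, and an
edge connects an ATAC node to an RNA node when the squared distance is
below 0.01. The raw-scale reading of that threshold is preserved as
`normalization="raw"`, but unnormalized log2 profiles essentially never
fall within 0.01 of each other except degenerately, so unit scaling is the
default that makes the threshold meaningful. All-zero profiles (e.g.
constitutively accessible genes, whose fold-change profile is identically
0) cannot be unit-scaled and are excluded with a warning. ATAC–ATAC and
RNA–RNA pairs are never evaluated; both self- and cross-gene ATAC–RNA pairs
are. Enriched motifs are linked to expression via the matched PWM's TF
name; motifs whose TF is absent from the table keep a missing-profile flag.

## Synthetic data

The generator emulates the study design: 4 stages × 3 replicates, a 1-Mb
uniform-ACGT genome with 100 two-exon genes laid out with ≥4 kb upstream
clearance (3-kb promoters never truncate), 48 accessible 300-bp regions
centred 200 bp upstream of TSSs plus 12 intergenic ones, with condition
patterns cycling through the named transitions and the stage-unique sets.
Fragment lengths mix a nucleosome-free component (normal, mean 60 bp) with
mono/di/tri-nucleosomal components at multiples of 180 bp (weights
0.45/0.30/0.15/0.10), reproducing the qualitative periodic decay of ATAC
libraries; midpoints fall in regions accessible in the sample's condition
20× more densely than background; per-sample totals are
Poisson(20 000) — sized so the full pipeline runs in well under ten
minutes on one CPU. Expression profiles of accessible-promoter genes equal
their accessibility log2 fold-change profile plus Gaussian noise with sd
`4.0 × (1 − expr_coupling)` (4.0 ≈ log2 of the enrichment fold, so coupling
spans exact to uninformative); other genes are independent noise. OJIP
prototypes are monotone sums of three logistic steps (J, I, P at 2, 30,
300 ms) whose weights shift from P-heavy (watered) to J-heavy (dry) —
mirroring the collapse of the late fluorescence rise with desiccation —
with multiplicative Gaussian noise (default sd 5%).

One global seed fans out to fixed per-stage child seeds, so individual
stages rerun identically in isolation.

What the generator does **not** emulate: sequence composition bias, Tn5
insertion sequence preference, mappability, duplicate reads, organellar
contamination, cross-species alignment loss, overdispersed replicate
variability, or genes with multiple isoforms. Passing tests therefore show
algorithmic correctness under the assumed statistical structure, not
robustness to every artefact of real libraries.

## Known limitations

- BH over candidate maxima is not per-base FDR control; with very ragged
  coverage the boundary of a peak can be slightly conservative.
- The discriminative motif statistic (binary per-sequence hits) loses power
  for short words in long windows; site-count statistics are not
  implemented.
- The PWM match null (column shuffles) is coarse for near-palindromic
  words.
- Hierarchical-clustering leaf order is deterministic but
  linkage-tie-dependent; only cluster membership, not order, should be
  interpreted.
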