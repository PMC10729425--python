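"""ATAC quality-control surfaces.

Tn5-corrected insertion tracks, fragment-length histograms (nucleosome
periodicity), TSS enrichment profiles and the replicate correlation
clustergram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats_io import FragmentSet, GeneModel, Genome

#: Standard Tn5 correction: the transposase cuts with a 9-bp stagger, so the
#: + strand end is shifted +4 and the − strand end −5 to centre insertions.
DEFAULT_PLUS_OFFSET = 4
DEFAULT_MINUS_OFFSET = -5


@dataclass
class InsertionTrack:
    """Per-bp Tn5 insertion events of one sample (both fragment ends)."""

    sample_id: str
    condition: str
    replicate: int
    positions: dict[str, np.ndarray]  # chrom -> sorted int positions
    n_clipped: int = 0

    @property
    def n_insertions(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class TSSProfile:
    """Strand-oriented insertion signal around TSSs (upstream negative)."""

    window: int
    offsets: np.ndarray  # -window .. +window
    mean_signal: np.ndarray  # insertions per gene per bp
    per_gene_matrix: np.ndarray  # genes x positions
    gene_ids: list[str]
    enrichment_ratio: float
    n_clipped_genes: int = 0


def make_insertion_track(
    frags: FragmentSet,
    genome: Genome,
    plus_offset: int = DEFAULT_PLUS_OFFSET,
    minus_offset: int = DEFAULT_MINUS_OFFSET,
) -> InsertionTrack:
    """Convert fragments to single-bp insertion events.

    Each fragment yields two events: ``start + plus_offset`` and
    ``end − 1 + minus_offset``.  Out-of-bounds events are clipped to the
    chromosome and counted in ``n_clipped``.
    """
    lengths = genome.lengths
    n_clipped = 0
    out: dict[str, list[int]] = {}
    for chrom, pairs in frags.by_chrom().items():
        L = lengths[chrom]
        left = pairs[:, 0] + plus_offset
        right = pairs[:, 1] - 1 + minus_offset
        both = np.concatenate([left, right])
        oob = (both < 0) | (both >= L)
        n_clipped += int(oob.sum())
        out[chrom] = np.clip(both, 0, L - 1)
    positions = {c: np.sort(v).astype(np.int64) for c, v in out.items()}
    return InsertionTrack(
        frags.sample_id, frags.condition, frags.replicate, positions, n_clipped
    )


def fragment_length_histogram(
    frags: FragmentSet, bin_size: int = 10, max_len: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_edges, counts) of fragment lengths; counts sum to n fragments."""
    lengths = np.array([e - s for _, s, e in frags.fragments], dtype=np.int64)
    if max_len is None:
        max_len = int(lengths.max()) + bin_size if len(lengths) else bin_size
    edges = np.arange(0, max_len + bin_size, bin_size)
    counts, _ = np.histogram(np.clip(lengths, 0, edges[-1] - 1), bins=edges)
    return edges, counts


def tss_profile(
    track: InsertionTrack,
    genes: list[GeneModel],
    window: int = 2000,
    chrom_lens: dict[str, int] | None = None,
) -> TSSProfile:
    """Per-gene insertion signal on strand-oriented TSS-relative coordinates.

    The enrichment ratio is the mean signal over [−50, +50] divided by the
    mean over the two outer 100-bp flanks ([−window, −window+100] and
    [window−100, window]); an all-zero profile has ratio 0.
    """
    if not genes:
        raise ValueError("need at least one gene")
    width = 2 * window + 1
    matrix = np.zeros((len(genes), width), dtype=np.int64)
    n_clipped_genes = 0
    for gi, g in enumerate(genes):
        pos = track.positions.get(g.chrom)
        L = chrom_lens.get(g.chrom) if chrom_lens else None
        if g.tss - window < 0 or (L is not None and g.tss + window >= L):
            n_clipped_genes += 1
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, g.tss - window, side="left")
        hi = np.searchsorted(pos, g.tss + window, side="right")
        rel = pos[lo:hi] - g.tss
        if g.strand == "-":
            rel = -rel
        matrix[gi] = np.bincount(rel + window, minlength=width)
    mean_signal = matrix.mean(axis=0)
    offsets = np.arange(-window, window + 1)
    center = mean_signal[np.abs(offsets) <= 50].mean()
    flank = mean_signal[np.abs(offsets) >= window - 100].mean()
    if flank > 0:
        ratio = float(center / flank)
    else:
        ratio = 0.0 if center == 0 else float("inf")
    return TSSProfile(
        window, offsets, mean_signal, matrix, [g.gene_id for g in genes],
        ratio, n_clipped_genes,
    )


def sample_correlation_clustergram(
    count_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pearson correlation of log2(x+1) counts plus average-linkage ordering.

    Returns (correlation matrix, leaf order, linkage matrix).  Zero-variance
    samples are excluded with a warning (their correlation is undefined).
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    logged = np.log2(count_matrix.astype(float) + 1.0)
    keep = [c for c in logged.columns if logged[c].std(ddof=0) > 0]
    dropped = [c for c in logged.columns if c not in keep]
    if dropped:
        warnings.warn(f"zero-variance sample(s) excluded: {dropped}")
    logged = logged[keep]
    if logged.shape[1] < 2:
        raise ValueError("fewer than two samples with nonzero variance")
    corr = np.corrcoef(logged.to_numpy().T)
    # exact symmetry/diagonal, robust to floating noise
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=keep, columns=keep)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    Z = hierarchy.linkage(dist, method="average")
    order = [keep[i] for i in hierarchy.leaves_list(Z)]
    return corr_df, order, Z
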