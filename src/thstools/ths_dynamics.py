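"""Consensus THSs and their cross-stage dynamics.

Replicate-reproducibility filtering of per-sample peaks, the merged
consensus set of transposase hypersensitive sites (THSs), per-condition
presence and Venn partitioning into named desiccation transitions, the
THS × sample insertion-count and fold-change matrices, genomic-feature
annotation against gene models, and a generic hypergeometric term
over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atac_qc import InsertionTrack
from .formats_io import CONDITIONS, GeneModel, Peak

#: Mapping from exact accessibility partition to the named stage group.
STAGE_GROUPS: dict[frozenset, str] = {
    frozenset({"C"}): "watered_unique",
    frozenset({"C", "D1"}): "watered_to_moderate",
    frozenset({"C", "D1", "D2"}): "watered_to_severe",
    frozenset({"D2", "D3"}): "severe_to_dry",
    frozenset({"C", "D1", "D2", "D3"}): "constitutive",
}

CATEGORIES = (
    "Promoter<=1kb", "Promoter1-2kb", "Promoter2-3kb", "5UTR", "Exon",
    "Intron", "Downstream<=1kb", "DistalIntergenic",
)


def stage_group_of(partition: frozenset) -> str:
    return STAGE_GROUPS.get(frozenset(partition), "other")


@dataclass
class THS:
    """A consensus accessible interval with per-condition presence."""

    chrom: str
    start: int
    end: int
    presence: dict[str, bool]
    source_peaks: dict[str, Peak] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(self.presence.values()):
            raise ValueError("THS must be present in at least one condition")

    @property
    def partition(self) -> frozenset:
        return frozenset(c for c, v in self.presence.items() if v)

    @property
    def stage_group(self) -> str:
        return stage_group_of(self.partition)

    @property
    def ths_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class AnnotatedTHS:
    ths: THS
    category: str
    gene_id: str
    tss_distance: int  # signed, negative = upstream (strand-aware)


@dataclass
class EnrichmentResult:
    term: str
    k: int  # hits in foreground
    K: int  # hits in background
    n: int  # foreground size
    N: int  # background size
    p: float
    q: float


# ---------------------------------------------------------------------------
# reproducibility filtering and consensus
# ---------------------------------------------------------------------------

def _overlap(a: Peak, b: Peak) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reproducible_peaks(
    replicate_peaks: Sequence[Sequence[Peak]],
    min_reps: int = 2,
    min_overlap_frac: float = 0.5,
    reciprocal: bool = False,
) -> list[Peak]:
    """Replicate-reproducibility filter followed by a union merge.

    A peak is retained iff it is supported by at least ``min_reps``
    replicates (itself included): a replicate supports it when some peak
    there overlaps it by at least ``min_overlap_frac`` of the *tested*
    peak's length (asymmetric rule; set ``reciprocal`` for the symmetric
    reading requiring the fraction of both peak lengths).  Retained peaks
    and their qualifying supporters are then merged by interval union into
    condition-level peaks, so the merged peak spans all the evidence that
    made the region reproducible.
    """
    if min_reps > len(replicate_peaks):
        raise ValueError("min_reps exceeds the number of replicates")
    pool: list[Peak] = []
    for i, peaks in enumerate(replicate_peaks):
        for p in peaks:
            support = 1
            supporters: list[Peak] = []
            for j, others in enumerate(replicate_peaks):
                if j == i:
                    continue
                found = False
                for q in others:
                    ov = _overlap(p, q)
                    if ov >= min_overlap_frac * p.length and (
                        not reciprocal or ov >= min_overlap_frac * q.length
                    ):
                        found = True
                        supporters.append(q)
                if found:
                    support += 1
            if support >= min_reps:
                pool.append(p)
                pool.extend(supporters)
    return merge_peaks(pool)


def merge_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Union-merge overlapping peaks; the merged peak inherits summit/score
    of its highest-scoring source and the smallest q-value."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        current: list[Peak] = []
        cur_end = -1
        for p in group:
            if current and p.start <= cur_end:  # overlapping or abutting
                current.append(p)
                cur_end = max(cur_end, p.end)
            else:
                if current:
                    merged.append(_fuse(chrom, current))
                current = [p]
                cur_end = p.end
        if current:
            merged.append(_fuse(chrom, current))
    return merged


def _fuse(chrom: str, group: list[Peak]) -> Peak:
    start = min(p.start for p in group)
    end = max(p.end for p in group)
    best = max(group, key=lambda p: p.score)
    return Peak(chrom, start, end, best.summit, best.score,
                min(p.qvalue for p in group))


def build_consensus(
    condition_peaks: Mapping[str, Sequence[Peak]],
) -> list[THS]:
    """Union-merge condition-level peaks into consensus THSs.

    A THS is present in a condition iff any of that condition's peaks
    overlaps the merged interval by at least 1 bp.
    """
    all_peaks = [p for peaks in condition_peaks.values() for p in peaks]
    merged = merge_peaks(all_peaks)
    thss: list[THS] = []
    for m in merged:
        presence = {
            cond: any(
                p.chrom == m.chrom and _overlap(p, m) >= 1 for p in peaks
            )
            for cond, peaks in condition_peaks.items()
        }
        for cond in CONDITIONS:
            presence.setdefault(cond, False)
        thss.append(THS(m.chrom, m.start, m.end, presence))
    return thss


# ---------------------------------------------------------------------------
# Venn partitioning
# ---------------------------------------------------------------------------

def venn_partition(thss: Sequence[THS]) -> dict[tuple[str, ...], int]:
    """Counts per exact accessibility partition (all 15 nonempty subsets of
    the four conditions are keys; counts sum to len(thss))."""
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, 5):
        from itertools import combinations

        for combo in combinations(CONDITIONS, r):
            counts[combo] = 0
    for t in thss:
        key = tuple(c for c in CONDITIONS if c in t.partition)
        counts[key] += 1
    return counts


# ---------------------------------------------------------------------------
# count and fold-change matrices
# ---------------------------------------------------------------------------

def count_matrix(
    thss: Sequence[THS], tracks: Sequence[InsertionTrack]
) -> pd.DataFrame:
    """THS × sample matrix of insertion counts within each THS interval."""
    data = np.zeros((len(thss), len(tracks)), dtype=np.int64)
    for j, tr in enumerate(tracks):
        for i, t in enumerate(thss):
            pos = tr.positions.get(t.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, t.start, side="left")
            hi = np.searchsorted(pos, t.end, side="left")
            data[i, j] = hi - lo
            t.counts[tr.sample_id] = int(hi - lo)
    df = pd.DataFrame(
        data, index=[t.ths_id for t in thss],
        columns=[tr.sample_id for tr in tracks],
    )
    df.index.name = "ths_id"
    return df


def fold_change_matrix(
    counts: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    baseline: str = "C",
) -> pd.DataFrame:
    """Per-condition log2 fold change of CPM-normalized counts vs baseline.

    CPM normalization per sample, condition means, then
    log2((mean_cond + 1) / (mean_baseline + 1)).  Columns are the
    non-baseline conditions in stage order.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        warnings.warn("sample(s) with zero total counts; CPM left as zeros")
        totals = totals.replace(0, 1.0)
    cpm = counts.astype(float) / totals * 1e6
    cond_means = {}
    for cond in CONDITIONS:
        cols = [s for s in counts.columns if sample_conditions[s] == cond]
        if cols:
            cond_means[cond] = cpm[cols].mean(axis=1)
    if baseline not in cond_means:
        raise ValueError(f"no samples for baseline condition {baseline!r}")
    base = cond_means[baseline]
    out = {
        cond: np.log2((m + 1.0) / (base + 1.0))
        for cond, m in cond_means.items()
        if cond != baseline
    }
    fc = pd.DataFrame(out, index=counts.index)
    fc.index.name = counts.index.name
    return fc


# ---------------------------------------------------------------------------
# genomic-feature annotation
# ---------------------------------------------------------------------------

def _signed_tss_distance(mid: int, gene: GeneModel) -> int:
    """Strand-aware distance of a point from the TSS; negative = upstream."""
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def categorize(mid: int, gene: GeneModel) -> str:
    """Feature category of a point relative to one gene (priority rules)."""
    d = _signed_tss_distance(mid, gene)
    if gene.start <= mid < gene.end:
        in_exon = any(s <= mid < e for s, e in gene.exons)
        if in_exon:
            first = gene.first_exon
            in_first = first[0] <= mid < first[1]
            upstream_of_codon = (
                mid < gene.start_codon if gene.strand == "+"
                else mid > gene.start_codon
            )
            return "5UTR" if in_first and upstream_of_codon else "Exon"
        return "Intron"
    if -1000 <= d < 0:
        return "Promoter<=1kb"
    if -2000 <= d < -1000:
        return "Promoter1-2kb"
    if -3000 <= d < -2000:
        return "Promoter2-3kb"
    # downstream: within 1 kb past the strand-aware gene end
    if gene.strand == "+" and gene.end <= mid < gene.end + 1000:
        return "Downstream<=1kb"
    if gene.strand == "-" and gene.start - 1000 <= mid < gene.start:
        return "Downstream<=1kb"
    return "DistalIntergenic"


def annotate_ths(
    thss: Sequence[THS], genes: Sequence[GeneModel]
) -> list[AnnotatedTHS]:
    """Annotate each THS against its nearest gene.

    The anchor is the THS midpoint; the nearest gene is chosen by absolute
    strand-aware TSS distance (ties toward the smaller gene id), and the
    category follows the priority rules of :func:`categorize`.
    """
    if not genes:
        raise ValueError("need at least one gene")
    genes = sorted(genes, key=lambda g: g.gene_id)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[AnnotatedTHS] = []
    for t in thss:
        cands = by_chrom.get(t.chrom, genes)
        mid = t.midpoint
        dists = [abs(_signed_tss_distance(mid, g)) for g in cands]
        best = min(dists)
        gene = next(g for g, d in zip(cands, dists) if d == best)
        out.append(
            AnnotatedTHS(t, categorize(mid, gene), gene.gene_id,
                         _signed_tss_distance(mid, gene))
        )
    return out


def annotation_to_frame(annotated: Sequence[AnnotatedTHS]) -> pd.DataFrame:
    rows = [
        {
            "ths_id": a.ths.ths_id,
            "chrom": a.ths.chrom,
            "start": a.ths.start,
            "end": a.ths.end,
            "partition": "+".join(c for c in CONDITIONS if c in a.ths.partition),
            "stage_group": a.ths.stage_group,
            "category": a.category,
            "gene_id": a.gene_id,
            "tss_distance": a.tss_distance,
        }
        for a in annotated
    ]
    return pd.DataFrame(rows).set_index("ths_id")


# ---------------------------------------------------------------------------
# term enrichment (generic hypergeometric layer)
# ---------------------------------------------------------------------------

def term_enrichment(
    foreground: set[str],
    background: set[str],
    term_map: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation of user-supplied terms.

    For each term with K annotated genes in the background of size N and k
    of them among the n foreground genes, p = P(X ≥ k), X ~
    Hypergeom(N, K, n); q is Benjamini–Hochberg across the tested terms.
    Terms absent from foreground and background are skipped with a warning.
    """
    fg = foreground & background
    N, n = len(background), len(fg)
    tested: list[tuple[str, int, int, float]] = []
    for term, genes in term_map.items():
        K = len(genes & background)
        if K == 0:
            warnings.warn(f"term {term!r} has no genes in the background; skipped")
            continue
        k = len(genes & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, K, min(p, 1.0)))
    if not tested:
        return []
    qvals = stats.false_discovery_control([t[3] for t in tested], method="bh")
    return [
        EnrichmentResult(term, k, K, n, N, p, float(q))
        for (term, k, K, p), q in zip(tested, qvals)
    ]
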