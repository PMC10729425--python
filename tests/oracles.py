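"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, per-base sets, direct tail summation) and shares no code path with
the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Poisson upper tail by direct summation (log-space, forward from c)
# ---------------------------------------------------------------------------

def poisson_upper_tail(c: int, lam: float) -> float:
    """P(X >= c) for X ~ Poisson(lam), summed term by term."""
    if c <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = c * math.log(lam) - lam - math.lgamma(c + 1)
    term = math.exp(log_term)
    total = 0.0
    k = c
    while term > 0 and (total == 0 or term > total * 1e-18):
        total += term
        k += 1
        term *= lam / k
        if k > c + 10_000:
            break
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# interval algebra, per-base
# ---------------------------------------------------------------------------

def base_set(start: int, end: int) -> set[int]:
    return set(range(start, end))


def reproducible_peaks_oracle(replicate_intervals, min_reps=2, frac=0.5,
                              reciprocal=False):
    """Retained-interval union per the reproducibility rule, on one
    chromosome.  ``replicate_intervals``: list (per replicate) of (start,
    end) tuples.  Returns the merged union intervals of retained peaks."""
    pool = []
    for i, peaks in enumerate(replicate_intervals):
        for p in peaks:
            pb = base_set(*p)
            support = 1
            supporters = []
            for j, others in enumerate(replicate_intervals):
                if j == i:
                    continue
                found = False
                for q in others:
                    ov = len(pb & base_set(*q))
                    ok = ov >= frac * len(pb)
                    if reciprocal:
                        ok = ok and ov >= frac * (q[1] - q[0])
                    if ok:
                        found = True
                        supporters.append(q)
                if found:
                    support += 1
            if support >= min_reps:
                pool.append(p)
                pool.extend(supporters)
    return union_runs(pool)


def union_runs(intervals):
    """Merged union of intervals via a per-base boolean mask."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    mask = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    out = []
    in_run = False
    for i in range(hi + 1):
        if mask[i] and not in_run:
            start, in_run = i, True
        elif not mask[i] and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, hi + 1))
    return out


def consensus_oracle(condition_intervals):
    """Merged union across conditions plus per-condition presence flags.

    ``condition_intervals``: dict condition -> list of (start, end).
    Returns list of (start, end, {condition: bool}).
    """
    all_iv = [iv for ivs in condition_intervals.values() for iv in ivs]
    merged = union_runs(all_iv)
    out = []
    for s, e in merged:
        mb = base_set(s, e)
        presence = {
            cond: any(len(mb & base_set(*iv)) >= 1 for iv in ivs)
            for cond, ivs in condition_intervals.items()
        }
        out.append((s, e, presence))
    return out


def count_in_interval_oracle(positions, start, end) -> int:
    return sum(1 for p in positions if start <= p < end)


def annotate_oracle(mid: int, genes):
    """(gene_id, signed distance, category) by exhaustive scan.

    ``genes``: GeneModel-like objects.  Reimplements the priority rules
    directly from their statement.
    """
    best = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        d = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
        if best is None or abs(d) < abs(best[1]):
            best = (g, d)
    g, d = best
    exon_bases = [base_set(s, e) for s, e in g.exons]
    if g.start <= mid < g.end:
        if any(mid in b for b in exon_bases):
            first = g.exons[0] if g.strand == "+" else g.exons[-1]
            before_codon = (
                mid < g.start_codon if g.strand == "+" else mid > g.start_codon
            )
            if mid in base_set(*first) and before_codon:
                cat = "5UTR"
            else:
                cat = "Exon"
        else:
            cat = "Intron"
    elif -1000 <= d < 0:
        cat = "Promoter<=1kb"
    elif -2000 <= d < -1000:
        cat = "Promoter1-2kb"
    elif -3000 <= d < -2000:
        cat = "Promoter2-3kb"
    elif (g.strand == "+" and g.end <= mid < g.end + 1000) or (
        g.strand == "-" and g.start - 1000 <= mid < g.start
    ):
        cat = "Downstream<=1kb"
    else:
        cat = "DistalIntergenic"
    return g.gene_id, d, cat


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def bmu_scan(prototypes, x) -> int:
    """Best-matching unit by a plain python distance scan."""
    best_i, best_d = 0, float("inf")
    for i, p in enumerate(prototypes):
        d = 0.0
        for a, b in zip(p, x):
            d += (a - b) ** 2
        if d < best_d:
            best_i, best_d = i, d
    return best_i


def all_pairs_edges(atac: dict, rna: dict, threshold: float):
    """Edge set {(atac_gene, rna_gene)} by exhaustive pairwise distance."""
    edges = set()
    for ga, va in atac.items():
        for gr, vr in rna.items():
            d2 = sum((a - b) ** 2 for a, b in zip(va, vr))
            if d2 < threshold:
                edges.add((ga, gr))
    return edges


def dinucleotide_counts(seq: str) -> dict:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out
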