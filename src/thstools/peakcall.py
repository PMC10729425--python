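"""Single-sample peak calling against a local Poisson background.

Each Tn5 insertion is shifted and extended to a fixed-size pileup element
(shift −100, extension 200 bp by default, so every insertion contributes a
200-bp window centred on itself).  Coverage is then scored position-wise
against a local Poisson rate: the maximum of the genome-wide rate and the
mean coverage in surrounding 1/5/10-kb windows.  Candidate positions (local
maxima of coverage) are corrected with Benjamini–Hochberg, significant
positions are merged into peaks, and each peak reports its summit and the
−log10 p-value there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .atac_qc import InsertionTrack
from .formats_io import Peak

_MAX_NEG_LOG10 = 999.0


@dataclass
class PeakCallParams:
    shift: int = -100
    extsize: int = 200
    qvalue_cutoff: float = 0.05
    local_windows: tuple[int, ...] = (1000, 5000, 10000)
    min_peak_len: int | None = None  # default extsize // 2
    merge_gap: int = 30

    def __post_init__(self) -> None:
        if self.extsize <= 0:
            raise ValueError("extsize must be positive")
        if not 0.0 < self.qvalue_cutoff < 1.0:
            raise ValueError("qvalue cutoff must lie in (0, 1)")
        if self.min_peak_len is None:
            self.min_peak_len = self.extsize // 2


def pileup(
    positions: np.ndarray, params: PeakCallParams, chrom_len: int
) -> np.ndarray:
    """Coverage vector: each insertion at p adds +1 on
    [p+shift, p+shift+extsize), clipped to the chromosome."""
    cov = np.zeros(chrom_len + 1, dtype=np.int64)
    if len(positions):
        starts = np.clip(positions + params.shift, 0, chrom_len)
        ends = np.clip(positions + params.shift + params.extsize, 0, chrom_len)
        np.add.at(cov, starts, 1)
        np.add.at(cov, ends, -1)
    return np.cumsum(cov)[:chrom_len]


def _window_mean(cov: np.ndarray, w: int) -> np.ndarray:
    """Mean coverage in a w-bp window centred on each position (edge windows
    use the in-bounds portion)."""
    L = len(cov)
    csum = np.concatenate([[0], np.cumsum(cov)])
    half = w // 2
    idx = np.arange(L)
    lo = np.clip(idx - half, 0, L)
    hi = np.clip(idx + (w - half), 0, L)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _local_lambda(cov: np.ndarray, params: PeakCallParams) -> np.ndarray:
    lam = np.full(len(cov), cov.sum() / len(cov), dtype=float)  # genome floor
    for w in params.local_windows:
        lam = np.maximum(lam, _window_mean(cov, w))
    return lam


def _candidate_positions(cov: np.ndarray) -> np.ndarray:
    """Leftmost positions of coverage runs that are local maxima (> both
    neighbouring runs, chromosome ends counting as −inf)."""
    if len(cov) == 0:
        return np.array([], dtype=np.int64)
    change = np.flatnonzero(np.diff(cov)) + 1
    run_starts = np.concatenate([[0], change])
    vals = cov[run_starts]
    left = np.concatenate([[-1], vals[:-1]])
    right = np.concatenate([vals[1:], [-1]])
    is_max = (vals > left) & (vals > right) & (vals > 0)
    return run_starts[is_max]


def poisson_neglog10_sf(count: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """−log10 upper-tail Poisson p-value P(X ≥ count), capped at 999."""
    logp = stats.poisson.logsf(np.asarray(count) - 1, np.asarray(lam))
    return np.minimum(-logp / np.log(10.0), _MAX_NEG_LOG10)


def call_peaks(
    track: InsertionTrack,
    params: PeakCallParams,
    chrom_lens: Mapping[str, int],
) -> list[Peak]:
    """Call peaks on every chromosome of one sample.

    BH correction runs over candidate positions (local coverage maxima)
    pooled across chromosomes; positions whose p-value falls at or below the
    BH threshold are merged (gap ≤ merge_gap) and peaks shorter than
    min_peak_len are dropped.  Summit = leftmost coverage argmax.
    """
    chroms = sorted(track.positions)
    covs: dict[str, np.ndarray] = {}
    lams: dict[str, np.ndarray] = {}
    cand_p: list[np.ndarray] = []
    for chrom in chroms:
        L = chrom_lens[chrom]
        if L <= params.extsize:
            raise ValueError(f"chromosome {chrom} shorter than extsize")
        cov = pileup(track.positions[chrom], params, L)
        lam = _local_lambda(cov, params)
        covs[chrom], lams[chrom] = cov, lam
        cand = _candidate_positions(cov)
        if len(cand):
            cand_p.append(
                10.0 ** -poisson_neglog10_sf(cov[cand], lam[cand])
            )
    if not cand_p:
        return []
    pvals = np.concatenate(cand_p)
    qvals = stats.false_discovery_control(pvals, method="bh")
    k = int((qvals <= params.qvalue_cutoff).sum())
    if k == 0:
        return []
    # BH threshold line: every position with p <= alpha*k/m is significant
    p_star = params.qvalue_cutoff * k / len(pvals)

    # step function p -> BH q for summit annotation
    order = np.argsort(pvals, kind="stable")
    p_sorted, q_sorted = pvals[order], qvals[order]

    peaks: list[Peak] = []
    for chrom in chroms:
        cov, lam = covs[chrom], lams[chrom]
        score = poisson_neglog10_sf(cov, lam)
        sig = (10.0 ** -score <= p_star) & (cov > 0)
        for s, e in _merge_runs(sig, params.merge_gap):
            if e - s < params.min_peak_len:
                continue
            summit = s + int(np.argmax(cov[s:e]))  # leftmost on ties
            p_summit = 10.0 ** -score[summit]
            qi = np.searchsorted(p_sorted, p_summit, side="right") - 1
            qvalue = float(q_sorted[max(qi, 0)])
            peaks.append(
                Peak(chrom, int(s), int(e), summit, float(score[summit]),
                     min(qvalue, 1.0))
            )
    return peaks


def _merge_runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs, joining runs separated by gaps ≤ merge_gap."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
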