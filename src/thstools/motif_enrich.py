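"""Discriminative promoter motif enrichment and PWM matching.

Short exact words (3–8 bp) found in positive promoter sequences are scored
against dinucleotide-shuffled (or user-supplied) negative sequences with a
one-sided Fisher exact test on per-sequence hit counts, generalized over
single-position IUPAC wildcards when that improves the p-value, and reported
in increasing E-value with the matched sites masked between rounds — the
regular-expression flavour of discriminative motif elicitation.  Discovered
words can then be matched against a library of known plant transcription
factor PWMs by maximal ungapped log-odds alignment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .formats_io import PWM, GeneModel, Genome, revcomp

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_OF = {frozenset(v): k for k, v in IUPAC.items()}


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str  # coding-strand oriented; position len(seq) abuts the start codon
    clipped: bool = False


@dataclass
class PromoterSet:
    records: list[PromoterRecord]

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


@dataclass
class MotifResult:
    word: str  # IUPAC, possibly generalized
    pos_hits: int
    neg_hits: int
    n_pos: int
    n_neg: int
    p: float
    evalue: float
    n_candidates: int  # distinct exact words tested in this round


@dataclass
class MotifMatch:
    word: str
    pwm: PWM
    score: float
    p: float


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(
    gene_ids: Sequence[str],
    genes: Sequence[GeneModel],
    genome: Genome,
    window: int = 3000,
) -> PromoterSet:
    """Promoter sequences: ``window`` bp upstream of the start codon,
    oriented so the last base abuts the start codon; clipped at contig ends
    (with the clip recorded)."""
    by_id = {g.gene_id: g for g in genes}
    records: list[PromoterRecord] = []
    for gid in gene_ids:
        if gid not in by_id:
            raise KeyError(f"unknown gene id {gid!r}")
        g = by_id[gid]
        L = genome.lengths[g.chrom]
        if g.strand == "+":
            start = g.start_codon - window
            clipped = start < 0
            seq = genome.fetch(g.chrom, max(start, 0), g.start_codon)
        else:
            end = g.start_codon + 1 + window
            clipped = end > L
            seq = revcomp(genome.fetch(g.chrom, g.start_codon + 1, min(end, L)))
        records.append(PromoterRecord(gid, seq, clipped))
    return PromoterSet(records)


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul–Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the original's dinucleotide counts.

    Eulerian-path shuffle: the sequence is a walk on the letter graph whose
    edges are its dinucleotides; a random last-edge tree toward the final
    letter is drawn, remaining out-edges are permuted, and the walk is
    replayed.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    non_terminal = [a for a in letters if a != last and edges[a]]
    for _ in range(10_000):
        chosen = {a: edges[a][rng.integers(len(edges[a]))] for a in non_terminal}
        if _reaches_last(chosen, last):
            break
    else:  # pragma: no cover - astronomically unlikely for real sequences
        raise RuntimeError("failed to sample a connecting last-edge tree")
    out_lists: dict[str, list[str]] = {}
    for a in letters:
        rest = list(edges[a])
        if a in chosen:
            rest.remove(chosen[a])
        perm = rng.permutation(len(rest))
        shuffled = [rest[i] for i in perm]
        if a in chosen:
            shuffled.append(chosen[a])
        out_lists[a] = shuffled
    result = [seq[0]]
    ptr = {a: 0 for a in letters}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def _reaches_last(chosen: dict[str, str], last: str) -> bool:
    for start in chosen:
        seen = set()
        cur = start
        while cur != last:
            if cur in seen or cur not in chosen:
                return False
            seen.add(cur)
            cur = chosen[cur]
    return True


def shuffle_negatives(promoters: PromoterSet, seed: int = 0) -> PromoterSet:
    """Per-sequence dinucleotide shuffles as the discriminative control set."""
    rng = np.random.default_rng(seed)
    return PromoterSet([
        PromoterRecord(r.gene_id + "_shuf", dinucleotide_shuffle(r.sequence, rng),
                       r.clipped)
        for r in promoters.records
    ])


# ---------------------------------------------------------------------------
# discriminative word enrichment
# ---------------------------------------------------------------------------

def _word_index(
    sequences: Sequence[str], min_len: int, max_len: int, both_strands: bool
) -> dict[str, int]:
    """word -> bitmask of sequence indices containing it (either strand)."""
    index: dict[str, int] = {}
    for i, seq in enumerate(sequences):
        bit = 1 << i
        strands = (seq, revcomp(seq)) if both_strands else (seq,)
        seen: set[str] = set()
        for s in strands:
            n = len(s)
            for w in range(min_len, max_len + 1):
                for j in range(n - w + 1):
                    word = s[j:j + w]
                    if "N" in word:
                        continue
                    seen.add(word)
        for word in seen:
            index[word] = index.get(word, 0) | bit
    return index


def fisher_greater(k_pos: int, n_pos: int, k_neg: int, n_neg: int) -> float:
    """One-sided (greater) Fisher exact p via the hypergeometric upper tail."""
    return float(
        stats.hypergeom.sf(k_pos - 1, n_pos + n_neg, k_pos + k_neg, n_pos)
    )


def expand_iupac(word: str) -> list[str]:
    """All plain-ACGT expansions of an IUPAC word."""
    out = [""]
    for ch in word:
        out = [p + b for p in out for b in IUPAC[ch]]
    return out


def _hits(word: str, index: dict[str, int]) -> int:
    mask = 0
    for w in expand_iupac(word):
        mask |= index.get(w, 0)
    return mask.bit_count()


def dreme_enrich(
    pos: PromoterSet,
    neg: PromoterSet,
    min_len: int = 3,
    max_len: int = 8,
    e_cutoff: float = 0.05,
    max_motifs: int = 10,
    both_strands: bool = True,
) -> list[MotifResult]:
    """Discriminative enrichment of short words in positives vs negatives.

    Candidate exact words (length ``min_len``–``max_len``, present in at
    least two positive sequences) are scored by one-sided Fisher exact on
    per-sequence binary hits (both strands by default).  The best word is
    refined by single-position IUPAC wildcards accepted only when the
    p-value improves; its E-value is p × the number of candidates tested.
    Motifs are reported while E < ``e_cutoff``; after each report the
    matching sites are masked in the positives and the scan repeats.
    """
    if not len(pos) or not len(neg):
        raise ValueError("both sequence sets must be nonempty")
    n_pos, n_neg = len(pos), len(neg)
    pos_seqs = [r.sequence for r in pos.records]
    neg_index = _word_index(neg.sequences(), min_len, max_len, both_strands)

    results: list[MotifResult] = []
    for _ in range(max_motifs):
        pos_index = _word_index(pos_seqs, min_len, max_len, both_strands)
        cand_words = [w for w, m in pos_index.items() if m.bit_count() >= 2]
        if not cand_words:
            break
        kp = np.array([pos_index[w].bit_count() for w in cand_words])
        kn = np.array([neg_index.get(w, 0).bit_count() for w in cand_words])
        pvals = stats.hypergeom.sf(kp - 1, n_pos + n_neg, kp + kn, n_pos)
        order = sorted(range(len(cand_words)),
                       key=lambda i: (pvals[i], cand_words[i]))
        best_i = order[0]
        word, p = cand_words[best_i], float(pvals[best_i])

        # IUPAC refinement: one wildcard position per step, only on improvement
        word, p = _refine(word, p, pos_index, neg_index, n_pos, n_neg)

        evalue = p * len(cand_words)
        if evalue >= e_cutoff:
            break
        results.append(
            MotifResult(word, _hits(word, pos_index), _hits(word, neg_index),
                        n_pos, n_neg, p, evalue, len(cand_words))
        )
        pos_seqs = [_mask_word(s, word, both_strands) for s in pos_seqs]
    return results


def _refine(
    word: str, p: float, pos_index: dict, neg_index: dict,
    n_pos: int, n_neg: int,
) -> tuple[str, float]:
    """Generalize single positions to wider IUPAC codes while the Fisher
    p-value strictly improves; each position is widened at most once."""
    generalized: set[int] = set()
    while True:
        best: tuple[float, str, int] | None = None
        for i in range(len(word)):
            if i in generalized:
                continue
            current = set(IUPAC[word[i]])
            for code, bases in IUPAC.items():
                if not current < set(bases):
                    continue
                trial = word[:i] + code + word[i + 1:]
                kp = _hits(trial, pos_index)
                kn = _hits(trial, neg_index)
                tp = fisher_greater(kp, n_pos, kn, n_neg)
                cand = (tp, trial, i)
                if best is None or cand < best:
                    best = cand
        if best is not None and best[0] < p:
            p, word = best[0], best[1]
            generalized.add(best[2])
        else:
            return word, p


def _mask_word(seq: str, word: str, both_strands: bool) -> str:
    expansions = set(expand_iupac(word))
    if both_strands:
        expansions |= {revcomp(w) for w in expansions}
    w = len(word)
    chars = list(seq)
    for j in range(len(seq) - w + 1):
        if seq[j:j + w] in expansions:
            chars[j:j + w] = "N" * w
    return "".join(chars)


# ---------------------------------------------------------------------------
# matching discovered words to known PWMs
# ---------------------------------------------------------------------------

def word_to_matrix(word: str) -> np.ndarray:
    """IUPAC word → probability matrix (uniform over the allowed letters)."""
    mat = np.zeros((len(word), 4))
    for i, ch in enumerate(word):
        for b in IUPAC[ch]:
            mat[i, "ACGT".index(b)] = 1.0 / len(IUPAC[ch])
    return mat


def _alignment_score(
    wmat: np.ndarray, pwm: np.ndarray, background: np.ndarray
) -> float:
    """Maximal ungapped log-odds alignment score over offsets (PWM columns
    outside the overlap behave as background, contributing zero)."""
    logodds = np.log2(np.clip(pwm, 1e-9, None) / background)  # (W, 4)
    wl, pl = len(wmat), len(pwm)
    best = -np.inf
    for off in range(-(wl - 1), pl):
        s = 0.0
        for i in range(wl):
            j = off + i
            if 0 <= j < pl:
                s += float(wmat[i] @ logodds[j])
        best = max(best, s)
    return best


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return mat[::-1, ::-1]


def match_known_motifs(
    results: Sequence[MotifResult | str],
    pwm_library: Sequence[PWM],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[MotifMatch]:
    """Best-matching library PWM for each discovered word.

    Similarity is the maximal ungapped log-odds alignment score over offsets
    and strands; the match p-value comes from an empirical null of
    column-shuffled copies of the word matrix (best library score of each
    shuffle, seeded).
    """
    bg = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    matches: list[MotifMatch] = []
    for res in results:
        word = res if isinstance(res, str) else res.word
        wmat = word_to_matrix(word)
        strands = (wmat, _revcomp_matrix(wmat))

        def lib_best(mat: np.ndarray) -> tuple[float, PWM | None]:
            best_s, best_pwm = -np.inf, None
            for pwm in pwm_library:
                s = max(
                    _alignment_score(mat, pwm.matrix, bg),
                    _alignment_score(_revcomp_matrix(mat), pwm.matrix, bg),
                )
                if s > best_s:
                    best_s, best_pwm = s, pwm
            return best_s, best_pwm

        obs_score, obs_pwm = lib_best(wmat)
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            perm = rng.permutation(len(wmat))
            null[i], _ = lib_best(wmat[perm])
        p = float((1 + (null >= obs_score).sum()) / (1 + n_shuffles))
        matches.append(MotifMatch(word, obs_pwm, float(obs_score), p))
    return matches


def load_builtin_pwms() -> list[PWM]:
    """The small bundled library of plant TF motifs (W-box/WRKY, ABRE/bZIP,
    MYB, homeodomain, C2H2, GATA, ...)."""
    from .formats_io import read_pwm_meme

    ref = importlib.resources.files("thstools").joinpath("data/plant_pwms.meme")
    with importlib.resources.as_file(ref) as path:
        return read_pwm_meme(path)
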