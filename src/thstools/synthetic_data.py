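"""Synthetic inputs with planted ground truth.

Generates a toy genome with gene models, condition-specific accessible
regions, ATAC-like fragment sets with nucleosome-periodic length structure,
expression profiles coupled to accessibility, and prototype chlorophyll
fluorescence (OJIP) transients — everything needed to exercise the full
analysis with a known answer key.

The default configuration mirrors the experimental design being emulated:
four desiccation stages (C, D1, D2, D3) with three replicates each, and
accessible regions distributed over the stage subsets the analysis
distinguishes (watered-unique, watered→moderate, watered→severe,
severe→dry, constitutive, plus stage-unique regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    CONDITIONS,
    FragmentSet,
    GeneModel,
    Genome,
    revcomp,
    write_fasta,
    write_fragments_bed,
    write_gff3,
    write_tsv_matrix,
)

#: Accessibility patterns cycled over planted regions: the named desiccation
#: transitions plus the stage-unique patterns.
DEFAULT_PARTITION_CYCLE: tuple[frozenset, ...] = (
    frozenset({"C"}),
    frozenset({"C", "D1"}),
    frozenset({"C", "D1", "D2"}),
    frozenset({"D2", "D3"}),
    frozenset({"C", "D1", "D2", "D3"}),
    frozenset({"D1"}),
    frozenset({"D2"}),
    frozenset({"D3"}),
)

# child-seed offsets: stage-level reproducibility when stages rerun alone
_SEED_GENOME = 11
_SEED_FRAGMENTS = 101
_SEED_EXPRESSION = 211
_SEED_OJIP = 307


@dataclass
class SimulationConfig:
    """Knobs of the simulated study; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 1_000_000
    n_genes: int = 100
    conditions: tuple[str, ...] = CONDITIONS
    replicates_per_condition: int = 3
    n_accessible_genes: int = 48
    n_decoy_regions: int = 12
    enrichment_fold: float = 20.0
    fragments_per_sample: int = 20_000
    nfr_len_mean: float = 60.0
    nucleosome_period: float = 180.0
    mixture_weights: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10)
    region_len: int = 300
    region_center_upstream: int = 200
    promoter_window: int = 3000
    upstream_clearance: int = 4000
    # default planted element: a W-box (TTGACC) in an 8-bp context; an
    # 8-mer is rare enough (~0.1 expected hits per 3-kb promoter) that
    # per-sequence presence is discriminative at desk scale
    planted_motifs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("TTGACCTT", 0.8, 0.1)]
    )
    expr_coupling: float = 0.9
    # full-decoupling noise sd; ~log2(enrichment_fold), i.e. the magnitude of
    # the planted accessibility signal, so expr_coupling spans exact -> none
    expr_noise_scale: float = 4.0
    ojip_noise_sd: float = 0.05
    ojip_n_curves: int = 200

    def __post_init__(self) -> None:
        if tuple(self.conditions) != CONDITIONS:
            raise ValueError(f"conditions must be exactly {CONDITIONS}")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        for word, fpos, fneg in self.planted_motifs:
            if not (0 <= fpos <= 1 and 0 <= fneg <= 1):
                raise ValueError("motif fractions must lie in [0, 1]")
            if set(word) - set("ACGT"):
                raise ValueError(f"planted motif {word!r} must be plain ACGT")
        if not 0 <= self.expr_coupling <= 1:
            raise ValueError("expr_coupling must lie in [0, 1]")
        if self.ojip_noise_sd < 0:
            raise ValueError("ojip_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """The planted answer key scored against every downstream stage."""

    accessible_regions: list[tuple[tuple[str, int, int], frozenset]]
    motif_positions: list[tuple[str, str, int]]  # (gene_id, word, offset<0)
    coupled_genes: list[str]
    region_gene: dict[int, str]  # region index -> gene id ('' for decoys)
    ojip_labels: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "accessible_regions": [
                [list(iv), sorted(conds)] for iv, conds in self.accessible_regions
            ],
            "motif_positions": [list(t) for t in self.motif_positions],
            "coupled_genes": self.coupled_genes,
            "region_gene": {str(k): v for k, v in self.region_gene.items()},
            "ojip_labels": self.ojip_labels,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            accessible_regions=[
                ((iv[0], int(iv[1]), int(iv[2])), frozenset(conds))
                for iv, conds in d["accessible_regions"]
            ],
            motif_positions=[tuple(t) for t in d["motif_positions"]],
            coupled_genes=list(d["coupled_genes"]),
            region_gene={int(k): v for k, v in d["region_gene"].items()},
            ojip_labels=list(d["ojip_labels"]),
        )


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(
    cfg: SimulationConfig,
) -> tuple[Genome, list[GeneModel], GroundTruth]:
    """Uniform-background genome, non-overlapping genes, planted regions/motifs.

    Genes are laid out with at least ``upstream_clearance`` (default 4 kb)
    of intergenic space upstream of every start codon, so that 3-kb promoter
    windows never truncate or overlap a neighbouring gene.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_GENOME)
    gene_len = 2000
    slot = cfg.upstream_clearance + gene_len + 1000
    capacity = cfg.n_chroms * (cfg.chrom_len // slot)
    if cfg.n_genes > capacity:
        raise ValueError(
            f"genome too small: {cfg.n_genes} genes need {cfg.n_genes * slot} bp "
            f"but only {cfg.n_chroms * cfg.chrom_len} bp are available"
        )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {
        name: "".join(rng.choice(list("ACGT"), size=cfg.chrom_len))
        for name in chrom_names
    }

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gid = 0
    for chrom in chrom_names:
        cursor = cfg.upstream_clearance
        for _ in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            if cursor + gene_len + 1000 > cfg.chrom_len:
                break
            start = cursor
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid + 1:04d}"
            # two exons with a 200-bp intron; start codon 100 bp into the
            # transcript on the coding strand
            if strand == "+":
                exons = [(start, start + 800), (start + 1000, end)]
                tss = start
                start_codon = start + 100
            else:
                exons = [(start, end - 1000), (end - 800, end)]
                tss = end - 1
                start_codon = end - 1 - 100
            genes.append(
                GeneModel(gene_id, chrom, strand, start, end, tss, start_codon,
                          exons, mrna_id=f"{gene_id}.1")
            )
            gid += 1
            cursor = end + slot - gene_len
    if gid < cfg.n_genes:
        raise ValueError("genome too small to place all genes with clearance")

    # accessible regions: promoter-proximal for a subset of genes ...
    order = rng.permutation(len(genes))
    acc_gene_idx = sorted(order[: cfg.n_accessible_genes])
    regions: list[tuple[tuple[str, int, int], frozenset]] = []
    region_gene: dict[int, str] = {}
    for i, idx in enumerate(acc_gene_idx):
        g = genes[idx]
        if g.strand == "+":
            center = g.tss - cfg.region_center_upstream
        else:
            center = g.tss + cfg.region_center_upstream
        start = center - cfg.region_len // 2
        end = start + cfg.region_len
        conds = DEFAULT_PARTITION_CYCLE[i % len(DEFAULT_PARTITION_CYCLE)]
        regions.append(((g.chrom, start, end), conds))
        region_gene[len(regions) - 1] = g.gene_id

    # ... plus intergenic decoys placed midway between consecutive genes
    placed = 0
    gi = 0
    while placed < cfg.n_decoy_regions and gi + 1 < len(genes):
        a, b = genes[gi], genes[gi + 1]
        if a.chrom == b.chrom and b.start - a.end >= cfg.upstream_clearance:
            mid = (a.end + b.start) // 2 - cfg.upstream_clearance // 4
            start = mid - cfg.region_len // 2
            end = start + cfg.region_len
            conds = DEFAULT_PARTITION_CYCLE[
                (len(regions)) % len(DEFAULT_PARTITION_CYCLE)
            ]
            regions.append(((a.chrom, start, end), conds))
            region_gene[len(regions) - 1] = ""
            placed += 1
        gi += 2

    # plant motif words into promoter sequence (coding strand, upstream of
    # the start codon), recording offsets relative to the start codon
    motif_positions: list[tuple[str, str, int]] = []
    acc_ids = {genes[i].gene_id for i in acc_gene_idx}
    other_ids = [g.gene_id for g in genes if g.gene_id not in acc_ids]
    by_id = {g.gene_id: g for g in genes}
    for word, frac_pos, frac_neg in cfg.planted_motifs:
        n_pos = int(round(frac_pos * len(acc_ids)))
        n_neg = int(round(frac_neg * len(other_ids)))
        chosen = [genes[i].gene_id for i in acc_gene_idx[:n_pos]] + other_ids[:n_neg]
        for gene_id in chosen:
            g = by_id[gene_id]
            offset = -int(rng.integers(len(word) + 50, cfg.promoter_window - 50))
            _write_word(seqs, g, word, offset)
            motif_positions.append((gene_id, word, offset))

    genome = Genome(seqs)
    truth = GroundTruth(
        accessible_regions=regions,
        motif_positions=motif_positions,
        coupled_genes=[genes[i].gene_id for i in acc_gene_idx],
        region_gene=region_gene,
    )
    return genome, genes, truth


def _write_word(seqs: dict[str, str], gene: GeneModel, word: str, offset: int) -> None:
    """Write ``word`` so it reads on the coding strand at ``offset`` (< 0)
    relative to the start codon: positions [offset, offset + len(word))."""
    if gene.strand == "+":
        pos = gene.start_codon + offset
        ins = word
    else:
        # coding-strand offset x maps to genomic start_codon - offset - len + 1
        pos = gene.start_codon - offset - len(word) + 1
        ins = revcomp(word)
    seq = seqs[gene.chrom]
    seqs[gene.chrom] = seq[:pos] + ins + seq[pos + len(word):]


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def simulate_fragments(cfg: SimulationConfig, truth: GroundTruth,
                       genome: Genome) -> list[FragmentSet]:
    """ATAC-like fragment sets for every sample.

    Fragment lengths come from a four-component mixture (nucleosome-free
    plus mono/di/tri-nucleosomal at multiples of the nucleosome period);
    fragment midpoints fall inside regions accessible in the sample's
    condition ``enrichment_fold`` times more densely than elsewhere.  The
    per-sample fragment count is Poisson-distributed (replicate noise).
    """
    chrom_names = list(genome.sequences)
    chrom_lens = np.array([len(genome.sequences[c]) for c in chrom_names])
    chrom_starts = np.concatenate([[0], np.cumsum(chrom_lens)])
    genome_len = int(chrom_lens.sum())

    sets: list[FragmentSet] = []
    sample_idx = 0
    for condition in cfg.conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            rng = np.random.default_rng(cfg.seed + _SEED_FRAGMENTS + sample_idx)
            sample_idx += 1
            regions = [
                iv for iv, conds in truth.accessible_regions if condition in conds
            ]
            frag = _sample_fragments(
                cfg, rng, regions, chrom_names, chrom_lens, chrom_starts,
                genome_len,
            )
            sets.append(
                FragmentSet(f"{condition}_rep{rep}", condition, rep, frag)
            )
    return sets


def _sample_fragments(cfg, rng, regions, chrom_names, chrom_lens, chrom_starts,
                      genome_len):
    n = int(rng.poisson(cfg.fragments_per_sample))
    # lengths: NFR + decaying nucleosome multiples
    comp = rng.choice(4, size=n, p=np.asarray(cfg.mixture_weights) / sum(cfg.mixture_weights))
    means = np.array([
        cfg.nfr_len_mean,
        cfg.nucleosome_period,
        2 * cfg.nucleosome_period,
        3 * cfg.nucleosome_period,
    ])
    sds = np.array([0.25 * cfg.nfr_len_mean, 35.0, 45.0, 55.0])
    lengths = rng.normal(means[comp], sds[comp])
    lengths = np.clip(np.round(lengths), 20, None).astype(np.int64)

    # midpoints: accessible regions weighted enrichment_fold per bp
    region_lens = np.array([e - s for (_, s, e) in regions], dtype=np.int64)
    total_region = int(region_lens.sum())
    fold = cfg.enrichment_fold
    w_region = fold * total_region
    w_bg = genome_len - total_region
    p_region = w_region / (w_region + w_bg)
    in_region = rng.random(n) < p_region

    mid = np.empty(n, dtype=np.int64)
    n_bg = int((~in_region).sum())
    # background: uniform over the genome outside planted regions (rejection)
    bg = rng.integers(0, genome_len, size=n_bg)
    if total_region and n_bg:
        iv = np.array([
            [chrom_starts[chrom_names.index(c)] + s,
             chrom_starts[chrom_names.index(c)] + e]
            for (c, s, e) in regions
        ])
        sorted_iv = iv[np.argsort(iv[:, 0])]
        for _ in range(20):
            idx = np.searchsorted(sorted_iv[:, 0], bg, side="right") - 1
            inside = (idx >= 0) & (bg < sorted_iv[np.clip(idx, 0, None), 1])
            if not inside.any():
                break
            bg[inside] = rng.integers(0, genome_len, size=int(inside.sum()))
    mid[~in_region] = bg
    if in_region.any():
        ridx = rng.choice(len(regions), size=int(in_region.sum()),
                          p=region_lens / region_lens.sum())
        offs = (rng.random(int(in_region.sum())) * region_lens[ridx]).astype(np.int64)
        gstart = np.array([
            chrom_starts[chrom_names.index(c)] + s for (c, s, e) in regions
        ])
        mid[in_region] = gstart[ridx] + offs

    # convert linear midpoints to per-chromosome fragments, clipped
    ci = np.searchsorted(chrom_starts, mid, side="right") - 1
    local = mid - chrom_starts[ci]
    starts = local - lengths // 2
    ends = starts + lengths
    starts = np.clip(starts, 0, chrom_lens[ci] - 1)
    ends = np.clip(ends, starts + 1, chrom_lens[ci])
    return [
        (chrom_names[int(c)], int(s), int(e))
        for c, s, e in zip(ci, starts, ends)
    ]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def accessibility_profile(conds: frozenset, fold: float) -> np.ndarray:
    """Planted per-stage log2 fold change vs C implied by an accessibility
    pattern: log2(fold_s / fold_C) with fold_s = fold if accessible else 1."""
    f = {c: (fold if c in conds else 1.0) for c in CONDITIONS}
    return np.array([np.log2(f[s] / f["C"]) for s in ("D1", "D2", "D3")])


def simulate_expression(cfg: SimulationConfig, truth: GroundTruth,
                        genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene log2 fold-change table (stages D1, D2, D3 vs C).

    Coupled genes (those with a planted accessible promoter) receive their
    accessibility profile plus Gaussian noise scaled by (1 − expr_coupling);
    all other genes receive independent random profiles.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_EXPRESSION)
    gene_conds = {}
    for ridx, gene_id in truth.region_gene.items():
        if gene_id:
            gene_conds[gene_id] = truth.accessible_regions[ridx][1]
    rows = {}
    for g in genes:
        if g.gene_id in gene_conds:
            base = accessibility_profile(gene_conds[g.gene_id], cfg.enrichment_fold)
            noise_sd = cfg.expr_noise_scale * (1.0 - cfg.expr_coupling)
            rows[g.gene_id] = base + rng.normal(0.0, noise_sd, size=3)
        else:
            rows[g.gene_id] = rng.normal(0.0, 2.0, size=3)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["D1", "D2", "D3"])
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# OJIP transients
# ---------------------------------------------------------------------------

#: handy-PEA style log time grid, 10 µs .. 1 s
OJIP_TIMES = np.logspace(-5, 0, 118)

# J/I/P step midpoints (s) and stage-specific amplitudes: the fluorescence
# rise flattens as the plant dries out
_STEP_TIMES = (2e-3, 3e-2, 3e-1)
_STAGE_AMP = {"C": 3.0, "D1": 2.2, "D2": 1.3, "D3": 0.5}
# With progressive drying the variable-fluorescence rise collapses: the late
# I->P phase vanishes first while the O->J phase dominates, so the step
# weights shift strongly from P-heavy (watered) to J-heavy (dry).
_STEP_WEIGHTS = {"C": (0.30, 0.25, 0.45), "D1": (0.50, 0.28, 0.22),
                 "D2": (0.70, 0.22, 0.08), "D3": (0.88, 0.10, 0.02)}


def ojip_prototype(stage: str, times: np.ndarray = OJIP_TIMES) -> np.ndarray:
    """Monotone-rising O–J–I–P transient prototype for one stage."""
    lt = np.log10(times)
    f = np.full_like(lt, 0.5)  # O level
    amp = _STAGE_AMP[stage]
    for w, t0 in zip(_STEP_WEIGHTS[stage], _STEP_TIMES):
        f = f + amp * w / (1.0 + np.exp(-(lt - np.log10(t0)) / 0.25))
    return f


def simulate_ojip(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(times, curves, labels): noisy prototype transients, balanced classes.

    Noise is multiplicative Gaussian with sd ``ojip_noise_sd`` (fraction of
    the local signal), mimicking shot/optics variability between leaves.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_OJIP)
    labels = [CONDITIONS[i % 4] for i in range(cfg.ojip_n_curves)]
    curves = np.empty((cfg.ojip_n_curves, len(OJIP_TIMES)))
    for i, stage in enumerate(labels):
        proto = ojip_prototype(stage)
        noise = rng.normal(0.0, cfg.ojip_noise_sd, size=proto.shape)
        curves[i] = np.clip(proto * (1.0 + noise), 0.0, None)
    return OJIP_TIMES.copy(), curves, labels


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def write_fixture(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Simulate everything and write the on-disk fixture layout:

    genome.fa, genes.gff3, samples.tsv, fragments/<sample>.bed,
    expression.tsv, ojip.tsv, truth.json
    """
    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome_and_genes(cfg)
    frag_sets = simulate_fragments(cfg, truth, genome)
    expr = simulate_expression(cfg, truth, genes)
    times, curves, labels = simulate_ojip(cfg)
    truth.ojip_labels = labels

    write_fasta(genome, outdir / "genome.fa")
    write_gff3(genes, outdir / "genes.gff3")
    rows = []
    for fs in frag_sets:
        bed = outdir / "fragments" / f"{fs.sample_id}.bed"
        write_fragments_bed(fs, bed)
        rows.append((fs.sample_id, fs.condition, fs.replicate,
                     str(Path("fragments") / bed.name)))
    pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "path"]) \
        .to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_tsv_matrix(expr, outdir / "expression.tsv")

    ojip = pd.DataFrame(curves.T, columns=[f"curve{i + 1}" for i in range(len(labels))])
    ojip.insert(0, "time_s", times)
    with open(outdir / "ojip.tsv", "w") as fh:
        fh.write("#labels\t" + "\t".join(labels) + "\n")
        ojip.to_csv(fh, sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))
    return outdir


def read_ojip_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Read an OJIP TSV (first column time, one column per curve; optional
    leading '#labels' row)."""
    path = Path(path)
    labels = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#labels"):
            labels = first.rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    times = df.iloc[:, 0].to_numpy(float)
    curves = df.iloc[:, 1:].to_numpy(float).T
    return times, curves, labels
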