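"""Readers, writers and core genomic records.

Every in-memory coordinate in this package is 0-based half-open (the BED
convention).  GFF3 is 1-based closed on disk; the conversion happens in this
module and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The four desiccation stages, in physiological order: fully watered control,
#: moderate (~50% RWC), severe (~20% RWC) and fully dry (~6% RWC).
CONDITIONS = ("C", "D1", "D2", "D3")

_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file; message carries the offending path/line."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A reference genome held in memory as plain ACGTN strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            if _NON_ACGTN.search(seq):
                raise FormatError(
                    f"chromosome {name!r} contains characters outside ACGTN"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the half-open interval [start, end)."""
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """A single gene model (first mRNA of the gene).

    ``start``/``end`` span the gene half-open; ``tss`` is the span start on
    the + strand and ``end - 1`` on the − strand; ``start_codon`` is the
    position of the first base of the CDS in transcription order.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    start_codon: int
    exons: list[tuple[int, int]]
    mrna_id: str | None = None
    other_mrnas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: empty span")
        expected_tss = self.start if self.strand == "+" else self.end - 1
        if self.tss != expected_tss:
            raise FormatError(f"gene {self.gene_id}: tss inconsistent with strand")
        if not (self.start <= self.start_codon < self.end):
            raise FormatError(f"gene {self.gene_id}: start codon outside span")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise FormatError(
                    f"gene {self.gene_id}: exons unsorted, overlapping or outside span"
                )
            prev_end = e

    @property
    def first_exon(self) -> tuple[int, int]:
        """First exon in transcription order."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class FragmentSet:
    """Aligned paired-end fragments of one sample; the pipeline entry point."""

    sample_id: str
    condition: str
    replicate: int
    fragments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise FormatError("replicate must be >= 1")
        for chrom, start, end in self.fragments:
            if start < 0 or start >= end:
                raise FormatError(
                    f"bad fragment {chrom}:{start}-{end} in {self.sample_id}"
                )

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Fragments grouped per chromosome as sorted (n, 2) int arrays."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.fragments:
            out.setdefault(chrom, []).append((start, end))
        return {
            chrom: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            for chrom, pairs in out.items()
        }


@dataclass
class Peak:
    """A called peak; ``score`` is −log10 of the summit p-value."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    qvalue: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError("peak with empty interval")
        if not (self.start <= self.summit < self.end):
            raise FormatError("summit outside peak interval")
        if not (0.0 <= self.qvalue <= 1.0):
            raise FormatError("qvalue outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    """Position weight matrix; ``matrix`` has shape (width, 4) over ACGT."""

    name: str
    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"PWM {self.name}: matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError(f"PWM {self.name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file; lowercase is uppercased, non-ACGTN mapped to N."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate record name {record.id!r} in {path}")
        seq = _NON_ACGTN.sub("N", str(record.seq).upper())
        if not seq:
            raise FormatError(f"empty record {record.id!r} in {path}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based closed → 0-based half-open).

    One GeneModel per gene, taken from its first mRNA in file order; the IDs
    of any further mRNAs are recorded in ``other_mrnas``.  A CDS feature is
    required — the start codon is anchored on it.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            raise FormatError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"gene {gene.id}: no mRNA feature")
        mrna = mrnas[0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            raise FormatError(f"gene {gene.id}: mRNA {mrna.id} has no exons")
        cds = list(db.children(mrna, featuretype="CDS"))
        if not cds:
            raise FormatError(
                f"gene {gene.id}: no CDS feature; cannot anchor the start codon"
            )
        span = (gene.start - 1, gene.end)
        for s, e in exons:
            if s < span[0] or e > span[1]:
                raise FormatError(f"gene {gene.id}: exon outside gene span")
        if gene.strand == "+":
            start_codon = min(f.start for f in cds) - 1
            tss = span[0]
        else:
            start_codon = max(f.end for f in cds) - 1
            tss = span[1] - 1
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=span[0],
                end=span[1],
                tss=tss,
                start_codon=start_codon,
                exons=exons,
                mrna_id=mrna.id,
                other_mrnas=[m.id for m in mrnas[1:]],
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features (0-based half-open → 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna_id = g.mrna_id or f"{g.gene_id}.1"
            cols = [g.chrom, "thstools", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, "."]
            fh.write("\t".join(cols + [f"ID={g.gene_id}"]) + "\n")
            fh.write(
                "\t".join(cols[:2] + ["mRNA", str(g.start + 1), str(g.end), ".",
                                      g.strand, ".",
                                      f"ID={mrna_id};Parent={g.gene_id}"])
                + "\n"
            )
            # CDS runs from the start codon to the gene 3' end, clipped to exons
            if g.strand == "+":
                cds_span = (g.start_codon, g.end)
            else:
                cds_span = (g.start, g.start_codon + 1)
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    "\t".join([g.chrom, "thstools", "exon", str(s + 1), str(e),
                               ".", g.strand, ".",
                               f"ID={mrna_id}.exon{i + 1};Parent={mrna_id}"])
                    + "\n"
                )
                cs, ce = max(s, cds_span[0]), min(e, cds_span[1])
                if cs < ce:
                    fh.write(
                        "\t".join([g.chrom, "thstools", "CDS", str(cs + 1),
                                   str(ce), ".", g.strand, "0",
                                   f"ID={mrna_id}.cds;Parent={mrna_id}"])
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED fragments
# ---------------------------------------------------------------------------

def read_fragments_bed(
    path: str | Path, sample_id: str, condition: str, replicate: int
) -> FragmentSet:
    """Read a BED3+ fragment file (0-based half-open, as BED is defined)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fragments: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            fragments.append((chrom, start, end))
    return FragmentSet(sample_id, condition, replicate, fragments)


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in frags.fragments:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """ENCODE narrowPeak (10 columns); summit stored relative to start."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            disp_score = min(1000, round(10 * p.score))
            log_q = -np.log10(p.qvalue) if p.qvalue > 0 else 999999.0
            fh.write(
                "\t".join([
                    p.chrom, str(p.start), str(p.end), name, str(disp_score),
                    ".", "%.17g" % p.score, "%.17g" % p.score,
                    "%.17g" % log_q, str(p.summit - p.start),
                ])
                + "\n"
            )


def read_narrowpeak(path: str | Path) -> list[Peak]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            score = float(parts[7])
            log_q = float(parts[8])
            qvalue = 0.0 if log_q >= 999999.0 else 10.0 ** (-log_q)
            summit = start + int(parts[9])
            peaks.append(Peak(chrom, start, end, summit, score, qvalue, name))
    return peaks


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def write_tsv_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV (index in the first column)."""
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "id")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = df.index.name or "id"
    return df


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_pwm_meme(path: str | Path) -> list[PWM]:
    """Parse MEME minimal motif format into PWMs.

    The optional second token of a MOTIF line is taken as the TF name, the
    convention used by plant PWM collections.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pwms: list[PWM] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}:{i + 1}: MOTIF line without a name")
            name = tokens[1]
            tf_name = tokens[2] if len(tokens) > 2 else name
            # scan forward for the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name} has no matrix")
                j += 1
            if j == len(lines):
                raise FormatError(f"{path}: motif {name} has no matrix")
            m = re.search(r"w=\s*(\d+)", lines[j])
            if not m:
                raise FormatError(f"{path}:{j + 1}: missing w= in matrix header")
            width = int(m.group(1))
            rows = []
            for k in range(j + 1, j + 1 + width):
                vals = [float(x) for x in lines[k].split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{k + 1}: expected 4 probabilities")
                rows.append(vals)
            pwms.append(PWM(name, tf_name, np.array(rows)))
            i = j + 1 + width
        else:
            i += 1
    return pwms


def write_pwm_meme(
    pwms: Sequence[PWM], path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(background))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name} {pwm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join("%.6f" % v for v in row) + "\n")
            fh.write("\n")
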