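"""Integration of THS accessibility with expression fold changes.

Joins THS-linked genes with a per-stage log2 fold-change expression table,
links enriched motifs to the expression of their matched transcription
factors, and builds the bipartite ATAC↔RNA correlation network: every gene
contributes one ATAC node (its accessibility fold-change profile) and one
RNA node (its expression profile), and two nodes are connected when the
squared Euclidean distance of their per-stage profiles falls below a
threshold — only ATAC–RNA pairs are ever evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .motif_enrich import MotifMatch
from .ths_dynamics import AnnotatedTHS

STAGES = ("D1", "D2", "D3")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression table: one row per gene, columns exactly D1–D3."""
    if list(expr.columns) != list(STAGES):
        raise ValueError(f"expression columns must be exactly {STAGES}")
    if not np.isfinite(expr.to_numpy(float)).all():
        raise ValueError("expression table contains non-finite values")
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    return expr


@dataclass
class JoinedTable:
    """Gene-level ATAC and RNA fold-change profiles, inner-joined."""

    table: pd.DataFrame  # index gene_id; columns atac_D1.. and rna_D1..
    atac_only: list[str]
    rna_only: list[str]

    def atac(self) -> pd.DataFrame:
        return self.table[[f"atac_{s}" for s in STAGES]]

    def rna(self) -> pd.DataFrame:
        return self.table[[f"rna_{s}" for s in STAGES]]


def gene_level_atac_fc(
    annotated: Sequence[AnnotatedTHS], atac_fc: pd.DataFrame
) -> pd.DataFrame:
    """Mean THS fold-change profile per nearest gene."""
    rows: dict[str, list[np.ndarray]] = {}
    for a in annotated:
        tid = a.ths.ths_id
        if tid in atac_fc.index:
            rows.setdefault(a.gene_id, []).append(
                atac_fc.loc[tid, list(STAGES)].to_numpy(float)
            )
    data = {g: np.mean(v, axis=0) for g, v in rows.items()}
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(STAGES))
    df.index.name = "gene_id"
    return df.sort_index()


def join_ths_expression(
    atac_gene_fc: pd.DataFrame, expr: pd.DataFrame
) -> JoinedTable:
    """Inner join of gene-level ATAC profiles with the expression table."""
    expr = validate_expression(expr)
    shared = sorted(set(atac_gene_fc.index) & set(expr.index))
    atac_only = sorted(set(atac_gene_fc.index) - set(expr.index))
    rna_only = sorted(set(expr.index) - set(atac_gene_fc.index))
    table = pd.concat(
        [
            atac_gene_fc.loc[shared, list(STAGES)].rename(
                columns={s: f"atac_{s}" for s in STAGES}
            ),
            expr.loc[shared, list(STAGES)].rename(
                columns={s: f"rna_{s}" for s in STAGES}
            ),
        ],
        axis=1,
    )
    table.index.name = "gene_id"
    return JoinedTable(table, atac_only, rna_only)


def _normalize(profiles: pd.DataFrame, mode: str) -> tuple[np.ndarray, list[str]]:
    """Return (normalized matrix, list of excluded gene ids)."""
    X = profiles.to_numpy(float)
    if mode == "raw":
        return X, []
    if mode != "unit":
        raise ValueError("normalization must be 'unit' or 'raw'")
    norms = np.linalg.norm(X, axis=1)
    excluded = [g for g, nz in zip(profiles.index, norms == 0) if nz]
    if excluded:
        warnings.warn(
            f"{len(excluded)} zero-norm profile(s) excluded under unit "
            f"normalization: {excluded[:5]}..."
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = X / norms[:, None]
    return Xn, excluded


def correlation_network(
    joined: JoinedTable,
    threshold: float = 0.01,
    normalization: str = "unit",
) -> nx.Graph:
    """Bipartite ATAC↔RNA network under a squared-distance threshold.

    Each gene yields an ATAC node ``("ATAC", gene)`` and an RNA node
    ``("RNA", gene)``; an edge joins ATAC node i to RNA node j iff
    d²(profile_i, profile_j) < threshold after the chosen normalization
    (``unit`` scales each profile to unit Euclidean norm; ``raw`` uses the
    profiles as stored).  ATAC–ATAC and RNA–RNA pairs are never evaluated.
    """
    if joined.table.empty:
        raise ValueError("joined table is empty")
    atac, excl_a = _normalize(joined.atac(), normalization)
    rna, excl_r = _normalize(joined.rna(), normalization)
    genes = list(joined.table.index)
    keep_a = [i for i, g in enumerate(genes) if g not in set(excl_a)]
    keep_r = [i for i, g in enumerate(genes) if g not in set(excl_r)]

    G = nx.Graph()
    for i in keep_a:
        G.add_node(("ATAC", genes[i]), source="ATAC", gene=genes[i])
    for j in keep_r:
        G.add_node(("RNA", genes[j]), source="RNA", gene=genes[j])
    if keep_a and keep_r:
        d2 = cdist(atac[keep_a], rna[keep_r], metric="sqeuclidean")
        for ii, i in enumerate(keep_a):
            for jj, j in enumerate(keep_r):
                if d2[ii, jj] < threshold:
                    G.add_edge(("ATAC", genes[i]), ("RNA", genes[j]),
                               distance=float(d2[ii, jj]))
    return G


def network_edge_list(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "atac_gene": (u if u[0] == "ATAC" else v)[1],
            "rna_gene": (v if u[0] == "ATAC" else u)[1],
            "sq_distance": d["distance"],
        }
        for u, v, d in G.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["atac_gene", "rna_gene", "sq_distance"])
    return df.sort_values(["atac_gene", "rna_gene"]).reset_index(drop=True)


def link_motifs_to_tf_expression(
    matches: Sequence[MotifMatch],
    expr: pd.DataFrame,
    motif_stage_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Attach matched-TF expression profiles to enriched motifs.

    Motifs whose matched TF is absent from the expression table are kept
    with a missing-profile flag; ``motif_stage_groups`` optionally labels
    each motif word with the stage group of its source THSs.
    """
    expr = validate_expression(expr)
    rows = []
    for m in matches:
        tf = m.pwm.tf_name if m.pwm is not None else ""
        has_expr = tf in expr.index
        profile = (
            expr.loc[tf, list(STAGES)].tolist() if has_expr else [np.nan] * 3
        )
        rows.append({
            "word": m.word,
            "pwm": m.pwm.name if m.pwm is not None else "",
            "tf_name": tf,
            "match_score": m.score,
            "match_p": m.p,
            "stage_group": (motif_stage_groups or {}).get(m.word, ""),
            "has_expression": has_expr,
            **{f"expr_{s}": v for s, v in zip(STAGES, profile)},
        })
    return pd.DataFrame(rows)
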