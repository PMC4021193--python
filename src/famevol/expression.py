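"""Expression normalization, correlation clustering, specificity calls,
and cis-element scanning in promoter sequences.

RPKM = reads / (gene length in kb) / (library size in millions).  Genes are
clustered on 1 − Pearson correlation with average linkage; genes with a
constant profile (including the never-expressed) are excluded from
clustering with a warning, since their correlation is undefined.

Specificity classes are mutually exclusive, assigned in precedence order
silent → single-tissue-exclusive → constitutive → single-tissue-peak →
other (a peak is a tissue holding at least ``peak_fraction`` of the row
total).

The packaged cis-element table carries approximate IUPAC consensi for the
common plant promoter elements (G-box, Box 4, TCA-element, MBS, ARE, HSE,
GARE-motif, circadian); callers may substitute their own definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .simulate import _iupac_regex, _motif_hit_positions, reverse_complement


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def rpkm_normalize(counts, gene_lengths_bp, library_sizes) -> pd.DataFrame:
    """reads / kilobase of gene / million mapped reads, per gene × tissue.

    *counts* is a genes × tissues DataFrame; *gene_lengths_bp* maps (or
    aligns to) its index, *library_sizes* its columns.
    """
    counts = pd.DataFrame(counts)
    lengths = pd.Series(gene_lengths_bp).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any():
        raise KeyError(f"missing gene lengths: {list(lengths[lengths.isna()].index)}")
    if libs.isna().any():
        raise KeyError(f"missing library sizes: {list(libs[libs.isna()].index)}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


# ---------------------------------------------------------------------------
# Pearson-correlation clustering
# ---------------------------------------------------------------------------

@dataclass
class ExpressionClustering:
    genes: list[str]          # clusterable genes, input order
    linkage: np.ndarray       # scipy linkage matrix (average)
    order: list[str]          # dendrogram leaf order
    excluded: list[str]       # constant-profile genes left out

    def ordered_matrix(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.loc[self.order]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.genes[node.id]}:{parent_height:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_expression(matrix: pd.DataFrame) -> ExpressionClustering:
    """Average-linkage clustering of genes on 1 − Pearson r."""
    matrix = pd.DataFrame(matrix)
    variances = matrix.var(axis=1, ddof=0)
    keep = variances > 0
    excluded = list(matrix.index[~keep])
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant-profile gene(s) excluded from clustering "
            f"(undefined correlation): {excluded[:6]}{'...' if len(excluded) > 6 else ''}"
        )
    clusterable = matrix.loc[keep]
    if clusterable.shape[0] < 2:
        raise ValueError("fewer than 2 clusterable (non-constant) genes")
    corr = np.corrcoef(clusterable.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    order_idx = hierarchy.leaves_list(Z)
    genes = list(clusterable.index)
    return ExpressionClustering(
        genes=genes,
        linkage=Z,
        order=[genes[i] for i in order_idx],
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# tissue-specificity classes
# ---------------------------------------------------------------------------

@dataclass
class SpecificityCall:
    gene_id: str
    label: str  # constitutive | single_tissue_exclusive | single_tissue_peak | silent | other
    peak_tissue: str | None = None


def call_specificity(
    matrix: pd.DataFrame, tissues=None, peak_fraction: float = 0.5
) -> list[SpecificityCall]:
    """Classify each gene's expression pattern across tissues."""
    matrix = pd.DataFrame(matrix)
    if tissues is not None:
        tissues = list(tissues)
        if set(tissues) != set(matrix.columns):
            raise ValueError("tissue list does not match matrix columns")
        matrix = matrix[tissues]
    calls = []
    for gene, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        nonzero = vals > 0
        peak_t = row.index[int(np.argmax(vals))] if nonzero.any() else None
        if not nonzero.any():
            calls.append(SpecificityCall(gene, "silent"))
        elif nonzero.sum() == 1:
            calls.append(SpecificityCall(gene, "single_tissue_exclusive", peak_t))
        elif nonzero.all():
            calls.append(SpecificityCall(gene, "constitutive", peak_t))
        elif vals.max() / vals.sum() >= peak_fraction:
            calls.append(SpecificityCall(gene, "single_tissue_peak", peak_t))
        else:
            calls.append(SpecificityCall(gene, "other", peak_t))
    return calls


# ---------------------------------------------------------------------------
# cis-element scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str  # IUPAC
    note: str = ""


def default_cis_elements() -> list[MotifDef]:
    """The packaged approximate cis-element consensus table."""
    path = resources.files("famevol").joinpath("data/cis_elements.tsv")
    table = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifDef(r["name"], r["consensus"], r.get("note", ""))
        for _, r in table.iterrows()
    ]


@dataclass
class MotifCounts:
    counts: pd.DataFrame       # genes × motif names, integer counts
    mean_copies: pd.Series     # per motif, rounded to 3 decimals

    def __getitem__(self, motif: str) -> pd.Series:
        return self.counts[motif]


def scan_cis_elements(promoters: dict[str, str], motifs=None) -> MotifCounts:
    """Count motif occurrences on both strands of each promoter.

    Overlapping occurrences count; a forward match and the reverse-
    complement match starting at the same locus count once.  Promoters must
    be over A/C/G/T/N; motif consensi must be valid IUPAC.
    """
    if motifs is None:
        motifs = default_cis_elements()
    motifs = [
        m if isinstance(m, MotifDef) else MotifDef(str(m), str(m)) for m in motifs
    ]
    for m in motifs:
        _iupac_regex(m.consensus)  # validates IUPAC codes
    rows = {}
    for gene, seq in promoters.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{gene}: invalid promoter characters {sorted(bad)}")
        rows[gene] = {
            m.name: len(_motif_hit_positions(seq, m.consensus)) for m in motifs
        }
    counts = pd.DataFrame.from_dict(rows, orient="index")[[m.name for m in motifs]]
    mean_copies = (counts.sum() / len(counts)).round(3)
    return MotifCounts(counts, mean_copies)
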