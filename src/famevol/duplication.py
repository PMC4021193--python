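"""Tandem-cluster detection, NG86 Ka/Ks, 4DTv, and Ks-based duplication dating.

Tandem duplicates follow the adjacency rule used for the soybean family:
family members on one chromosome whose ordinal gene ranks differ by at most
``max_intervening + 1`` chain into a cluster (singletons are discarded).

Ka/Ks uses Nei–Gojobori (1986) counting with the Jukes–Cantor multiple-hit
correction; multi-hit codons average over equal-weight minimal substitution
pathways, discarding pathways through stop codons.  Segmental events are
dated from synteny-anchor Ks lists by T = mean(Ks) / (2 * lambda).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import (
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    is_fourfold_degenerate,
    is_transversion,
)
from .alignment import CodonAlignment

FABACEAE_LAMBDA = 6.1e-9  # synonymous substitutions / site / year


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # in rank order
    ranks: list[int]
    max_intervening: int

    @property
    def size(self) -> int:
        return len(self.members)


def detect_tandem_clusters(
    locus_table: pd.DataFrame,
    family_ids,
    max_intervening: int = 1,
) -> list[TandemCluster]:
    """Maximal chains of family genes under the rank-gap rule.

    *locus_table* needs columns gene_id, chromosome, rank with ranks unique
    per chromosome.  Clusters never span chromosomes; chains of length 1
    are not reported.
    """
    family_ids = list(family_ids)
    known = set(locus_table["gene_id"])
    missing = [g for g in family_ids if g not in known]
    if missing:
        raise KeyError(f"family ids absent from locus table: {missing}")
    fam = locus_table[locus_table.gene_id.isin(set(family_ids))]
    clusters: list[TandemCluster] = []
    for chrom, sub in fam.groupby("chromosome", sort=True):
        if sub["rank"].duplicated().any():
            raise ValueError(f"duplicate ordinal ranks on {chrom}")
        sub = sub.sort_values("rank")
        ids = list(sub.gene_id)
        ranks = list(sub["rank"].astype(int))
        chain_ids, chain_ranks = [ids[0]], [ranks[0]]
        for gid, rank in zip(ids[1:], ranks[1:]):
            if rank - chain_ranks[-1] <= max_intervening + 1:
                chain_ids.append(gid)
                chain_ranks.append(rank)
            else:
                if len(chain_ids) >= 2:
                    clusters.append(
                        TandemCluster(chrom, chain_ids, chain_ranks, max_intervening)
                    )
                chain_ids, chain_ranks = [gid], [rank]
        if len(chain_ids) >= 2:
            clusters.append(
                TandemCluster(chrom, chain_ids, chain_ranks, max_intervening)
            )
    return clusters


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    ka: float
    ks: float
    n_sites: float  # N: nonsynonymous sites
    s_sites: float  # S: synonymous sites
    n_diffs: float  # Nd
    s_diffs: float  # Sd
    n_codons: int

    @property
    def omega(self) -> float:
        """Ka/Ks; NaN when Ks = 0."""
        return self.ka / self.ks if self.ks > 0 else math.nan


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    At each position the synonymous fraction is taken over the single-
    nucleotide changes that do not create a stop codon.
    """
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def _pathway_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal pathways.

    Pathways are the orderings of the differing positions; any pathway
    passing through a stop codon is discarded.  Returns NaNs if every
    pathway is blocked (the codon pair is then dropped by the caller).
    """
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return math.nan, math.nan
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise ValueError(f"p = {p:.4f} >= 3/4: Jukes–Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def compute_ng86(pair: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for a two-sequence codon alignment."""
    if pair.n_sequences != 2:
        raise ValueError("NG86 needs exactly two sequences")
    codon_pairs = pair.ungapped_pair_codons(*pair.names)
    # drop codon pairs whose every minimal pathway passes through a stop
    kept = []
    for ca, cb in codon_pairs:
        sd, nd = _pathway_diff_counts(ca, cb)
        if not math.isnan(sd):
            kept.append((ca, cb, sd, nd))
    if not kept:
        raise ValueError("zero comparable codons after gap/stop-path removal")
    S = N = Sd = Nd = 0.0
    for ca, cb, sd, nd in kept:
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        n_sites=N,
        s_sites=S,
        n_diffs=Nd,
        s_diffs=Sd,
        n_codons=len(kept),
    )


# ---------------------------------------------------------------------------
# 4DTv
# ---------------------------------------------------------------------------

@dataclass
class FourDTv:
    n_4d_sites: int
    n_transversions: int

    @property
    def value(self) -> float:
        return self.n_transversions / self.n_4d_sites


def compute_4dtv(pair: CodonAlignment) -> FourDTv:
    """Transversion proportion at shared fourfold-degenerate third positions.

    A column qualifies iff both codons are fourfold degenerate at position 3
    and identical at positions 1–2; the value is the uncorrected proportion
    of qualifying third positions that differ by a transversion.
    """
    if pair.n_sequences != 2:
        raise ValueError("4DTv needs exactly two sequences")
    sites = tv = 0
    for ca, cb in pair.ungapped_pair_codons(*pair.names):
        if ca[:2] != cb[:2]:
            continue
        if not (is_fourfold_degenerate(ca) and is_fourfold_degenerate(cb)):
            continue
        sites += 1
        if is_transversion(ca[2], cb[2]):
            tv += 1
    if sites == 0:
        raise ValueError("no qualifying fourfold-degenerate sites")
    return FourDTv(sites, tv)


# ---------------------------------------------------------------------------
# segmental dating
# ---------------------------------------------------------------------------

@dataclass
class SegmentalEvent:
    gene_a: str
    gene_b: str
    raw_anchor_ks: list[float]
    filtered_ks: list[float]
    lam: float
    accepted: bool
    reject_reason: str | None = None
    mean_ks: float = math.nan
    sd_ks: float = math.nan

    @property
    def n_anchors(self) -> int:
        return len(self.filtered_ks)

    @property
    def t_years(self) -> float:
        return self.mean_ks / (2.0 * self.lam)

    @property
    def t_my(self) -> int:
        """Age in million years, rounded to the nearest integer (half up)."""
        return int(math.floor(self.t_years / 1e6 + 0.5))


def date_segmental_event(
    pair: tuple[str, str],
    anchor_ks,
    lam: float = FABACEAE_LAMBDA,
    ks_window: tuple[float, float] = (0.0, 1.0),
    min_anchors: int = 3,
) -> SegmentalEvent:
    """Date one duplicated pair from its synteny-anchor Ks values.

    Anchors are filtered to the open window (default 0 < Ks < 1); pairs
    with fewer than *min_anchors* surviving anchors are rejected.  The age
    is T = mean(Ks) / (2 lambda), with the sample (n-1) standard deviation
    reported alongside.
    """
    anchor_ks = [float(k) for k in anchor_ks]
    if not anchor_ks:
        raise ValueError("anchor list is empty")
    lo, hi = ks_window
    filtered = [k for k in anchor_ks if lo < k < hi]
    gene_a, gene_b = pair
    if len(filtered) < min_anchors:
        return SegmentalEvent(
            gene_a,
            gene_b,
            anchor_ks,
            filtered,
            lam,
            accepted=False,
            reject_reason=(
                f"only {len(filtered)} anchors in window "
                f"({lo}, {hi}); need >= {min_anchors}"
            ),
        )
    arr = np.array(filtered)
    return SegmentalEvent(
        gene_a,
        gene_b,
        anchor_ks,
        filtered,
        lam,
        accepted=True,
        mean_ks=float(arr.mean()),
        sd_ks=float(arr.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

@dataclass
class DuplicationReport:
    n_members: int
    n_tandem: int
    n_segmental: int

    @property
    def tandem_pct(self) -> float:
        return round(100.0 * self.n_tandem / self.n_members, 1) if self.n_members else 0.0

    @property
    def segmental_pct(self) -> float:
        return (
            round(100.0 * self.n_segmental / self.n_members, 1)
            if self.n_members
            else 0.0
        )


def duplication_report(members, clusters, events) -> DuplicationReport:
    """Counts and percentages of family genes in tandem / segmental events."""
    members = list(members)
    tandem = set()
    for c in clusters:
        tandem.update(c.members)
    segmental = set()
    for e in events:
        if getattr(e, "accepted", True):
            segmental.update((e.gene_a, e.gene_b) if hasattr(e, "gene_a") else e)
    member_set = set(members)
    return DuplicationReport(
        n_members=len(members),
        n_tandem=len(tandem & member_set),
        n_segmental=len(segmental & member_set),
    )
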