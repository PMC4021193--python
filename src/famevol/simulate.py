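"""Synthetic-data generators.

Everything the analysis stages consume can be generated here with planted,
recorded truth: codon alignments evolved under the site / branch-site
omega-class models, chromosome layouts with planted tandem clusters and
segmental anchor pairs, expression matrices with planted specificity
classes, and promoters with planted cis-element copies.

Random-number contract: every generator takes one integer seed and draws
from a single ``numpy.random.default_rng(seed)`` stream, in the documented
order, so identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import N_SENSE, SENSE_CODONS, CODON_INDEX
from .alignment import CodonAlignment
from .gy94 import get_process, uniform_codon_freqs
from .trees import Tree

SITE_MODELS = ("M0", "M3", "M7", "M8", "branch_site_A")


# ---------------------------------------------------------------------------
# codon-alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimModelSpec:
    """Parameters of the generating omega-class model.

    ``omega_classes`` is a list of (proportion, omega) pairs; for M7/M8 the
    beta component must already be discretized by the caller (or use
    :func:`famevol.selection.discretize_beta`).  For the branch-site model,
    each class may instead carry (proportion, omega_background,
    omega_foreground) triples and ``foreground_branches`` names the branches
    (by child-node label) on which the foreground ratio applies.
    """

    model_name: str
    kappa: float
    omega_classes: list
    beta_params: tuple | None = None
    foreground_branches: frozenset = frozenset()
    codon_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model_name not in SITE_MODELS:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        props = np.array([c[0] for c in self.omega_classes], dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {props.sum()}, not 1")
        for c in self.omega_classes:
            if any(w < 0 for w in c[1:]):
                raise ValueError("omega ratios must be >= 0")
        if self.codon_freqs is None:
            self.codon_freqs = uniform_codon_freqs()
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_SENSE,):
            raise ValueError("codon_freqs must have length 61 (sense codons only)")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("codon_freqs must sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c[0] for c in self.omega_classes], dtype=float)

    def class_omegas(self, foreground: bool) -> np.ndarray:
        out = []
        for c in self.omega_classes:
            if len(c) == 2:
                out.append(c[1])
            else:
                out.append(c[2] if foreground else c[1])
        return np.array(out, dtype=float)


def simulate_codon_alignment(
    tree: Tree, spec: SimModelSpec, n_codons: int, root_sequence: str | None = None
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons down *tree* under *spec*.

    Returns the leaf alignment and the per-site true class labels.  Draw
    order: (1) one multinomial vector of site classes, (2) root codons from
    the stationary frequencies (skipped when *root_sequence* is supplied),
    (3) child states branch by branch in pre-order, classes grouped in
    ascending class index.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    leaves = tree.leaf_names
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    rng = np.random.default_rng(spec.seed)
    if spec.foreground_branches:
        tree = tree.copy()
        tree.mark_foreground(spec.foreground_branches)

    n_classes = len(spec.omega_classes)
    site_class = rng.choice(n_classes, size=n_codons, p=spec.proportions)
    pi = spec.codon_freqs
    if root_sequence is not None:
        root_sequence = root_sequence.upper()
        if len(root_sequence) != 3 * n_codons:
            raise ValueError("root sequence length must be 3 * n_codons")
        codons = [root_sequence[3 * j : 3 * j + 3] for j in range(n_codons)]
        bad = [c for c in codons if c not in CODON_INDEX]
        if bad:
            raise ValueError(f"stop or invalid codon in root sequence: {bad[0]}")
        root_state = np.array([CODON_INDEX[c] for c in codons])
    else:
        root_state = rng.choice(N_SENSE, size=n_codons, p=pi)

    w_bg = spec.class_omegas(foreground=False)
    w_fg = spec.class_omegas(foreground=True)

    states = {tree.root: root_state}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[node.parent]
        child_state = parent_state.copy()
        omegas = w_fg if node.foreground else w_bg
        if node.length > 0:
            for k in range(n_classes):
                sites = np.nonzero(site_class == k)[0]
                if sites.size == 0:
                    continue
                P = get_process(spec.kappa, omegas[k], pi).transition_matrix(
                    node.length
                )
                cum = P.cumsum(axis=1)
                u = rng.random(sites.size)
                child_state[sites] = (
                    u[:, None] > cum[parent_state[sites]]
                ).sum(axis=1)
        states[node] = child_state

    names, seqs = [], []
    for leaf in tree.leaves:
        names.append(leaf.name)
        seqs.append("".join(SENSE_CODONS[s] for s in states[leaf]))
    return CodonAlignment(names, seqs), site_class


# ---------------------------------------------------------------------------
# genome layouts with planted duplications
# ---------------------------------------------------------------------------

@dataclass
class SegmentalSpec:
    """How to plant segmentally duplicated pairs and draw their anchor Ks."""

    n_pairs: int = 0
    n_anchors: int = 5
    ks_distribution: str = "normal"  # "normal" | "uniform" | "lognormal"
    ks_params: tuple = (0.15, 0.05)  # (mean, sd) / (low, high) / (mu, sigma)
    truncate_01: bool = True


@dataclass
class GenomeFixture:
    locus_table: pd.DataFrame  # gene_id, chromosome, rank, start, end, strand, is_family_member
    planted_tandem_clusters: list[list[str]]
    planted_segmental_pairs: list[tuple[str, str, list[float]]]

    @property
    def family_ids(self) -> list[str]:
        tbl = self.locus_table
        return list(tbl.loc[tbl.is_family_member, "gene_id"])


def _draw_ks(rng: np.random.Generator, spec: SegmentalSpec, n: int) -> list[float]:
    out: list[float] = []
    while len(out) < n:
        if spec.ks_distribution == "normal":
            x = rng.normal(*spec.ks_params)
        elif spec.ks_distribution == "uniform":
            x = rng.uniform(*spec.ks_params)
        elif spec.ks_distribution == "lognormal":
            x = rng.lognormal(*spec.ks_params)
        else:
            raise ValueError(f"unknown Ks distribution {spec.ks_distribution!r}")
        if spec.truncate_01 and not (0.0 < x < 1.0):
            continue
        out.append(float(x))
    return out


def generate_genome_fixture(
    n_chromosomes: int,
    n_genes: int,
    tandem_spec=(),
    segmental_spec: SegmentalSpec | None = None,
    seed: int = 0,
) -> GenomeFixture:
    """Lay out *n_genes* over chromosomes with planted duplication structure.

    ``tandem_spec`` is a sequence of cluster sizes (each >= 2); each planted
    cluster occupies consecutive ordinal ranks except for at most one
    single-gene gap per adjacent pair (drawn at random), so it satisfies the
    one-intervening-gene adjacency rule by construction.  Family members not
    in the same cluster are separated by at least two non-family genes so
    that detection recovers exactly what was planted.

    Draw order: tandem gap patterns, cluster placements, segmental-pair
    placements, anchor Ks values, gene coordinates.
    """
    tandem_spec = list(tandem_spec)
    if any(s < 2 for s in tandem_spec):
        raise ValueError("tandem cluster sizes must be >= 2")
    segmental_spec = segmental_spec or SegmentalSpec(n_pairs=0)
    rng = np.random.default_rng(seed)

    genes_per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        genes_per_chrom[i] += 1

    # family slots: (chrom, rank) -> cluster id / pair role
    family_slots: dict[int, set[int]] = {c: set() for c in range(n_chromosomes)}
    blocked: dict[int, set[int]] = {c: set() for c in range(n_chromosomes)}

    def reserve(chrom: int, ranks: list[int]) -> bool:
        taken = family_slots[chrom] | blocked[chrom]
        if any(r < 1 or r > genes_per_chrom[chrom] for r in ranks):
            return False
        pad = set()
        for r in ranks:  # keep 2 buffer ranks around each member
            pad.update(range(r - 2, r + 3))
        if pad & taken:
            return False
        family_slots[chrom].update(ranks)
        blocked[chrom].update(pad)
        return True

    clusters: list[tuple[int, list[int]]] = []
    for size in tandem_spec:
        gaps = rng.integers(0, 2, size=size - 1)  # 0 or 1 intervening gene
        span = size + int(gaps.sum())
        for _ in range(10_000):
            chrom = int(rng.integers(n_chromosomes))
            if genes_per_chrom[chrom] < span + 4:
                continue
            start = int(rng.integers(1, genes_per_chrom[chrom] - span + 2))
            ranks = [start]
            for g in gaps:
                ranks.append(ranks[-1] + 1 + int(g))
            if reserve(chrom, ranks):
                clusters.append((chrom, ranks))
                break
        else:
            raise ValueError("could not place planted tandem clusters; too many genes requested")

    seg_slots: list[tuple[int, int]] = []
    for _ in range(segmental_spec.n_pairs * 2):
        for _ in range(10_000):
            chrom = int(rng.integers(n_chromosomes))
            rank = int(rng.integers(1, genes_per_chrom[chrom] + 1))
            if reserve(chrom, [rank]):
                seg_slots.append((chrom, rank))
                break
        else:
            raise ValueError("could not place planted segmental genes")

    n_family = sum(len(r) for _, r in clusters) + len(seg_slots)
    if n_family > n_genes:
        raise ValueError(f"{n_family} planted family genes exceed n_genes={n_genes}")

    anchors = [
        _draw_ks(rng, segmental_spec, segmental_spec.n_anchors)
        for _ in range(segmental_spec.n_pairs)
    ]

    rows = []
    cluster_ids: list[list[str]] = [[] for _ in clusters]
    pair_ids: list[list[str]] = [[] for _ in range(segmental_spec.n_pairs)]
    fam_counter = 0
    for chrom in range(n_chromosomes):
        pos = 1
        for rank in range(1, genes_per_chrom[chrom] + 1):
            length = int(rng.integers(800, 5000))
            is_family = rank in family_slots[chrom]
            if is_family:
                fam_counter += 1
                gid = f"fam{fam_counter:03d}"
                for k, (cc, ranks) in enumerate(clusters):
                    if cc == chrom and rank in ranks:
                        cluster_ids[k].append(gid)
                for k, slot in enumerate(seg_slots):
                    if slot == (chrom, rank):
                        pair_ids[k // 2].append(gid)
            else:
                gid = f"bg_c{chrom + 1:02d}r{rank:03d}"
            rows.append(
                dict(
                    gene_id=gid,
                    chromosome=f"chr{chrom + 1:02d}",
                    rank=rank,
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    is_family_member=is_family,
                )
            )
            pos += length + int(rng.integers(200, 2000))

    pairs = [
        (ids[0], ids[1], anchors[k]) for k, ids in enumerate(pair_ids)
    ]
    return GenomeFixture(pd.DataFrame(rows), cluster_ids, pairs)


# ---------------------------------------------------------------------------
# expression matrices with planted specificity classes
# ---------------------------------------------------------------------------

EXPRESSION_CLASSES = (
    "constitutive",
    "single_tissue_exclusive",
    "single_tissue_peak",
    "silent",
)


def generate_expression_fixture(
    n_genes: int,
    tissues,
    class_assignments,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM-scale matrix (genes x tissues) with planted specificity classes.

    ``class_assignments`` maps gene index (or id) to a class label; missing
    genes default to ``constitutive``.  Returns (matrix, truth) where truth
    records the planted class and peak tissue.  Constitutive rows are drawn
    flat enough that no tissue reaches the peak-call fraction; peak rows
    have one dominant tissue, at least one silent tissue, and two or more
    expressed tissues, so the planted classes are the classes the caller's
    classifier must return.
    """
    tissues = list(tissues)
    if not tissues:
        raise ValueError("tissues must be nonempty")
    n_t = len(tissues)
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_genes, n_t))
    truth = []
    for g in range(n_genes):
        gid = f"gene{g + 1:03d}"
        label = class_assignments.get(g, class_assignments.get(gid, "constitutive"))
        if label not in EXPRESSION_CLASSES:
            raise ValueError(f"unknown expression class {label!r}")
        peak = None
        if label == "silent":
            pass
        elif label == "constitutive":
            # flat profile: all nonzero, max share < 0.5 (needs >= 3 tissues)
            row = rng.uniform(5.0, 15.0, size=n_t)
            if n_t >= 3:
                while row.max() / row.sum() >= 0.5:  # pragma: no cover
                    row = rng.uniform(5.0, 15.0, size=n_t)
            mat[g] = row
        elif label == "single_tissue_exclusive":
            peak = int(rng.integers(n_t))
            mat[g, peak] = rng.uniform(20.0, 200.0)
        else:  # single_tissue_peak
            if n_t < 3:
                raise ValueError("single_tissue_peak needs >= 3 tissues")
            peak = int(rng.integers(n_t))
            others = [t for t in range(n_t) if t != peak]
            rng.shuffle(others)
            n_on = int(rng.integers(1, len(others)))  # >=1 on, >=1 off
            level = rng.uniform(50.0, 200.0)
            mat[g, peak] = level
            for t in others[:n_on]:
                mat[g, t] = rng.uniform(0.5, level / (2 * max(n_on, 1)))
        truth.append(
            dict(
                gene_id=gid,
                planted_class=label,
                peak_tissue=tissues[peak] if peak is not None else None,
            )
        )
    matrix = pd.DataFrame(mat, index=[f"gene{g + 1:03d}" for g in range(n_genes)],
                          columns=tissues)
    return matrix, pd.DataFrame(truth).set_index("gene_id")


# ---------------------------------------------------------------------------
# promoters with planted motifs
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(
            c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in motif.upper()
        ))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in motif {motif!r}")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _motif_hit_positions(seq: str, motif: str) -> set[int]:
    """Start positions of both-strand matches, same-locus deduplicated."""
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(reverse_complement(motif))
    hits = set()
    for pat in (fwd, rev):
        pos = 0
        while True:
            m = pat.search(seq, pos)
            if m is None:
                break
            hits.add(m.start())
            pos = m.start() + 1  # overlapping occurrences count
    return hits


def generate_promoter_fixture(
    n_genes: int,
    length: int,
    motif_plants,
    seed: int = 0,
    exclude_background: bool = True,
    max_tries: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoter set with exact planted counts of forward-strand motifs.

    ``motif_plants`` maps an IUPAC consensus to either one integer (same
    planted count for every gene) or a per-gene sequence of counts.  With
    ``exclude_background`` the background is redrawn until the both-strand
    scan count equals exactly the planted count for every motif.

    Returns (promoters, truth) with truth counts per gene per motif.
    Draw order per gene: background bases, then planting positions, motif
    by motif in the given order; degenerate positions are instantiated
    uniformly over their IUPAC choices.
    """
    motifs = {m.upper(): counts for m, counts in motif_plants.items()}
    for m in motifs:
        _iupac_regex(m)  # validate
        if length < len(m):
            raise ValueError(f"promoter length {length} shorter than motif {m}")
    rng = np.random.default_rng(seed)
    names = [f"gene{g + 1:03d}" for g in range(n_genes)]
    promoters: dict[str, str] = {}
    rows = []

    def planted_count(counts, g):
        if np.isscalar(counts):
            return int(counts)
        return int(counts[g])

    for g, name in enumerate(names):
        wanted = {m: planted_count(c, g) for m, c in motifs.items()}
        total_len = sum(len(m) * k for m, k in wanted.items())
        if total_len > length:
            raise ValueError(
                f"{name}: planted motifs ({total_len} bp) cannot fit in {length} bp"
            )
        for _ in range(max_tries):
            seq = rng.choice(list("ACGT"), size=length)
            # plant non-overlapping instances, longest motifs first
            occupied: list[tuple[int, int]] = []
            ok = True
            for m in sorted(wanted, key=len, reverse=True):
                for _ in range(wanted[m]):
                    for _try in range(500):
                        s = int(rng.integers(0, length - len(m) + 1))
                        e = s + len(m)
                        if all(e <= a or s >= b for a, b in occupied):
                            occupied.append((s, e))
                            inst = "".join(
                                c if len(_IUPAC[c]) == 1
                                else _IUPAC[c][rng.integers(len(_IUPAC[c]))]
                                for c in m
                            )
                            seq[s:e] = list(inst)
                            break
                    else:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            text = "".join(seq)
            if exclude_background:
                if all(
                    len(_motif_hit_positions(text, m)) == k
                    for m, k in wanted.items()
                ):
                    break
            else:
                break
        else:
            raise ValueError(f"{name}: could not build motif-clean promoter")
        promoters[name] = text
        rows.append(dict(gene_id=name, **{m: wanted[m] for m in motifs}))
    return promoters, pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# type-I divergence profiles (counts drawn straight from the mixture model)
# ---------------------------------------------------------------------------

def simulate_type1_profiles(
    theta: float,
    alpha: float,
    d_a: float,
    d_b: float,
    n_sites: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site substitution counts for two clusters under the rate-shift mixture.

    With probability ``theta`` a site draws independent Gamma(alpha, mean 1)
    rates in the two clusters; otherwise one shared rate.  Counts are
    Poisson with cluster exposures ``d_a`` and ``d_b``.  Returns
    (counts_a, counts_b, is_divergent).
    """
    rng = np.random.default_rng(seed)
    divergent = rng.random(n_sites) < theta
    shared = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    ra = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    rb = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    rate_a = np.where(divergent, ra, shared)
    rate_b = np.where(divergent, rb, shared)
    xa = rng.poisson(rate_a * d_a)
    xb = rng.poisson(rate_b * d_b)
    return xa, xb, divergent
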