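"""Protein distance matrices, neighbor-joining trees, subfamily assignment.

The NJ implementation is the classic Saitou–Nei agglomeration with the
standard Q-criterion.  Ties in the Q minimization are broken by the lowest
(row, column) index pair after sorting the input leaves lexicographically,
so output is reproducible and invariant to input order.  Negative branch
length estimates are clamped to zero with a warning (the MEGA behaviour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, GAP_CHARS
from .trees import Node, Tree


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match name count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly 0")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    def __getitem__(self, pair):
        a, b = pair
        return self.matrix[self.names.index(a), self.names.index(b)]


def pairwise_protein_distance(
    alignment: Alignment, model: str = "p_distance"
) -> DistanceMatrix:
    """p-distance or Poisson-corrected distance with pairwise gap deletion.

    For each pair, columns where either sequence is gapped are dropped;
    p = mismatches / compared sites; poisson d = -ln(1 - p).
    """
    if alignment.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = alignment.n_sequences
    arr = np.array([list(s) for s in alignment.sequences])
    is_gap = np.isin(arr, list(GAP_CHARS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.names[i]} "
                    f"and {alignment.names[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p = 1 between {alignment.names[i]} and "
                        f"{alignment.names[j]}: poisson distance undefined"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(alignment.names), d)


def build_nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Leaves are processed in lexicographic order; the returned tree is the
    unrooted topology represented with a trifurcating root.
    """
    order = np.argsort(dm.names)
    names = [dm.names[i] for i in order]
    if len(names) < 3:
        raise ValueError("NJ needs at least 3 leaves")
    D = dm.matrix[np.ix_(order, order)].astype(float).copy()

    nodes: list[Node] = [Node(n) for n in names]
    active = list(range(len(names)))

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(
                    f"negative NJ branch length {x:.3g} joining {a}/{b}; "
                    "clamped to 0",
                    stacklevel=3,
                )
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: first (i, j) in row-major order
        flat = np.argmin(Q)
        i, j = divmod(int(flat), r)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = Node()
        na, nb = nodes[a], nodes[b]
        na.length = clamp(li, na.name or "internal", nb.name or "internal")
        nb.length = clamp(lj, na.name or "internal", nb.name or "internal")
        parent.add_child(na)
        parent.add_child(nb)
        # distances from the new node
        new_d = 0.5 * (D[a, :] + D[b, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_d)] = new_d
        D[: len(new_d), -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # closed-form star join of the last three
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = Node()
    for idx, l in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        nodes[idx].length = clamp(l, nodes[idx].name or "internal", "star")
        root.add_child(nodes[idx])
    return Tree(root)


@dataclass
class SubfamilyAssignment:
    label: str
    ambiguous: bool = False


def assign_subfamilies(
    tree: Tree, reference_labels: dict[str, str]
) -> dict[str, SubfamilyAssignment]:
    """Label query leaves from reference-labelled leaves by clade context.

    Each query receives the label of the smallest bipartition side
    containing it whose reference leaves are all of one subfamily; if no
    such side exists the label of the topologically nearest reference leaf
    is used and the assignment is flagged ambiguous.
    """
    leaf_set = set(tree.leaf_names)
    missing = set(reference_labels) - leaf_set
    if missing:
        raise KeyError(f"reference leaves not in tree: {sorted(missing)}")
    queries = sorted(leaf_set - set(reference_labels))

    sides: list[frozenset] = []
    for below, _node in tree.bipartitions():
        sides.append(below)
        sides.append(frozenset(leaf_set - below))

    hop = tree.path_distances(weighted=False)
    out: dict[str, SubfamilyAssignment] = {}
    for q in queries:
        best: tuple[int, tuple, str] | None = None
        for side in sides:
            if q not in side:
                continue
            refs = {reference_labels[l] for l in side if l in reference_labels}
            if len(refs) != 1:
                continue
            key = (len(side), tuple(sorted(side)))
            if best is None or key < best[:2]:
                best = (*key, next(iter(refs)))
        if best is not None:
            out[q] = SubfamilyAssignment(best[2], ambiguous=False)
        else:
            nearest = min(
                reference_labels,
                key=lambda r: (hop[(q, r) if q < r else (r, q)], r),
            )
            out[q] = SubfamilyAssignment(reference_labels[nearest], ambiguous=True)
    return out


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support (0–100) per nontrivial bipartition.

    Supports are reported for the bipartitions of the NJ tree built from the
    full alignment, keyed by the smaller leaf-set side.
    """
    rng = np.random.default_rng(seed)
    ref_tree = build_nj_tree(pairwise_protein_distance(alignment, model))
    all_leaves = set(ref_tree.leaf_names)

    def canonical(below: frozenset) -> frozenset:
        other = frozenset(all_leaves - below)
        return min(below, other, key=lambda s: (len(s), tuple(sorted(s))))

    ref_bips = {
        canonical(b)
        for b, _ in ref_tree.bipartitions()
        if 1 < len(b) < len(all_leaves) - 1
    }
    counts = {b: 0 for b in ref_bips}
    n_cols = len(alignment)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        seqs = ["".join(s[c] for c in cols) for s in alignment.sequences]
        rep = Alignment(list(alignment.names), seqs)
        rep_tree = build_nj_tree(pairwise_protein_distance(rep, model))
        rep_bips = {
            canonical(b)
            for b, _ in rep_tree.bipartitions()
            if 1 < len(b) < len(all_leaves) - 1
        }
        for b in ref_bips & rep_bips:
            counts[b] += 1
    return {b: 100.0 * c / n_replicates for b, c in counts.items()}
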