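"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the package's own code
paths: the genetic code comes from Biopython's CodonTable, rate matrices
are exponentiated with scipy.linalg.expm, and likelihoods are brute-force
sums over internal-node states.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable
from scipy.linalg import expm

from famevol.trees import Tree

# ---------------------------------------------------------------------------
# independent genetic-code tables (Biopython standard table)
# ---------------------------------------------------------------------------

_STD = CodonTable.unambiguous_dna_by_id[1]
ORACLE_STOPS = set(_STD.stop_codons)
ORACLE_CODE = dict(_STD.forward_table)  # codon -> amino acid, sense only
ORACLE_SENSE = sorted(
    ("".join(c) for c in itertools.product("TCAG", repeat=3)),
    key=lambda c: ["TCAG".index(x) for x in c],
)
ORACLE_SENSE = [c for c in ORACLE_SENSE if c not in ORACLE_STOPS]
assert len(ORACLE_SENSE) == 61

_PURINE = set("AG")


def oracle_is_transition(a: str, b: str) -> bool:
    return (a in _PURINE) == (b in _PURINE)


def oracle_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Independent GY94 generator, scaled to one expected substitution/codon."""
    n = len(ORACLE_SENSE)
    Q = np.zeros((n, n))
    for i, ci in enumerate(ORACLE_SENSE):
        for j, cj in enumerate(ORACLE_SENSE):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = pi[j]
            if oracle_is_transition(ci[k], cj[k]):
                rate *= kappa
            if ORACLE_CODE[ci] != ORACLE_CODE[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -(pi * np.diag(Q)).sum()


def oracle_transition_matrix(kappa, omega, pi, t) -> np.ndarray:
    return expm(oracle_rate_matrix(kappa, omega, pi) * t)


def oracle_tree_log_likelihood(alignment, tree: Tree, kappa, omega, pi) -> float:
    """Brute-force lnL: explicit sum over all internal-node codon states."""
    idx = {c: i for i, c in enumerate(ORACLE_SENSE)}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    P = {
        node: oracle_transition_matrix(kappa, omega, pi, node.length)
        for node in tree.postorder()
        if node is not tree.root
    }
    seqs = {name: alignment[name] for name in tree.leaf_names}
    n_codons = len(alignment) // 3
    total = 0.0
    n_states = len(ORACLE_SENSE)
    for s in range(n_codons):
        leaf_state = {
            name: idx[seq[3 * s : 3 * s + 3]] for name, seq in seqs.items()
        }
        lik = 0.0
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            states = dict(zip(internals, assign))
            term = pi[states[tree.root]]
            for node in tree.postorder():
                if node is tree.root:
                    continue
                state = (
                    leaf_state[node.name] if node.is_leaf else states[node]
                )
                term *= P[node][states[node.parent], state]
            lik += term
        total += np.log(lik)
    return total


# ---------------------------------------------------------------------------
# common fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def quartet_tree() -> Tree:
    return Tree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")


@pytest.fixture(scope="session")
def star3_tree() -> Tree:
    return Tree.from_newick("(A:0.3,B:0.2,C:0.4);")
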