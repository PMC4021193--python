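"""Felsenstein pruning over the 61-state codon chain.

The engine is built once per (alignment, tree) pair: it compresses the
alignment to unique site patterns, fixes a post-order traversal, and then
evaluates per-site log-likelihoods for arbitrary (kappa, omega) classes.
Site-class mixtures (M3/M7/M8, branch-site model A) are log-sum-exp
combinations of per-class site likelihoods.

Branch lengths are interpreted as expected substitutions per codon; a
global multiplicative ``scale`` lets optimizers stretch a fixed input
topology without re-estimating every branch.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ._codon import N_SENSE
from .alignment import CodonAlignment
from .gy94 import get_process
from .trees import Tree


class LikelihoodEngine:
    def __init__(self, alignment: CodonAlignment, tree: Tree, pi: np.ndarray):
        leaf_names = tree.leaf_names
        if set(leaf_names) != set(alignment.names):
            raise ValueError(
                "tree leaves and alignment names differ: "
                f"{sorted(set(leaf_names) ^ set(alignment.names))}"
            )
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        idx = alignment.codon_indices()
        order = [alignment.names.index(n) for n in leaf_names]
        idx = idx[order, :]  # rows in tree leaf order
        patterns, inverse, counts = np.unique(
            idx, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.pattern_index = inverse.ravel()  # site -> pattern
        self.pattern_counts = counts.astype(float)
        self.n_sites = idx.shape[1]
        self.n_patterns = patterns.shape[1]
        self._postorder = list(tree.postorder())
        self._leaf_row = {name: r for r, name in enumerate(leaf_names)}
        # precomputed leaf partials: one-hot, or all-ones for gaps (-1)
        self._leaf_partials = {}
        for name, row in self._leaf_row.items():
            part = np.zeros((N_SENSE, self.n_patterns))
            codes = patterns[row]
            gap = codes < 0
            part[:, gap] = 1.0
            part[codes[~gap], np.nonzero(~gap)[0]] = 1.0
            self._leaf_partials[name] = part

    # -- per-class likelihoods -------------------------------------------
    def pattern_log_likelihood(
        self,
        kappa: float,
        scale: float,
        omega: float,
        omega_foreground: float | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood for one omega class.

        ``omega`` applies on background branches; ``omega_foreground`` (if
        given) applies on branches flagged foreground.
        """
        if omega_foreground is None:
            omega_foreground = omega
        logscale = np.zeros(self.n_patterns)
        partial: dict = {}
        for node in self._postorder:
            if node.is_leaf:
                partial[node] = self._leaf_partials[node.name]
                continue
            acc = np.ones((N_SENSE, self.n_patterns))
            for child in node.children:
                w = omega_foreground if child.foreground else omega
                proc = get_process(kappa, w, self.pi)
                P = proc.transition_matrix(child.length * scale)
                acc *= P @ partial.pop(child)
            # rescale to dodge underflow on deep trees
            m = acc.max(axis=0)
            m[m == 0] = 1.0
            acc /= m
            logscale += np.log(m)
            partial[node] = acc
        root = partial[self._postorder[-1]]
        lik = self.pi @ root
        return np.log(np.maximum(lik, 1e-300)) + logscale

    def site_log_likelihood_matrix(
        self,
        kappa: float,
        scale: float,
        omegas,
        omegas_foreground=None,
    ) -> np.ndarray:
        """(n_classes, n_sites) matrix of per-site log-likelihoods."""
        omegas = list(omegas)
        if omegas_foreground is None:
            omegas_foreground = omegas
        rows = []
        for w_bg, w_fg in zip(omegas, omegas_foreground):
            per_pattern = self.pattern_log_likelihood(kappa, scale, w_bg, w_fg)
            rows.append(per_pattern[self.pattern_index])
        return np.array(rows)

    def mixture_log_likelihood(
        self,
        kappa: float,
        scale: float,
        proportions,
        omegas,
        omegas_foreground=None,
    ) -> float:
        """Total lnL for a proportions-weighted omega-class mixture."""
        proportions = np.asarray(proportions, dtype=float)
        if abs(proportions.sum() - 1.0) > 1e-9 or (proportions < -1e-12).any():
            raise ValueError("class proportions must be nonnegative and sum to 1")
        # work on patterns, weight by counts
        logp = np.log(np.maximum(proportions, 1e-300))
        rows = []
        omegas = list(omegas)
        if omegas_foreground is None:
            omegas_foreground = omegas
        for w_bg, w_fg in zip(omegas, omegas_foreground):
            rows.append(self.pattern_log_likelihood(kappa, scale, w_bg, w_fg))
        per_pattern = logsumexp(np.array(rows) + logp[:, None], axis=0)
        return float(per_pattern @ self.pattern_counts)


def codon_log_likelihood(
    alignment: CodonAlignment,
    tree: Tree,
    kappa: float,
    omega: float,
    pi: np.ndarray,
    scale: float = 1.0,
) -> float:
    """Single-class (M0) log-likelihood of an alignment on a tree."""
    engine = LikelihoodEngine(alignment, tree, pi)
    return engine.mixture_log_likelihood(kappa, scale, [1.0], [omega])
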