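"""Goldman–Yang-style (GY94) codon substitution process.

The instantaneous rate from sense codon *i* to *j* is nonzero only for
single-nucleotide changes:

    q_ij ∝ pi_j                    synonymous transversion
    q_ij ∝ kappa * pi_j            synonymous transition
    q_ij ∝ omega * pi_j            nonsynonymous transversion
    q_ij ∝ kappa * omega * pi_j    nonsynonymous transition

Stop codons are excluded (61-state chain, standard code).  Each matrix is
scaled so the expected rate at stationarity is one substitution per codon
per unit branch length: -sum_i pi_i q_ii = 1.

The chain is reversible with respect to pi, so transition probabilities are
computed by a symmetric eigendecomposition, which is both faster and better
conditioned than a generic matrix exponential.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._codon import (
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    is_transition,
)


def _neighbor_tables():
    """Sparse structure of single-nucleotide codon changes."""
    pairs = []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ts = is_transition(ci[k], cj[k])
            syn = GENETIC_CODE[ci] == GENETIC_CODE[cj]
            pairs.append((i, j, ts, syn))
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    ts = np.array([p[2] for p in pairs])
    syn = np.array([p[3] for p in pairs])
    return rows, cols, ts, syn


_ROWS, _COLS, _IS_TS, _IS_SYN = _neighbor_tables()


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_codon_freqs(sequences) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    The product over the three codon positions, renormalized over the 61
    sense codons (the codeml CodonFreq=2 convention).  Gap characters are
    ignored.  A small pseudocount keeps simulated or short alignments away
    from structural zeros.
    """
    counts = np.full((3, 4), 0.1)
    order = {"T": 0, "C": 1, "A": 2, "G": 3}
    for seq in sequences:
        for j in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[j : j + 3]
            for pos, nt in enumerate(codon):
                if nt in order:
                    counts[pos, order[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled 61x61 GY94 generator; rows sum to zero."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("pi must be a 61-vector of frequencies summing to 1")
    Q = np.zeros((N_SENSE, N_SENSE))
    rate = pi[_COLS].copy()
    rate[_IS_TS] *= kappa
    rate[~_IS_SYN] *= omega
    Q[_ROWS, _COLS] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (omega = 0 with no synonymous rate?)")
    return Q / mean_rate


class CodonProcess:
    """A fixed (kappa, omega, pi) GY94 process with cached spectral form."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.pi = np.asarray(pi, dtype=float)
        self.Q = rate_matrix(kappa, omega, self.pi)
        # reversibility: D^{1/2} Q D^{-1/2} is symmetric (D = diag(pi))
        sqrt_pi = np.sqrt(np.maximum(self.pi, 1e-300))
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)
        self._evals, U = np.linalg.eigh(B)
        self._left = U / sqrt_pi[:, None]   # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, clipped at 0 for round-off."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@lru_cache(maxsize=256)
def _cached_process(kappa: float, omega: float, pi_key: tuple) -> CodonProcess:
    return CodonProcess(kappa, omega, np.array(pi_key))


def get_process(kappa: float, omega: float, pi: np.ndarray) -> CodonProcess:
    """Memoized CodonProcess; pi is keyed by value."""
    return _cached_process(round(kappa, 12), round(omega, 12), tuple(np.round(pi, 15)))
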