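"""Standard genetic code tables and codon-level predicates.

Everything downstream (the GY94 engine, the simulator, NG86 counting, 4DTv)
works on the 61 sense codons of the standard nuclear code, indexed in fixed
lexicographic order over the alphabet T, C, A, G (the ordering conventional
in codon-model software).
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_CODE_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

GENETIC_CODE: dict[str, str] = {
    "".join(c): aa
    for c, aa in zip(itertools.product(NUCLEOTIDES, repeat=3), _CODE_STRING)
}

STOP_CODONS: frozenset[str] = frozenset(
    c for c, aa in GENETIC_CODE.items() if aa == "*"
)

#: the 61 sense codons in fixed T<C<A<G lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in GENETIC_CODE if c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_SENSE = len(SENSE_CODONS)  # 61


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for *codon*; '*' for a stop."""
    return GENETIC_CODE[codon.upper().replace("U", "T")]


def translate(cds: str) -> str:
    """Translate an ungapped CDS; length must be a multiple of 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(
        translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)
    )


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def is_transversion(a: str, b: str) -> bool:
    return a != b and not is_transition(a, b)


def codon_diff_positions(c1: str, c2: str) -> list[int]:
    """0-based positions at which the two codons differ."""
    return [i for i in range(3) if c1[i] != c2[i]]


def is_fourfold_degenerate(codon: str) -> bool:
    """True if every third-position state yields the same amino acid.

    Only such codons contribute 4DTv sites.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        return False
    return all(GENETIC_CODE[codon[:2] + n] == aa for n in NUCLEOTIDES)


def single_step_neighbors(codon: str):
    """Yield (neighbor_codon, position, is_transition) for all 9 single-nt changes."""
    for pos in range(3):
        for n in NUCLEOTIDES:
            if n != codon[pos]:
                yield codon[:pos] + n + codon[pos + 1 :], pos, is_transition(
                    codon[pos], n
                )
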