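"""Aligned sequence containers: protein alignments and codon alignments."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import CODON_INDEX, STOP_CODONS

GAP_CHARS = "-."


@dataclass
class Alignment:
    """A generic equal-length alignment (protein or nucleotide)."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        records = list(SeqIO.parse(source, "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path=None) -> str | None:
        records = [
            SeqRecord(Seq(s), id=n, description="")
            for n, s in zip(self.names, self.sequences)
        ]
        if path is None:
            buf = io.StringIO()
            SeqIO.write(records, buf, "fasta")
            return buf.getvalue()
        SeqIO.write(records, path, "fasta")
        return None


@dataclass
class CodonAlignment(Alignment):
    """Gap-aware aligned CDS: each ungapped sequence is a multiple of 3.

    Gaps are only allowed in whole-codon units at aligned codon positions
    (the PAL2NAL convention), so the aligned length is a multiple of 3 and
    every aligned codon is either an intact triplet or ``---``.
    """

    def __post_init__(self):
        super().__post_init__()
        if len(self) % 3:
            raise ValueError("aligned length not a multiple of 3")
        for name, seq in zip(self.names, self.sequences):
            for j in range(0, len(seq), 3):
                codon = seq[j : j + 3]
                gaps = sum(c in GAP_CHARS for c in codon)
                if gaps not in (0, 3):
                    raise ValueError(
                        f"{name}: partial-gap codon {codon!r} at column {j + 1}"
                    )
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"{name}: stop codon {codon} at codon position {j // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codon(self, i_seq: int, j_codon: int) -> str:
        return self.sequences[i_seq][3 * j_codon : 3 * (j_codon + 1)]

    def codon_indices(self) -> np.ndarray:
        """(n_sequences, n_codons) array of sense-codon indices; -1 = gap/ambiguous."""
        out = np.full((self.n_sequences, self.n_codons), -1, dtype=np.int64)
        for i, seq in enumerate(self.sequences):
            for j in range(self.n_codons):
                out[i, j] = CODON_INDEX.get(seq[3 * j : 3 * j + 3], -1)
        return out

    def ungapped_pair_codons(self, name_a: str, name_b: str):
        """Codon pairs at columns where neither sequence is gapped/ambiguous."""
        a = self[name_a]
        b = self[name_b]
        pairs = []
        for j in range(0, len(a), 3):
            ca, cb = a[j : j + 3], b[j : j + 3]
            if ca in CODON_INDEX and cb in CODON_INDEX:
                pairs.append((ca, cb))
        return pairs
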