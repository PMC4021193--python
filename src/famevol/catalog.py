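"""Family-membership filtering and per-protein descriptive statistics.

Candidates enter the family when (i) both diagnostic Pfam domains —
DPBB_1/expansin domain I (PF03330) and Pollen_allerg_1/domain II (PF01357)
— hit with E-value at or below the cutoff, and (ii) the CDS is an integral
open reading frame: starts with ATG, ends with a stop codon, contains no
internal stop, and has length divisible by three.

Isoelectric points use a packaged Bjellqvist-style pKa set (the table
behind the ExPASy Compute pI/Mw tool) with bisection on the Henderson–
Hasselbalch net-charge function; molecular weights are average-mass sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._codon import STOP_CODONS, translate

DOMAIN_I = "PF03330"
DOMAIN_II = "PF01357"

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Bjellqvist pKa values as used by the ExPASy Compute pI/Mw tool.
#: N-terminal pKa depends on the first residue; C-terminal on the last.
PKA_SIDE_CHAIN = {
    "C": 9.00,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
    "Y": 10.00,
}
PKA_NTERM = {
    "A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36,
    "T": 6.82, "V": 7.44, "E": 7.70, "G": 7.50,
}
PKA_NTERM_DEFAULT = 7.50
# the C-terminal carboxyl pKa is context-independent here: residue-specific
# terminal values (e.g. a raised pKa for a C-terminal Asp) would make the pI
# non-monotone in added acidic residues
PKA_CTERM_DEFAULT = 3.55

POSITIVE_RESIDUES = "KRH"
NEGATIVE_RESIDUES = "DECY"


@dataclass
class GeneRecord:
    """One family candidate with its sequences and genomic context."""

    gene_id: str
    chromosome: str | None = None
    rank: int | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    cds: str | None = None
    protein: str | None = None
    subfamily: str | None = None
    signal_peptide_length: int | None = None  # pass-through annotation


@dataclass
class DomainHit:
    gene_id: str
    domain_accession: str
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("E-value must be nonnegative")


def has_integral_orf(cds: str) -> bool:
    """ATG start, stop end, no internal stop, length divisible by 3."""
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6 or len(cds) % 3:
        return False
    if not cds.startswith("ATG"):
        return False
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in STOP_CODONS:
        return False
    return not any(c in STOP_CODONS for c in codons[:-1])


def filter_family_members(
    candidates,
    hits,
    e_max: float = 1e-10,
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Apply the two-domain + E-value + integral-ORF filters.

    Returns (retained records, exclusions) where exclusions maps gene id to
    a reason code: ``missing_cds``, ``no_significant_hit``,
    ``single_domain``, or ``unintegrated_orf``.
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        if h.e_value <= e_max:
            by_gene.setdefault(h.gene_id, set()).add(h.domain_accession)
    retained: list[GeneRecord] = []
    excluded: dict[str, str] = {}
    for rec in candidates:
        if not rec.cds:
            excluded[rec.gene_id] = "missing_cds"
            continue
        domains = by_gene.get(rec.gene_id, set()) & {DOMAIN_I, DOMAIN_II}
        if not domains:
            excluded[rec.gene_id] = "no_significant_hit"
            continue
        if len(domains) == 1:
            excluded[rec.gene_id] = "single_domain"
            continue
        if not has_integral_orf(rec.cds):
            excluded[rec.gene_id] = "unintegrated_orf"
            continue
        retained.append(rec)
    return retained, excluded


# ---------------------------------------------------------------------------
# pI and Mw
# ---------------------------------------------------------------------------

def _check_standard(protein: str) -> str:
    protein = protein.upper().rstrip("*")
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return protein


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at the given pH."""
    protein = _check_standard(protein)
    pos = [PKA_NTERM.get(protein[0], PKA_NTERM_DEFAULT)]
    pos += [PKA_SIDE_CHAIN[a] for a in protein if a in POSITIVE_RESIDUES]
    neg = [PKA_CTERM_DEFAULT]
    neg += [PKA_SIDE_CHAIN[a] for a in protein if a in NEGATIVE_RESIDUES]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return charge


def compute_pi(protein: str, tol: float = 1e-4) -> float:
    """Isoelectric point: pH where the net charge crosses zero.

    Bisection on (0, 14); the charge function is strictly decreasing in pH,
    so the root is unique.  Converges to |charge| < *tol*.
    """
    protein = _check_standard(protein)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(protein, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)  # pragma: no cover


#: average residue masses (Da), computed from residue elemental
#: compositions with IUPAC standard atomic weights
#: (C 12.011, H 1.008, N 14.007, O 15.999, S 32.06)
RESIDUE_MASS = {
    "G": 57.0520, "A": 71.0790, "S": 87.0780, "P": 97.1170, "V": 99.1330,
    "T": 101.1050, "C": 103.1390, "L": 113.1600, "I": 113.1600,
    "N": 114.1040, "D": 115.0880, "Q": 128.1310, "K": 128.1750,
    "E": 129.1150, "M": 131.1930, "H": 137.1420, "F": 147.1770,
    "R": 156.1890, "Y": 163.1760, "W": 186.2140,
}
WATER_MASS = 18.015


def compute_mw(protein: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    protein = protein.upper().rstrip("*")
    if protein:
        _check_standard(protein)
        return sum(RESIDUE_MASS[a] for a in protein) + WATER_MASS
    return WATER_MASS  # empty chain: one water


@dataclass
class ProteinStats:
    gene_id: str
    length: int
    pi: float
    mw: float
    signal_peptide_length: int | None = None


def protein_stats(record: GeneRecord) -> ProteinStats:
    protein = record.protein or translate(record.cds).rstrip("*")
    protein = protein.rstrip("*")
    return ProteinStats(
        gene_id=record.gene_id,
        length=len(protein),
        pi=compute_pi(protein),
        mw=compute_mw(protein),
        signal_peptide_length=record.signal_peptide_length,
    )


# ---------------------------------------------------------------------------
# family summary
# ---------------------------------------------------------------------------

SUBFAMILIES = ("EXPA", "EXPB", "EXLA", "EXLB")


@dataclass
class FamilySummary:
    counts: dict[str, int]
    total: int
    tandem_pct: float | None = None
    segmental_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {**self.counts, "total": self.total}
        if self.tandem_pct is not None:
            row["tandem_pct"] = self.tandem_pct
        if self.segmental_pct is not None:
            row["segmental_pct"] = self.segmental_pct
        return pd.DataFrame([row])


def family_summary(members, duplication_flags=None) -> FamilySummary:
    """Per-subfamily counts plus duplication-class percentages (one decimal).

    *duplication_flags* maps gene id to a set drawn from
    {"tandem", "segmental"}.
    """
    members = list(members)
    counts = {s: 0 for s in SUBFAMILIES}
    for rec in members:
        if rec.subfamily is None:
            raise ValueError(f"{rec.gene_id}: missing subfamily label")
        counts[rec.subfamily] = counts.get(rec.subfamily, 0) + 1
    total = len(members)
    tandem_pct = segmental_pct = None
    if duplication_flags is not None:
        n_t = sum(
            1 for r in members if "tandem" in duplication_flags.get(r.gene_id, ())
        )
        n_s = sum(
            1 for r in members if "segmental" in duplication_flags.get(r.gene_id, ())
        )
        tandem_pct = round(100.0 * n_t / total, 1) if total else 0.0
        segmental_pct = round(100.0 * n_s / total, 1) if total else 0.0
    return FamilySummary(counts, total, tandem_pct, segmental_pct)
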