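"""Family identification by the four conserved domains, plus per-protein
descriptive statistics (length, molecular weight, isoelectric point).

Domain matching is Hamming (no indels) with a per-domain mismatch
tolerance; the short domains II and IV default to 0 mismatches to avoid
random hits, the longer I and III to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

# conserved family domains: name -> amino-acid motif
DEFAULT_DOMAIN_MOTIFS = {
    "I": "SPNTDGI",
    "II": "GDDC",
    "III": "CGPGHGIS",
    "IV": "RIK",
}
DEFAULT_TOLERANCE = {"I": 1, "II": 0, "III": 1, "IV": 0}

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Average masses of the free amino acids (Da) and of water; residue mass in
# a chain = free mass minus one water per peptide bond.
DEFAULT_MASS_TABLE = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}
WATER_MASS = 18.02

# EMBOSS-style pKa values for ionizable groups
DEFAULT_PKA_TABLE = {
    "n_term": 8.6, "c_term": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,       # basic (positive when protonated)
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # acidic
}
_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


class IdentifyError(ValueError):
    pass


@dataclass
class DomainHit:
    domain: str
    start: int          # 1-based position in the protein
    mismatches: int
    best: bool = False  # fewest mismatches, then leftmost, within its domain


@dataclass
class PGClassification:
    is_pg: bool
    composition: frozenset


@dataclass
class ProteinStats:
    length: int
    molecular_weight: float
    isoelectric_point: float
    signal_peptide: int | None = None  # externally supplied length, if any


def _check_protein(protein: str) -> str:
    if not protein:
        raise IdentifyError("empty protein sequence")
    protein = protein.upper().rstrip("*")
    bad = set(protein) - AA20
    if bad:
        raise IdentifyError(f"unknown residue characters {sorted(bad)}")
    return protein


def scan_domains(protein: str, motif_defs: dict[str, str] | None = None,
                 tolerance_per_domain: dict[str, int] | None = None
                 ) -> list[DomainHit]:
    """Report every window within the per-domain Hamming tolerance; the best
    hit (fewest mismatches, then leftmost) per domain is flagged."""
    protein = _check_protein(protein)
    motifs = motif_defs or DEFAULT_DOMAIN_MOTIFS
    tolerances = dict(DEFAULT_TOLERANCE if tolerance_per_domain is None
                      else tolerance_per_domain)
    hits: list[DomainHit] = []
    for domain, motif in motifs.items():
        tol = tolerances.get(domain, 0)
        domain_hits = []
        for start in range(len(protein) - len(motif) + 1):
            window = protein[start:start + len(motif)]
            mismatches = sum(1 for a, b in zip(window, motif) if a != b)
            if mismatches <= tol:
                domain_hits.append(DomainHit(domain, start + 1, mismatches))
        if domain_hits:
            best = min(domain_hits, key=lambda h: (h.mismatches, h.start))
            best.best = True
        hits.extend(domain_hits)
    return hits


def classify_pg(hits: list[DomainHit]) -> PGClassification:
    """A protein with at least one conserved-domain hit is a family member."""
    composition = frozenset(h.domain for h in hits)
    return PGClassification(bool(composition), composition)


def _net_charge(protein: str, ph: float, pka: dict[str, float]) -> float:
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for res in _BASIC:
        pos += protein.count(res) / (1.0 + 10.0 ** (ph - pka[res]))
    for res in _ACIDIC:
        neg += protein.count(res) / (1.0 + 10.0 ** (pka[res] - ph))
    return pos - neg


def protein_stats(protein: str, pka_table: dict[str, float] | None = None,
                  mass_table: dict[str, float] | None = None,
                  signal_peptide: int | None = None) -> ProteinStats:
    """Length, molecular weight (sum of monomer masses minus peptide-bond
    water) and isoelectric point (bisection on Henderson-Hasselbalch net
    charge to |charge| < 1e-4)."""
    protein = _check_protein(protein)
    pka = pka_table or DEFAULT_PKA_TABLE
    masses = mass_table or DEFAULT_MASS_TABLE
    mw = sum(masses[res] for res in protein) - (len(protein) - 1) * WATER_MASS
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        charge = _net_charge(protein, mid, pka)
        if abs(charge) < 1e-4:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    else:  # pragma: no cover - bisection always converges on [0, 14]
        raise IdentifyError("pI solver failed to converge")
    return ProteinStats(len(protein), mw, mid, signal_peptide)
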