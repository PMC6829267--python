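"""Physicochemical protein profiling: molecular weight, isoelectric point,
GRAVY, instability index and aliphatic index for a residue sequence.

The conventions follow ExPASy ProtParam: average (not monoisotopic)
residue masses plus one water; GRAVY as the mean Kyte-Doolittle
hydropathy; the Guruprasad dipeptide-weight instability index (< 40
predicts an in-vitro-stable protein); the Ikai aliphatic index
X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu) over mole percents; and the
Bjellqvist pKa set (with residue-specific terminal pKa values) for pI.

The Kyte-Doolittle and DIWV dipeptide tables are taken from
``Bio.SeqUtils.ProtParamData`` (published data shipped with Biopython);
all arithmetic is done here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data.IUPACData import protein_weights as _AVG_RESIDUE_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

__all__ = [
    "PropertyBlock",
    "gravy",
    "molecular_weight",
    "isoelectric_point",
    "instability_index",
    "aliphatic_index",
    "property_block",
    "property_table",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
WATER_DA = 18.0153

# Bjellqvist pKa values as used by ProtParam. Terminal pKa values are
# residue-specific where Bjellqvist measured them.
_PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
_PKA_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}


def _check_residues(protein: str) -> str:
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
    return protein


@dataclass(frozen=True)
class PropertyBlock:
    """The physicochemical profile of one protein.

    ``mw`` is in kDa, ``pi`` in pH units; the other indices are
    dimensionless. ``stable`` is the instability-index < 40 call.
    """

    length: int
    mw: float
    pi: float
    gravy: float
    instability: float
    aliphatic: float

    @property
    def stable(self) -> bool:
        return self.instability < 40.0


def gravy(protein: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle hydropathy.

    Negative values indicate a hydrophilic protein.
    """
    protein = _check_residues(protein)
    return sum(_KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)


def molecular_weight(protein: str) -> float:
    """Average-isotope molecular weight in kDa.

    Sum of average residue masses plus one water (18.0153 Da).
    """
    protein = _check_residues(protein)
    # protein_weights are free-amino-acid masses; each peptide bond loses water.
    da = sum(_AVG_RESIDUE_WEIGHTS[aa] for aa in protein) - WATER_DA * (len(protein) - 1)
    return da / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH under the Bjellqvist pKa model.

    Basic groups contribute 1/(1+10^(pH-pKa)); acidic groups contribute
    -1/(1+10^(pKa-pH)); the termini use residue-specific pKa values
    where available.
    """
    protein = _check_residues(protein)
    counts: dict[str, int] = {}
    for aa in protein:
        counts[aa] = counts.get(aa, 0) + 1

    pos = 0.0
    nterm_pka = _PKA_NTERM_BY_RESIDUE.get(protein[0], _PKA_POSITIVE["Nterm"])
    pos += 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    for aa in ("K", "R", "H"):
        if counts.get(aa):
            pos += counts[aa] / (1.0 + 10 ** (ph - _PKA_POSITIVE[aa]))

    neg = 0.0
    cterm_pka = _PKA_CTERM_BY_RESIDUE.get(protein[-1], _PKA_NEGATIVE["Cterm"])
    neg += 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa in ("D", "E", "C", "Y"):
        if counts.get(aa):
            neg += counts[aa] / (1.0 + 10 ** (_PKA_NEGATIVE[aa] - ph))

    return pos - neg


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero (bisection on [0, 14]).

    The charge function is strictly decreasing in pH, so the root is
    unique; bisection runs until |charge| < ``tol``.
    """
    protein = _check_residues(protein)
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(protein, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def instability_index(protein: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights.

    Values >= 40 predict an unstable protein in a test tube.
    """
    protein = _check_residues(protein)
    if len(protein) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = 0.0
    for a, b in zip(protein, protein[1:]):
        total += _DIWV[a][b]
    return 10.0 / len(protein) * total


def aliphatic_index(protein: str) -> float:
    """Ikai aliphatic index: relative volume of aliphatic side chains.

    X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu), X in mole percent.
    """
    protein = _check_residues(protein)
    n = len(protein)
    x = {aa: 100.0 * protein.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def property_block(protein: str) -> PropertyBlock:
    """Compute the full property block at full precision."""
    protein = _check_residues(protein)
    return PropertyBlock(
        length=len(protein),
        mw=molecular_weight(protein),
        pi=isoelectric_point(protein),
        gravy=gravy(protein),
        instability=instability_index(protein),
        aliphatic=aliphatic_index(protein),
    )


def property_table(records: Iterable[tuple[str, str]]):
    """Property blocks for many proteins as a tidy DataFrame.

    Columns mirror the classic characterization-table layout: Gene,
    Length, MW_kDa, pI, Instability, Aliphatic, GRAVY, Stable. Numbers
    are rounded half-up to 2 decimals for presentation; use
    :func:`property_block` for full precision.
    """
    import pandas as pd

    def round2(x: float) -> float:
        # round-half-up at 2 decimals
        from decimal import Decimal, ROUND_HALF_UP

        return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))

    rows = []
    for rid, seq in records:
        b = property_block(seq)
        rows.append(
            {
                "Gene": rid,
                "Length": b.length,
                "MW_kDa": round2(b.mw),
                "pI": round2(b.pi),
                "Instability": round2(b.instability),
                "Aliphatic": round2(b.aliphatic),
                "GRAVY": round2(b.gravy),
                "Stable": b.stable,
            }
        )
    return pd.DataFrame(rows)
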