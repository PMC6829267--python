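"""Promoter extraction and degenerate cis-element scanning.

The promoter of a gene is the 1000 bp immediately upstream of its start
codon (measured from the CDS start; transcript starts are typically
unknown for draft genomes), reported on the gene's strand. Promoters
are scanned for the CRT/DRE low-temperature response element (G/ACCGAC,
IUPAC RCCGAC) and for a catalogue of named consensus cis-elements,
producing a gene x element count grid.

Patterns are IUPAC-degenerate consensus strings, not PWMs; matching is
exact set membership per position, overlapping matches are all
reported, and an N in the promoter matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import Contig, GeneModel, reverse_complement

__all__ = [
    "IUPAC",
    "MotifPattern",
    "CRT_DRE",
    "DEFAULT_CATALOGUE",
    "PromoterSequence",
    "MotifHit",
    "extract_promoter",
    "extract_promoters",
    "scan_motif",
    "scan_catalogue",
    "count_hits",
    "read_catalogue_tsv",
    "hits_to_bed",
]

IUPAC: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC-degenerate nucleotide pattern."""

    name: str
    iupac: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        pat = self.iupac.upper()
        if len(pat) < 4:
            raise ValueError(f"motif {self.name!r}: length must be >= 4")
        bad = [c for c in pat if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC code(s) {bad}")
        if set(pat) == {"N"}:
            raise ValueError(f"motif {self.name!r}: all-N pattern carries no information")
        object.__setattr__(self, "iupac", pat)

    def __len__(self) -> int:
        return len(self.iupac)


# The C-repeat / dehydration-responsive element bound by CBF
# transcription factors: G/ACCGAC. Scanned on both strands by default.
CRT_DRE = MotifPattern("CRT/DRE", "RCCGAC", both_strands=True)

# Built-in catalogue of common plant promoter cis-elements (canonical
# consensus patterns; users may override with their own table).
DEFAULT_CATALOGUE: tuple[MotifPattern, ...] = (
    MotifPattern("CRT/DRE", "RCCGAC"),
    MotifPattern("G-box", "CACGTG"),
    MotifPattern("ABRE", "ACGTGGC"),
    MotifPattern("CGTCA-motif", "CGTCA"),
    MotifPattern("TGACG-motif", "TGACG"),
    MotifPattern("MBS", "CAACTG"),
    MotifPattern("LTR", "CCGAAA"),
    MotifPattern("ERE", "ATTTTAAA"),
    MotifPattern("TGA-element", "AACGAC"),
    MotifPattern("TATC-box", "TATCCCA"),
    MotifPattern("GARE-motif", "TCTGTTG"),
    MotifPattern("Box4", "ATTAAT"),
    MotifPattern("Sp1", "GGGCGG"),
    MotifPattern("GATA-motif", "AAGATAAGATT"),
    MotifPattern("TCT-motif", "TCTTAC"),
)


@dataclass(frozen=True)
class PromoterSequence:
    """An upstream promoter window, oriented on the gene's strand.

    ``window_start``/``window_end`` are 0-based half-open genome
    coordinates of the window on the contig; ``sequence`` ends just
    before the start codon. ``truncated`` marks windows clipped at a
    contig edge (length < the requested window).
    """

    gene_id: str
    contig_id: str
    strand: str
    sequence: str
    window_start: int
    window_end: int
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a promoter.

    ``offset`` is 0-based within the promoter (gene-strand orientation);
    ``strand`` is the match strand relative to the promoter; ``length``
    is the match (pattern) length.
    """

    gene_id: str
    motif: str
    offset: int
    strand: str
    length: int = 6


def extract_promoter(
    gene: GeneModel,
    contigs: Mapping[str, str],
    length: int = 1000,
) -> PromoterSequence:
    """The up-to-``length`` bp window upstream of the start codon.

    Plus-strand genes read genomic [start-length, start) as-is; minus
    strand genes read (end, end+length] reverse-complemented. Windows
    are clipped at contig edges and flagged ``truncated``.
    """
    if gene.contig_id not in contigs:
        raise KeyError(f"contig {gene.contig_id!r} not in genome")
    contig_seq = contigs[gene.contig_id].upper()
    clen = len(contig_seq)
    if gene.strand == "+":
        end = gene.cds_start
        start = max(0, end - length)
        seq = contig_seq[start:end]
    else:
        start = gene.cds_end
        end = min(clen, start + length)
        seq = reverse_complement(contig_seq[start:end])
    return PromoterSequence(
        gene_id=gene.gene_id,
        contig_id=gene.contig_id,
        strand=gene.strand,
        sequence=seq,
        window_start=start,
        window_end=end,
        truncated=len(seq) < length,
    )


def extract_promoters(
    genes: Sequence[GeneModel],
    contigs: Mapping[str, str],
    length: int = 1000,
    drop_empty: bool = True,
) -> list[PromoterSequence]:
    """Promoters for many genes; zero-length windows are warned about
    and (by default) excluded from downstream scans."""
    import warnings

    out = []
    for g in genes:
        p = extract_promoter(g, contigs, length=length)
        if len(p) == 0:
            warnings.warn(f"gene {g.gene_id}: empty promoter window (contig edge)")
            if drop_empty:
                continue
        out.append(p)
    return out


import numpy as np

# byte lookup tables per IUPAC code: allowed[code][byte] is True when the
# sequence base may sit under that pattern position (N in the sequence
# matches nothing, so only A/C/G/T bytes are ever allowed)
_ALLOWED: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC.items():
    _tab = np.zeros(256, dtype=bool)
    for _b in _bases:
        _tab[ord(_b)] = True
    _ALLOWED[_code] = _tab


def _match_offsets(seq_bytes: np.ndarray, pat: str) -> np.ndarray:
    """0-based start offsets of all matches of an IUPAC pattern."""
    k = len(pat)
    n = seq_bytes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off, code in enumerate(pat):
        valid &= _ALLOWED[code][seq_bytes[off : off + n]]
    return np.nonzero(valid)[0]


def scan_motif(promoter: PromoterSequence | str, motif: MotifPattern,
               gene_id: str | None = None) -> list[MotifHit]:
    """All (overlapping) occurrences of a motif in a promoter.

    Forward-strand matches are reported with strand '+'; if the motif
    scans both strands, occurrences of its reverse complement in the
    promoter string are reported with strand '-' at the offset where
    the reverse-complement string begins. Hits are sorted by offset.
    """
    if isinstance(promoter, PromoterSequence):
        seq = promoter.sequence
        gid = promoter.gene_id
    else:
        seq = promoter.upper()
        gid = gene_id or ""
    k = len(motif)
    pats = [(motif.iupac, "+")]
    if motif.both_strands:
        rc = reverse_complement(motif.iupac)
        # A palindromic pattern's reverse-strand hits coincide with its
        # forward hits; report each site once.
        if rc != motif.iupac:
            pats.append((rc, "-"))
    seq_bytes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    found: list[tuple[int, str]] = []
    for pat, strand in pats:
        found.extend((int(pos), strand) for pos in _match_offsets(seq_bytes, pat))
    found.sort()
    return [
        MotifHit(gene_id=gid, motif=motif.name, offset=pos, strand=strand, length=k)
        for pos, strand in found
    ]


def scan_catalogue(
    promoters: Sequence[PromoterSequence],
    catalogue: Sequence[MotifPattern],
) -> pd.DataFrame:
    """Gene x element count grid (zero cells retained)."""
    names = [m.name for m in catalogue]
    if len(set(names)) != len(names):
        raise ValueError("duplicate catalogue names")
    grid = pd.DataFrame(
        0,
        index=[p.gene_id for p in promoters],
        columns=names,
        dtype=int,
    )
    for p in promoters:
        for m in catalogue:
            grid.loc[p.gene_id, m.name] = len(scan_motif(p, m))
    grid.index.name = "gene_id"
    return grid


def count_hits(
    promoters: Sequence[PromoterSequence],
    motif: MotifPattern = CRT_DRE,
) -> dict[str, int]:
    """Per-gene occurrence counts of one motif (both strands unless the
    pattern says otherwise)."""
    return {p.gene_id: len(scan_motif(p, motif)) for p in promoters}


def read_catalogue_tsv(path: str | Path) -> list[MotifPattern]:
    """Read a name -> IUPAC pattern table (TSV: name, pattern[, strands])."""
    out: list[MotifPattern] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            both = True
            if len(parts) >= 3:
                both = parts[2].strip().lower() not in {"plus", "+", "forward", "false"}
            out.append(MotifPattern(parts[0], parts[1], both_strands=both))
    if not out:
        raise ValueError(f"{path}: empty cis-element catalogue")
    return out


def hits_to_bed(
    hits: Iterable[MotifHit],
    promoters: Mapping[str, PromoterSequence] | None = None,
) -> str:
    """BED6 text for motif hits.

    Promoter-relative by default (chrom = gene id). When ``promoters``
    maps gene ids to their windows, hits are projected onto genome
    coordinates instead (chrom = contig; strand composed with the gene
    strand).
    """
    lines = []
    for h in hits:
        if promoters is None:
            lines.append(
                f"{h.gene_id}\t{h.offset}\t{h.offset + h.length}"
                f"\t{h.motif}\t0\t{h.strand}"
            )
        else:
            p = promoters[h.gene_id]
            if p.strand == "+":
                gstart = p.window_start + h.offset
            else:
                gstart = p.window_end - (h.offset + h.length)
            gstrand = h.strand if p.strand == "+" else ("-" if h.strand == "+" else "+")
            lines.append(
                f"{p.contig_id}\t{gstart}\t{gstart + h.length}"
                f"\t{h.motif}\t0\t{gstrand}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
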