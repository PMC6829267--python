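"""Sequence and annotation IO: FASTA, GFF3 gene models, and the two
sequence primitives (reverse complement, translation) the rest of the
pipeline consumes.

Coordinate convention: GFF3 files are 1-based inclusive on disk; every
in-memory coordinate in this package is 0-based half-open. The conversion
happens here, in the readers/writers, and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "Contig",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "reverse_complement",
    "translate",
    "spliced_cds",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
# IUPAC degenerate nucleotide codes; needed so degenerate motifs can be
# reverse-complemented with the same primitive as plain sequence.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence (one FASTA record of a genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("contig id must be nonempty")
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        bad = set(seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One gene's CDS layout on a contig.

    ``cds_segments`` are 0-based half-open intervals in genome coordinates,
    non-overlapping and sorted ascending (genome order, regardless of
    strand). ``cds_start``/``cds_end`` span the whole CDS.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.cds_segments:
            raise FormatError(f"gene {self.gene_id!r}: no CDS segments")
        segs = tuple(sorted((int(a), int(b)) for a, b in self.cds_segments))
        for a, b in segs:
            if a < 0 or b <= a:
                raise FormatError(
                    f"gene {self.gene_id!r}: invalid CDS segment ({a}, {b})"
                )
        for (_, b0), (a1, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise FormatError(
                    f"gene {self.gene_id!r}: overlapping CDS segments"
                )
        object.__setattr__(self, "cds_segments", segs)

    @property
    def cds_start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    def is_coding_complete(self) -> bool:
        return self.cds_length % 3 == 0


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    ``alphabet`` may be ``"nucleotide"`` or ``"protein"`` to validate
    residues (case-insensitive; sequences are uppercased). The id is the
    header token before the first whitespace.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    allowed = None
    if alphabet == "nucleotide":
        allowed = NUCLEOTIDE_ALPHABET
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    elif alphabet is not None:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if allowed is not None:
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"{path.name}: record {rec.id!r} has invalid "
                    f"{alphabet} characters {sorted(bad)}"
                )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as multi-line FASTA with LF endings."""
    with open(path, "w", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file, grouped by their Parent gene.

    Only ``CDS`` rows are consumed; the Parent attribute (falling back to
    ID) names the gene. Coordinates are converted from 1-based inclusive
    to 0-based half-open. Genes are returned in order of first appearance.
    """
    path = Path(path)
    by_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise FormatError(
                    f"{path.name}:{lineno}: CDS start {start} > end {end}"
                )
            if strand not in {"+", "-"}:
                raise FormatError(
                    f"{path.name}:{lineno}: unknown strand {strand!r}"
                )
            attrs = _gff3_attributes(col9)
            parent = attrs.get("Parent") or attrs.get("ID")
            if not parent:
                raise FormatError(
                    f"{path.name}:{lineno}: CDS with no Parent/ID attribute"
                )
            entry = by_gene.get(parent)
            if entry is None:
                entry = {"contig": seqid, "strand": strand, "segments": []}
                by_gene[parent] = entry
                order.append(parent)
            if entry["contig"] != seqid or entry["strand"] != strand:
                raise FormatError(
                    f"{path.name}:{lineno}: CDS of gene {parent!r} on "
                    "inconsistent contig/strand"
                )
            entry["segments"].append((start - 1, end))  # to 0-based half-open
    return [
        GeneModel(
            gene_id=g,
            contig_id=by_gene[g]["contig"],
            strand=by_gene[g]["strand"],
            cds_segments=tuple(by_gene[g]["segments"]),
        )
        for g in order
    ]


def write_gff3(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 gene + CDS rows (1-based inclusive)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id, "cbfsurvey", "gene",
                        str(g.cds_start + 1), str(g.cds_end), ".",
                        g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for a, b in g.cds_segments:
                fh.write(
                    "\t".join(
                        [
                            g.contig_id, "cbfsurvey", "CDS",
                            str(a + 1), str(b), ".", g.strand, "0",
                            f"ID={g.gene_id}.cds;Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) nucleotide string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise FormatError(f"non-nucleotide character {exc.args[0]!r}") from None


def translate(cds: str, permissive: bool = False) -> str:
    """Translate a CDS with the standard genetic code.

    A single terminal stop is excluded from the returned residues. An
    internal stop raises unless ``permissive``, in which case translation
    is truncated at the first stop with a warning.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FormatError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - NUCLEOTIDE_ALPHABET
    if bad:
        raise FormatError(f"CDS contains non-nucleotide characters {sorted(bad)}")
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        if not permissive:
            pos = protein.index("*")
            raise FormatError(f"internal stop codon at residue {pos}")
        warnings.warn("internal stop codon; truncating translation")
        protein = protein.split("*", 1)[0]
    return protein


def spliced_cds(gene: GeneModel, contigs: dict[str, str]) -> str:
    """Concatenate a gene's CDS segments in 5'->3' (coding) orientation."""
    if gene.contig_id not in contigs:
        raise KeyError(f"contig {gene.contig_id!r} not in genome")
    seq = contigs[gene.contig_id].upper()
    joined = "".join(seq[a:b] for a, b in gene.cds_segments)
    if gene.strand == "-":
        joined = reverse_complement(joined)
    return joined
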