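"""CBF-family candidate identification.

CBF/DREB1 proteins are AP2/ERF transcription factors whose ~60-residue
AP2 DNA-binding domain is flanked by two short signature sequences:
PKK/RPAGRxKFxETRHP upstream and DSAWR downstream. A candidate is
accepted when it (a) scores above a homology threshold in an exact
Smith-Waterman local alignment against a seed CBF, and (b) carries both
signatures in order with a plausible separation (the AP2 domain sits
between them).

Alignment is delegated to Bio.Align.PairwiseAligner with BLOSUM62 and
affine gaps (a gap of length k costs open + (k-1)*extend; defaults
open=11, extend=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import reverse_complement

__all__ = [
    "SignaturePattern",
    "SIGNATURE_S1",
    "SIGNATURE_S2",
    "CandidateHit",
    "Thresholds",
    "smith_waterman",
    "self_score",
    "match_signature",
    "verify_candidate",
    "identify_family",
    "six_frame_peptides",
    "write_hits_tsv",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SignaturePattern:
    """An ordered residue-class pattern with a mismatch budget.

    ``elements`` holds one ``frozenset`` of allowed residues per
    position, or ``None`` for a wildcard; wildcards never count as
    mismatches.
    """

    name: str
    elements: tuple[frozenset | None, ...]
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.elements) < 3:
            raise ValueError(f"pattern {self.name!r}: length must be >= 3")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for el in self.elements:
            if el is not None and (not el or not el <= frozenset(AA20)):
                raise ValueError(f"pattern {self.name!r}: bad residue set {el}")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def parse(cls, name: str, pattern: str, max_mismatches: int = 0) -> "SignaturePattern":
        """Parse e.g. ``"PK[KR]PAGRxKFxETRHP"``; ``x``/``X``/``.`` = wildcard."""
        elements: list[frozenset | None] = []
        i = 0
        while i < len(pattern):
            c = pattern[i]
            if c == "[":
                j = pattern.index("]", i)
                elements.append(frozenset(pattern[i + 1 : j].upper()))
                i = j + 1
            elif c in "xX.":
                elements.append(None)
                i += 1
            else:
                elements.append(frozenset(c.upper()))
                i += 1
        return cls(name=name, elements=tuple(elements), max_mismatches=max_mismatches)


# The two CBF signature sequences flanking the AP2 domain. K/R at
# position 3 of S1 is a residue class; x positions are wildcards.
SIGNATURE_S1 = SignaturePattern.parse("S1", "PK[KR]PAGRxKFxETRHP", max_mismatches=2)
SIGNATURE_S2 = SignaturePattern.parse("S2", "DSAWR", max_mismatches=0)


@dataclass(frozen=True)
class CandidateHit:
    """One screened protein: homology score, signature layout, verdict."""

    protein_id: str
    sw_score: float
    s1_start: int  # 0-based residue offset; -1 when absent
    s2_start: int
    separation: int  # residues between S1 end and S2 start; -1 when undefined
    accepted: bool


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds for :func:`verify_candidate`.

    ``min_score_frac`` scales the seed's Smith-Waterman self-score;
    ``separation`` bounds the S1-end to S2-start gap (the AP2 domain is
    about 60 residues, so the default window is [40, 120]).
    """

    min_score_frac: float = 0.4
    separation: tuple[int, int] = (40, 120)


def _aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if gap_open < gap_extend or gap_extend <= 0:
        raise ValueError("require gap_open >= gap_extend > 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def smith_waterman(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
):
    """Exact local alignment score and best alignment.

    Returns ``(score, alignment)``; ``alignment`` is ``None`` when the
    best local score is 0 (empty alignment).
    """
    query, subject = query.upper(), subject.upper()
    if not query or not subject:
        raise ValueError("empty sequence")
    for seq in (query, subject):
        bad = set(seq) - set(AA20)
        if bad:
            raise ValueError(f"unknown residue(s) {sorted(bad)}")
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, None
    return score, next(iter(aligner.align(query, subject)))


def self_score(seq: str, matrix: str = "BLOSUM62") -> float:
    """Sum of diagonal substitution scores (score of a perfect self-match)."""
    m = substitution_matrices.load(matrix)
    return float(sum(m[aa, aa] for aa in seq.upper()))


def match_signature(protein: str, pattern: SignaturePattern) -> list[tuple[int, int]]:
    """All windows matching ``pattern`` within its mismatch budget.

    Returns ``(start, mismatches)`` pairs sorted by start; wildcard
    positions never count as mismatches.
    """
    protein = protein.upper()
    L, k = len(protein), len(pattern)
    hits: list[tuple[int, int]] = []
    for start in range(L - k + 1):
        mism = 0
        for off, allowed in enumerate(pattern.elements):
            if allowed is None:
                continue
            if protein[start + off] not in allowed:
                mism += 1
                if mism > pattern.max_mismatches:
                    break
        else:
            hits.append((start, mism))
    return hits


def verify_candidate(
    protein_id: str,
    protein: str,
    sw_score: float,
    min_score: float,
    separation: tuple[int, int] = (40, 120),
    s1: SignaturePattern = SIGNATURE_S1,
    s2: SignaturePattern = SIGNATURE_S2,
) -> CandidateHit:
    """Combine the homology score with the two-signature layout check.

    Accepted iff ``sw_score >= min_score`` and some S1 hit precedes some
    S2 hit with S1-end to S2-start separation inside ``separation``.
    When several layouts qualify the leftmost (s1, then s2) is reported.
    """
    lo, hi = separation
    s1_hits = match_signature(protein, s1)
    s2_hits = match_signature(protein, s2)
    best: tuple[int, int] | None = None
    for s1_start, _ in s1_hits:
        s1_end = s1_start + len(s1)
        for s2_start, _ in s2_hits:
            sep = s2_start - s1_end
            if s1_start < s2_start and lo <= sep <= hi:
                best = (s1_start, s2_start)
                break
        if best:
            break
    if best is not None:
        s1_start, s2_start = best
        sep = s2_start - (s1_start + len(s1))
        accepted = sw_score >= min_score
    else:
        s1_start = s1_hits[0][0] if s1_hits else -1
        s2_start = s2_hits[0][0] if s2_hits else -1
        sep = -1
        accepted = False
    return CandidateHit(
        protein_id=protein_id,
        sw_score=sw_score,
        s1_start=s1_start,
        s2_start=s2_start,
        separation=sep,
        accepted=accepted,
    )


def identify_family(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    min_score_frac: float = 0.4,
    separation: tuple[int, int] = (40, 120),
    s1: SignaturePattern = SIGNATURE_S1,
    s2: SignaturePattern = SIGNATURE_S2,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[CandidateHit]:
    """Screen a proteome against seed sequences.

    Each subject's homology score is its best Smith-Waterman score over
    the seeds; the acceptance threshold is ``min_score_frac`` times the
    self-score of the seed achieving that best score.
    """
    if not queries:
        raise ValueError("need at least one query seed")
    selfs = [self_score(q, matrix) for _, q in queries]
    hits: list[CandidateHit] = []
    for sid, sseq in subjects:
        best_score, best_self = 0.0, selfs[0]
        for (qid, qseq), qself in zip(queries, selfs):
            score, _ = smith_waterman(sseq, qseq, matrix, gap_open, gap_extend)
            if score > best_score:
                best_score, best_self = score, qself
        hits.append(
            verify_candidate(
                sid, sseq, best_score,
                min_score=min_score_frac * best_self,
                separation=separation, s1=s1, s2=s2,
            )
        )
    return hits


def six_frame_peptides(nuc_seq: str, min_len: int = 30) -> list[tuple[str, int, str]]:
    """Stop-delimited peptides from all six reading frames.

    Returns ``(frame, aa_offset, peptide)`` with frame in {+1,+2,+3,-1,
    -2,-3}, longest peptides first (the tie-break used when screening
    genomes rather than proteomes).
    """
    out: list[tuple[str, int, str]] = []
    for strand, seq in (("+", nuc_seq.upper()), ("-", reverse_complement(nuc_seq))):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = _translate_through_stops(sub)
            pos = 0
            for pep in prot.split("*"):
                if len(pep) >= min_len:
                    out.append((f"{strand}{frame + 1}", pos, pep))
                pos += len(pep) + 1
    out.sort(key=lambda t: -len(t[2]))
    return out


def _translate_through_stops(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate(table=1))


def write_hits_tsv(hits: Iterable[CandidateHit], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tsw_score\ts1_start\ts2_start\tseparation\taccepted\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.sw_score:.1f}\t{h.s1_start}\t{h.s2_start}"
                f"\t{h.separation}\t{str(h.accepted).lower()}\n"
            )
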