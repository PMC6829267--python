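"""Promoter extraction arithmetic and IUPAC motif scanning, with a
regex-expansion brute-force oracle."""

import re

import numpy as np
import pytest

from cbfsurvey.promoter_scan import (
    CRT_DRE,
    DEFAULT_CATALOGUE,
    IUPAC,
    MotifPattern,
    PromoterSequence,
    extract_promoter,
    extract_promoters,
    hits_to_bed,
    scan_catalogue,
    scan_motif,
)
from cbfsurvey.seqio import GeneModel, reverse_complement


def regex_oracle(seq: str, motif: MotifPattern):
    """Overlap-aware regex expansion of the IUPAC pattern, both strands."""

    def to_regex(pat: str) -> str:
        return "(?=" + "".join(
            c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
            for c in pat
        ) + ")"

    hits = [(m.start(), "+") for m in re.finditer(to_regex(motif.iupac), seq)]
    if motif.both_strands:
        rc = reverse_complement(motif.iupac)
        if rc != motif.iupac:
            hits += [(m.start(), "-") for m in re.finditer(to_regex(rc), seq)]
    return sorted(hits)


def promoter(seq: str, gid: str = "g") -> PromoterSequence:
    return PromoterSequence(
        gene_id=gid, contig_id="c", strand="+", sequence=seq,
        window_start=0, window_end=len(seq), truncated=False,
    )


def test_motif_pattern_validation():
    with pytest.raises(ValueError):
        MotifPattern("short", "ACG")
    with pytest.raises(ValueError):
        MotifPattern("bad", "ACGQ")
    with pytest.raises(ValueError):
        MotifPattern("allN", "NNNN")


def test_extract_promoter_plus_strand_window():
    contig = "A" * 5000
    gene = GeneModel("g", "c", "+", ((2000, 2300),))  # 1-based start 2001
    p = extract_promoter(gene, {"c": contig})
    assert (p.window_start, p.window_end) == (1000, 2000)
    assert len(p) == 1000 and not p.truncated


def test_extract_promoter_minus_strand_is_reverse_complemented():
    rng = np.random.default_rng(1)
    contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
    gene = GeneModel("g", "c", "-", ((2700, 3000),))  # 1-based CDS end 3000
    p = extract_promoter(gene, {"c": contig})
    assert (p.window_start, p.window_end) == (3000, 4000)
    assert p.sequence == reverse_complement(contig[3000:4000])


def test_extract_promoter_truncated_at_contig_edge():
    contig = "A" * 1000
    gene = GeneModel("g", "c", "+", ((500, 800),))  # 1-based start 501
    p = extract_promoter(gene, {"c": contig})
    assert len(p) == 500 and p.truncated


def test_extract_promoter_strand_mirror_symmetry():
    """A + gene and its coordinate-mirrored - twin have identical
    promoter strings."""
    rng = np.random.default_rng(7)
    contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
    plus = GeneModel("p", "c", "+", ((2500, 2800),))
    mirrored = reverse_complement(contig)
    # position x in contig maps to len-x in the mirror
    minus = GeneModel("m", "c2", "-", ((4000 - 2800, 4000 - 2500),))
    p1 = extract_promoter(plus, {"c": contig})
    p2 = extract_promoter(minus, {"c2": mirrored})
    assert p1.sequence == p2.sequence


def test_extract_promoters_warns_and_drops_empty():
    gene = GeneModel("g", "c", "+", ((0, 300),))  # starts at contig edge
    with pytest.warns(UserWarning, match="empty promoter"):
        out = extract_promoters([gene], {"c": "A" * 400})
    assert out == []


def test_extract_promoter_missing_contig():
    gene = GeneModel("g", "nope", "+", ((100, 200),))
    with pytest.raises(KeyError):
        extract_promoter(gene, {"c": "ACGT"})


def test_scan_motif_r_expansion():
    assert [
        (h.offset, h.strand) for h in scan_motif(promoter("TTACCGACTT"), CRT_DRE)
    ] == [(2, "+")]
    assert [
        (h.offset, h.strand) for h in scan_motif(promoter("TTGCCGACTT"), CRT_DRE)
    ] == [(2, "+")]
    assert scan_motif(promoter("TTCCCGACTT"), CRT_DRE) == []


def test_scan_motif_reverse_strand_hit():
    # GTCGGT = revcomp(ACCGAC)
    hits = scan_motif(promoter("AAGTCGGTAA"), CRT_DRE)
    assert [(h.offset, h.strand) for h in hits] == [(2, "-")]


def test_scan_motif_n_in_sequence_matches_nothing():
    assert scan_motif(promoter("AANCCGACTT"), CRT_DRE) == []


def test_scan_motif_overlapping_hits_all_reported():
    # ACCGACCGAC: ACCGAC at 0, and at 4 (overlap)? positions 4..9 = ACCGAC
    hits = scan_motif(promoter("ACCGACCGAC"), MotifPattern("m", "ACCGAC", False))
    assert [h.offset for h in hits] == [0, 4]


@pytest.mark.parametrize("trial", range(5))
def test_scan_motif_equals_regex_oracle_on_random_input(trial):
    rng = np.random.default_rng(trial)
    seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, 3000)])
    codes = list(IUPAC)
    pat = "".join(rng.choice(codes, size=int(rng.integers(4, 9))))
    try:
        motif = MotifPattern(f"rand{trial}", pat)
    except ValueError:
        motif = MotifPattern(f"rand{trial}", "RCCGAC")
    got = sorted((h.offset, h.strand) for h in scan_motif(promoter(seq), motif))
    assert got == regex_oracle(seq, motif)


def test_strand_pair_symmetry(rng):
    """hits(p, m) and hits(revcomp(p), m) have equal counts for a
    both-strand motif."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    for motif in (CRT_DRE, MotifPattern("gbox", "CACGTG")):
        n_fwd = len(scan_motif(promoter(seq), motif))
        n_rev = len(scan_motif(promoter(reverse_complement(seq)), motif))
        assert n_fwd == n_rev


def test_scan_catalogue_counts_planted_copies():
    seq = list("ACGT" * 300)
    seq[100:106] = list("CACGTG")
    seq[700:706] = list("CACGTG")
    p = promoter("".join(seq))
    grid = scan_catalogue([p], list(DEFAULT_CATALOGUE))
    assert grid.loc["g", "G-box"] == 2


def test_scan_catalogue_empty_and_duplicates():
    p = promoter("ACGT" * 10)
    assert scan_catalogue([p], []).shape == (1, 0)
    with pytest.raises(ValueError, match="duplicate"):
        scan_catalogue([p], [CRT_DRE, CRT_DRE])


def test_scan_catalogue_row_sums_conserve_hits(rng):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1500)])
    p = promoter(seq)
    catalogue = list(DEFAULT_CATALOGUE)
    grid = scan_catalogue([p], catalogue)
    total = sum(len(scan_motif(p, m)) for m in catalogue)
    assert grid.loc["g"].sum() == total


def test_planted_motif_recovery(genome_fixture):
    proms = extract_promoters(genome_fixture.genes, genome_fixture.contigs)
    for p in proms:
        truth = genome_fixture.truth[p.gene_id]
        hits = scan_motif(p, CRT_DRE)
        plus_hits = [h for h in hits if h.strand == "+"]
        assert len(plus_hits) == truth["copies"]
        assert [h.offset for h in plus_hits] == truth["offsets"]


def test_hits_to_bed_promoter_relative_and_projected(genome_fixture):
    proms = extract_promoters(genome_fixture.genes[:5], genome_fixture.contigs)
    hits = [h for p in proms for h in scan_motif(p, CRT_DRE)]
    rel = hits_to_bed(hits)
    assert all(len(line.split("\t")) == 6 for line in rel.strip().split("\n"))
    proj = hits_to_bed(hits, promoters={p.gene_id: p for p in proms})
    # projected hits carry the planted motif string on the genome
    for line in proj.strip().split("\n"):
        contig, start, end, _name, _score, _strand = line.split("\t")
        sub = genome_fixture.contigs[contig][int(start):int(end)]
        assert sub in {s for s in _expansions("RCCGAC")} | {
            s for s in _expansions("GTCGGY")
        }


def _expansions(pat):
    import itertools

    pools = [sorted(IUPAC[c]) for c in pat]
    for combo in itertools.product(*pools):
        yield "".join(combo)
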