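"""Synthetic fixtures with planted ground truth.

Every downstream stage of the pipeline is exercisable without any
download: toy multi-contig genomes with CRT/DRE copies planted in
promoters at controlled rates, fragment-count tables with planted
>= 2-fold winter/summer effects over log-normal noise, protein families
carrying the two CBF signature sequences, and nucleotide sequences
evolved along a known tree. Generators are pure functions of a
:class:`FixtureSpec` (seed included): reruns are byte-identical, and
the returned truth structures suffice to predict every downstream
stage's expected output.

Default conditions mirror the motivating study where it states them:
1000-bp promoters, a 2-fold expression criterion over a winter vs.
summer mature-leaf contrast, a five-member signature-bearing family,
and planted effects of 3 log2 units over log-normal noise of sd 0.1
(chosen so planted genes clear the 2-fold rule with margin while decoys
stay strictly inside it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .expression import CountTable
from .family_id import SIGNATURE_S1, SIGNATURE_S2, SignaturePattern, match_signature
from .promoter_scan import CRT_DRE, IUPAC, MotifPattern
from .seqio import GeneModel, reverse_complement

__all__ = [
    "FixtureSpec",
    "GenomeFixture",
    "CountsFixture",
    "FamilyFixture",
    "make_genome",
    "make_counts",
    "make_family",
    "evolve",
    "random_tree",
    "additive_matrix",
]

BASES = np.array(list("ACGT"))
AA20 = "ACDEFGHIKLMNPQRSTVWY"

WINTER = "winter_mature_leaf"
SUMMER = "summer_mature_leaf"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study system.

    Genome: ``n_contigs`` contigs carrying ``n_genes`` stranded genes
    (``strand_mix`` = fraction on the minus strand) with ``promoter_len``
    bp promoters; ``plant_copies`` CRT/DRE copies are planted per gene
    promoter (an int, or one int per gene). Expression: ``n_up`` /
    ``n_down`` genes shifted by ``effect_log2fc`` log2 units in winter,
    ``n_decoy`` decoys shifted strictly inside (0.6, 1.7)-fold, the rest
    untouched; per-gene baselines are log-normal with sd ``noise_sd``
    (log2 scale) and counts are Poisson around the FPKM-implied means.
    Family: ``n_members`` signature-carrying proteins over
    ``n_background`` signature-free decoys with an S1->S2 separation in
    ``separation_window``.
    """

    seed: int = 0
    # genome
    n_contigs: int = 2
    n_genes: int = 200
    strand_mix: float = 0.5
    promoter_len: int = 1000
    gene_len: int = 300
    spacing: int = 60
    plant_copies: int | tuple[int, ...] = 1
    scrub_chance_hits: bool = True
    # counts
    n_up: int = 30
    n_down: int = 80
    n_decoy: int = 90
    effect_log2fc: float = 3.0
    noise_sd: float = 0.1
    baseline_log2_fpkm: float = 6.0
    library_size: int = 20_000_000
    # family
    n_members: int = 5
    n_background: int = 50
    protein_len: int = 300
    separation_window: tuple[int, int] = (40, 120)


@dataclass
class GenomeFixture:
    contigs: dict[str, str]
    genes: list[GeneModel]
    truth: dict  # gene_id -> {"copies": int, "offsets": [...], "strand": str}


@dataclass
class CountsFixture:
    table: CountTable
    truth: dict  # gene_id -> {"direction": "up"|"down"|"decoy"|"none", "planted_log2fc": float}


@dataclass
class FamilyFixture:
    records: list[tuple[str, str]]
    truth: dict  # protein_id -> {"member": bool, "s1_start": int, "s2_start": int}


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _scrub_motif(seq: list[str], motif: MotifPattern, rng: np.random.Generator,
                 protect: set[int]) -> None:
    """Destroy occurrences of ``motif`` (either orientation) in-place,
    leaving positions in ``protect`` (planted copies) untouched.

    A match whose positions are all protected is a planted copy and is
    kept; any other match has one unprotected position mutated to a
    base outside the pattern's residue class there. Re-scans until the
    window is clean (mutations can create new chance matches).
    """
    pats = {motif.iupac, reverse_complement(motif.iupac)}
    k = len(motif)
    for _ in range(100):  # convergence cap; typically 1-2 passes
        changed = False
        s = "".join(seq)
        for pat in pats:
            for pos in range(len(s) - k + 1):
                window = "".join(seq[pos : pos + k])
                if not all(c in IUPAC[p] for c, p in zip(window, pat)):
                    continue
                cands = [off for off in range(k) if (pos + off) not in protect]
                if not cands:
                    continue  # fully planted copy
                off = int(rng.choice(cands))
                outside = [b for b in "ACGT" if b not in IUPAC[pat[off]]]
                if not outside:  # N position; mutating cannot unmatch here
                    continue
                seq[pos + off] = str(rng.choice(outside))
                changed = True
        if not changed:
            return
    raise RuntimeError("motif scrubbing did not converge")


def make_genome(spec: FixtureSpec, motif: MotifPattern = CRT_DRE) -> GenomeFixture:
    """Toy genome with stranded genes and motif copies planted in
    promoters at recorded offsets.

    With ``scrub_chance_hits`` (default), chance occurrences of the
    motif inside promoter windows are mutated away before planting, so
    the truth counts are exact; without it they are lower bounds.
    Planted instantiations draw the degenerate positions uniformly
    (e.g. ACCGAC or GCCGAC for CRT/DRE).
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.plant_copies, int):
        copies = [spec.plant_copies] * spec.n_genes
    else:
        copies = list(spec.plant_copies)
        if len(copies) != spec.n_genes:
            raise ValueError("plant_copies length must equal n_genes")
    slot = spec.promoter_len + spec.gene_len + spec.spacing
    per_contig = int(np.ceil(spec.n_genes / spec.n_contigs))
    contig_len = per_contig * slot + spec.promoter_len + spec.spacing

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth: dict = {}
    gene_idx = 0
    k = len(motif)
    for ci in range(spec.n_contigs):
        cid = f"contig{ci + 1}"
        seq = list(_random_bases(rng, contig_len))
        for gi in range(per_contig):
            if gene_idx >= spec.n_genes:
                break
            gid = f"g{gene_idx + 1:04d}"
            strand = "-" if rng.random() < spec.strand_mix else "+"
            slot_start = spec.spacing + gi * slot
            if strand == "+":
                prom_start = slot_start
                cds_start = prom_start + spec.promoter_len
                cds_end = cds_start + spec.gene_len
                # promoter occupies [prom_start, cds_start), gene strand = +
                window = range(prom_start, cds_start)
            else:
                cds_start = slot_start
                cds_end = cds_start + spec.gene_len
                window = range(cds_end, cds_end + spec.promoter_len)
            # make the CDS look like a CDS (ATG ... stop) for realism
            if strand == "+":
                seq[cds_start : cds_start + 3] = list("ATG")
                seq[cds_end - 3 : cds_end] = list("TGA")
            else:
                seq[cds_end - 3 : cds_end] = list(reverse_complement("ATG"))
                seq[cds_start : cds_start + 3] = list(reverse_complement("TGA"))

            w0, w1 = window.start, window.stop
            n_copies = copies[gene_idx]
            # choose non-overlapping offsets within the promoter (promoter
            # coordinates, gene-strand orientation)
            offsets: list[int] = []
            attempts = 0
            while len(offsets) < n_copies:
                cand = int(rng.integers(0, spec.promoter_len - k + 1))
                if all(abs(cand - o) >= k for o in offsets):
                    offsets.append(cand)
                attempts += 1
                if attempts > 1000:
                    raise RuntimeError("infeasible motif packing")
            offsets.sort()
            protect: set[int] = set()
            for off in offsets:
                inst = "".join(
                    str(rng.choice(sorted(IUPAC[c]))) for c in motif.iupac
                )
                if strand == "+":
                    gpos = w0 + off
                    seq[gpos : gpos + k] = list(inst)
                else:
                    # promoter is revcomp of genomic (cds_end, cds_end+L];
                    # promoter offset `off` maps to genome position
                    # w1 - off - k, carrying the revcomp instantiation.
                    gpos = w1 - off - k
                    seq[gpos : gpos + k] = list(reverse_complement(inst))
                protect |= set(range(gpos, gpos + k))
            if spec.scrub_chance_hits:
                sub = seq[w0:w1]
                _scrub_motif(
                    sub, motif, rng,
                    protect={p - w0 for p in protect},
                )
                seq[w0:w1] = sub
            genes.append(
                GeneModel(
                    gene_id=gid,
                    contig_id=cid,
                    strand=strand,
                    cds_segments=((cds_start, cds_end),),
                )
            )
            truth[gid] = {"copies": n_copies, "offsets": offsets, "strand": strand}
            gene_idx += 1
        contigs[cid] = "".join(seq)
    return GenomeFixture(contigs=contigs, genes=genes, truth=truth)


def make_counts(spec: FixtureSpec, gene_ids: Sequence[str] | None = None) -> CountsFixture:
    """Fragment counts for a winter/summer contrast with planted effects.

    The first ``n_up`` genes are shifted up by ``effect_log2fc`` log2
    units in winter, the next ``n_down`` down, the next ``n_decoy`` by a
    uniform draw strictly inside (0.6, 1.7)-fold, and the rest left at
    baseline. Counts are Poisson around the FPKM-implied means at the
    configured library size.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    n = len(gene_ids)
    if spec.n_up + spec.n_down + spec.n_decoy > n:
        raise ValueError("n_up + n_down + n_decoy exceeds gene count")
    lengths = rng.integers(600, 3000, size=n).astype(float)
    base_log2 = rng.normal(spec.baseline_log2_fpkm, spec.noise_sd, size=n)
    effect = np.zeros(n)
    direction = np.array(["none"] * n, dtype=object)
    effect[: spec.n_up] = spec.effect_log2fc
    direction[: spec.n_up] = "up"
    sl = slice(spec.n_up, spec.n_up + spec.n_down)
    effect[sl] = -spec.effect_log2fc
    direction[sl] = "down"
    sl = slice(spec.n_up + spec.n_down, spec.n_up + spec.n_down + spec.n_decoy)
    # strictly inside (0.6, 1.7)-fold
    effect[sl] = rng.uniform(np.log2(0.62), np.log2(1.68), size=spec.n_decoy)
    direction[sl] = "decoy"

    # The log-normal noise perturbs the per-gene baseline shared by both
    # conditions; planted fold changes therefore equal 2^effect exactly
    # up to Poisson counting noise.
    summer_fpkm = np.power(2.0, base_log2)
    winter_fpkm = np.power(2.0, base_log2 + effect)
    N = float(spec.library_size)
    counts = pd.DataFrame(
        {
            SUMMER: rng.poisson(summer_fpkm * lengths * N / 1e9),
            WINTER: rng.poisson(winter_fpkm * lengths * N / 1e9),
        },
        index=list(gene_ids),
    )
    table = CountTable(
        counts=counts,
        lengths=pd.Series(lengths, index=list(gene_ids)),
        totals=pd.Series({SUMMER: N, WINTER: N}),
    )
    truth = {
        g: {"direction": str(direction[i]), "planted_log2fc": float(effect[i])}
        for i, g in enumerate(gene_ids)
    }
    return CountsFixture(table=table, truth=truth)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _instantiate(pattern: SignaturePattern, rng: np.random.Generator) -> str:
    out = []
    for el in pattern.elements:
        if el is None:
            out.append(str(rng.choice(list(AA20))))
        else:
            out.append(str(rng.choice(sorted(el))))
    return "".join(out)


def make_family(spec: FixtureSpec) -> FamilyFixture:
    """A protein family with planted signatures over signature-free
    background.

    Members share a common scaffold (so they are mutually homologous)
    carrying S1, an AP2-like spacer, and S2 with separation inside
    ``separation_window``; each member then receives a few substitutions
    outside the signatures. Background proteins are uniform-random and
    rejection-sampled until they contain no S1 hit (at S1's mismatch
    budget) and no S2 hit.
    """
    rng = np.random.default_rng(spec.seed + 2)
    lo, hi = spec.separation_window
    sep = int(rng.integers(lo, hi + 1))
    s1_start = int(rng.integers(10, 40))
    s1 = _instantiate(SIGNATURE_S1, rng)
    s2 = _instantiate(SIGNATURE_S2, rng)
    s2_start = s1_start + len(s1) + sep
    total = max(spec.protein_len, s2_start + len(s2) + 30)
    scaffold = list(_random_protein(rng, total))
    scaffold[s1_start : s1_start + len(s1)] = list(s1)
    scaffold[s2_start : s2_start + len(s2)] = list(s2)
    protected = set(range(s1_start, s1_start + len(s1))) | set(
        range(s2_start, s2_start + len(s2))
    )

    records: list[tuple[str, str]] = []
    truth: dict = {}
    for m in range(spec.n_members):
        prot = scaffold.copy()
        n_subs = int(rng.integers(3, 10))
        for _ in range(n_subs):
            pos = int(rng.integers(0, total))
            if pos in protected:
                continue
            prot[pos] = str(rng.choice(list(AA20)))
        pid = f"member{m + 1}"
        records.append((pid, "".join(prot)))
        truth[pid] = {"member": True, "s1_start": s1_start, "s2_start": s2_start}

    for b in range(spec.n_background):
        while True:
            cand = _random_protein(rng, spec.protein_len)
            if match_signature(cand, SIGNATURE_S1):
                continue
            if match_signature(cand, SIGNATURE_S2):
                continue
            break
        pid = f"bg{b + 1:03d}"
        records.append((pid, cand))
        truth[pid] = {"member": False, "s1_start": -1, "s2_start": -1}
    return FamilyFixture(records=records, truth=truth)


def evolve(
    tree_newick: str,
    rate: float,
    seed: int,
    root_seq: str | None = None,
    n_sites: int = 1000,
) -> dict[str, str]:
    """Evolve a nucleotide sequence along a tree.

    Independent-site uniform-replacement process: on a branch of length
    b, each site is replaced with a uniformly drawn base (possibly the
    same one) with probability 1 - exp(-rate*b); the expected observed
    difference fraction on the branch is therefore
    (3/4) * (1 - exp(-rate*b)), saturating at 3/4. Returns leaf name ->
    sequence; deterministic under ``seed``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    rng = np.random.default_rng(seed)
    if root_seq is None:
        root_arr = rng.integers(0, 4, size=n_sites)
    else:
        idx = {b: i for i, b in enumerate("ACGT")}
        root_arr = np.array([idx[c] for c in root_seq.upper()])
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            arr = root_arr
        else:
            parent_arr = seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            p_sub = 1.0 - np.exp(-rate * b)
            mask = rng.random(parent_arr.size) < p_sub
            arr = parent_arr.copy()
            arr[mask] = rng.integers(0, 4, size=int(mask.sum()))
            seqs[id(node)] = arr
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(BASES[arr])
    return leaves


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    bl_range: tuple[float, float] = (0.05, 0.3),
) -> str:
    """A random binary topology with uniform branch lengths, as Newick.

    Taxa are labelled t1..tn; built by sequential random joins.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    lo, hi = bl_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    nodes = [f"t{i + 1}:{bl():.6f}" for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"


def additive_matrix(tree_newick: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (the additive oracle)."""
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = tuple(sorted(t.label for t in tree.taxon_namespace))
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return taxa, d


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
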