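# Methods

This note documents the models and procedures implemented in
`cbfsurvey`, the parameters that matter, the numerical choices, and
what the synthetic study system does and does not emulate.

## Family identification

CBF/DREB1 proteins carry a ~60-residue AP2 DNA-binding domain flanked
by two short signatures: `PKK/RPAGRxKFxETRHP` (S1; position 3 admits K
or R, `x` is a wildcard) and `DSAWR` (S2). A candidate is accepted when

1. its best Smith–Waterman score against a seed CBF reaches a fraction
   (`min_score_frac`, default 0.4) of that seed's self-score, and
2. an S1 hit precedes an S2 hit with an S1-end→S2-start separation
   inside `[40, 120]` residues (the AP2 domain sits between them).

Alignment uses BLOSUM62 with affine gaps; a gap of length k costs
`open + (k-1)·extend` with open = 11, extend = 1 (the
`Bio.Align.PairwiseAligner` convention). Signature matching tolerates
`max_mismatches` per pattern (defaults: S1 = 2, S2 = 0; wildcards never
count). The 0.4 self-score fraction is a deliberately permissive
retrieval threshold — the signature layout is the discriminating step —
and is exposed in the config. A six-frame translation helper
(`six_frame_peptides`) supports screening nucleotide input; stop-free
peptides are returned longest-first.

## Physicochemical property block

All conventions follow ExPASy ProtParam, which the indices were defined
against:

- **Molecular weight**: sum of average (not monoisotopic) residue
  masses plus one water (18.0153 Da), reported in kDa.
- **pI**: unique root of the Bjellqvist charge model — basic groups
  (N-terminus, K, R, H) contribute `1/(1+10^(pH−pKa))`, acidic groups
  (C-terminus, D, E, C, Y) `−1/(1+10^(pKa−pH))`, with residue-specific
  terminal pKa values — solved by bisection on [0, 14] to
  |charge| < 1e−4. The charge is strictly decreasing in pH, so the
  root is unique.
- **GRAVY**: mean Kyte–Doolittle hydropathy; negative ⇒ hydrophilic.
- **Instability index**: `(10/L)·Σ DIWV(x_i, x_{i+1})` over adjacent
  residue pairs (Guruprasad dipeptide weights); < 40 predicts an
  in-vitro-stable protein. The DIWV matrix is asymmetric, so this index
  (unlike the others) depends on residue order.
- **Aliphatic index**: `X_A + 2.9·X_V + 3.9·(X_I + X_L)` in mole
  percent.

The Kyte–Doolittle and DIWV tables are taken from
`Bio.SeqUtils.ProtParamData`; the pKa constants are in-module.
Computation is at full precision; the presentation table rounds
half-up to 2 decimals. Ambiguous residues (B, Z, X) are rejected with
the offending position named. The test suite cross-checks every index
against Biopython's independent ProtParam implementation.

## Phylogeny

Distances are p-distances: mismatched aligned positions divided by
aligned positions, gap columns excluded. Unaligned protein input is
globally aligned per pair (Needleman–Wunsch, BLOSUM62, affine gaps as
above); pre-aligned input (`aligned=True`, e.g. simulated sequences of
equal length) is compared positionally, which is exact for that case
and keeps large simulation studies fast. A Poisson correction
(−ln(1−p)) is available behind the `model="poisson"` flag. Because
distances come from pairwise alignments rather than a single MSA, they
can differ from MSA-based pipelines (e.g. MEGA); this is a documented
design choice, not an equivalence claim.

Neighbor joining is Saitou–Nei with the Studier–Keppler criterion
Q(i,j) = (n−2)·d(i,j) − r_i − r_j. Ties in Q are broken by the lowest
(i, j) index pair, so topologies are deterministic. Branch lengths use
the standard formulas; negative estimates are clamped to 0 with the
deficit moved to the sibling branch (logged at debug level). On
additive matrices the output tree's path-length matrix reproduces the
input to numerical precision.

Bootstrap support resamples alignment columns with replacement: each
replicate draws one master vector of uniforms, fanned out to each
pair's column count via `floor(u·L_pair)` — for pre-aligned input this
is exact joint column resampling. Support is the percentage of
replicates whose NJ tree contains each internal bipartition of the
original tree, serialized as integer internal-node labels in Newick.
The replicate count defaults to 1000 and the seed is mandatory in the
config (default 20191017), so supports are bit-reproducible.

## Promoters and motif scanning

The promoter is the `promoter_len` (default 1000) bp immediately
upstream of the start codon, measured from the CDS start — transcript
starts are typically unavailable for draft genomes — and reported on
the gene's strand: plus-strand genes read genomic `[start−L, start)`
as-is, minus-strand genes read `(end, end+L]` reverse-complemented.
Windows clipped at contig edges are flagged truncated; zero-length
windows are warned about and excluded from scans.

Patterns are IUPAC-degenerate consensus strings (CRT/DRE is `RCCGAC`),
not PWMs. Matching is exact set membership per position; an N in the
sequence matches nothing; overlapping matches are all reported (the
survey criterion only needs ≥ 1, so multiplicity is informational).
Both strands are scanned by default — a reverse-strand hit is an
occurrence of the pattern's reverse complement, reported at its offset
on the promoter string; palindromic patterns report each site once.
The built-in catalogue ships canonical consensus strings for common
plant elements (G-box, ABRE, CGTCA/TGACG, MBS, LTR, ERE, TGA-element,
TATC-box, GARE-motif, Box4, Sp1, GATA-motif, TCT-motif); it is a
convenience default, not a replication of any external database
version, and users can override it with a TSV.

## Expression

FPKM = c·10⁹/(N·L) with N the per-library total mapped fragments
(an explicit input, never recomputed from the table) and L the exonic
length in bp. Fold changes guard zero expression with a floor (default
0.1 FPKM) applied to the ratio only, so printed FPKM values are never
modified; direction is "up" at fc ≥ threshold (boundary inclusive,
"at least 2-fold"), "down" at fc ≤ 1/threshold. Single-library
contrasts (such as one winter and one summer tissue library) carry no
p-value — the criterion is threshold-only by design.

qPCR: per replicate ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
calibrator's mean ΔCt; RQ = 2^−ΔΔCt. The summary RQ is 2^(−mean ΔΔCt)
— the geometric-style summary — so the calibrator's RQ is identically
1 whatever its replicate spread; the SEM of per-replicate RQs is
reported alongside. Significance is a two-sided Welch t-test on
replicate ΔCt (not on RQ, whose distribution is skewed), requiring at
least two replicates per side; mismatched replicate counts are fine.
Ct values outside (0, 45) are rejected.

## Target survey

A gene is a putative CBF target iff (1) |log2 fc| ≥ 1 between the
contrast conditions and (2) its promoter has ≥ 1 CRT/DRE hit (either
strand by default; a plus-only mode exists). Classification matches
annotation substrings case-insensitively against an ordered keyword map
(11 default categories: carbohydrate metabolism, lipid metabolism,
cell wall modification, circadian rhythm, calcium signaling,
transcription factor, hormone signaling, kinase, chloroplast,
transporter, other); multiple categories are retained in map order and
unmatched annotations fall through to "other".

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) for k
of n annotated survey genes in a term covering K of M annotated
background genes, where the annotated universe is the background genes
present in any term. The background defaults to all genes with a
promoter and an expression value. Raw p is compared to 0.05 (the
conventional call) with Benjamini–Hochberg adjusted values reported
alongside; results are sorted by p with ties broken by term name.

## Synthetic study system

The generators are pure functions of a `FixtureSpec` (seed included):
reruns are byte-identical and each fixture ships a truth structure
sufficient to predict every downstream stage's expected output.

- **Genomes**: uniform-random base composition (0.25 each), genes laid
  out in fixed slots on both strands (strand mix 0.5), one CDS per gene
  with ATG/stop termini. CRT/DRE copies are planted at recorded
  promoter offsets with degenerate positions instantiated uniformly.
  By default, chance occurrences of the motif inside promoter windows
  (either orientation) are mutated away before the truth is recorded,
  so planted counts are exact; with `scrub_chance_hits=False` the
  chance rate is ≈ 2·(1/4)⁶ per strand per bp and truth counts are
  lower bounds.
- **Counts**: per-gene baseline log2-FPKM ~ Normal(6, noise_sd = 0.1),
  shared by both conditions; planted genes are shifted ±3 log2 units in
  winter, decoys by a uniform draw strictly inside (0.62, 1.68)-fold.
  Counts are Poisson around the FPKM-implied means at a 2·10⁷-fragment
  library. Because the log-normal noise perturbs the shared baseline,
  planted fold changes equal 2^effect exactly up to Poisson counting
  noise — which at these depths keeps decoys ≥ 3σ from the 2-fold
  boundary, so exact planted-truth recovery is a stable contract.
- **Families**: members share a random scaffold carrying instantiated
  S1/S2 signatures at a separation drawn from the configured window,
  then receive a few substitutions outside the signatures; background
  proteins are uniform-random and rejection-sampled to be signature-free
  at the screening mismatch budgets.
- **Evolution**: independent-site uniform replacement — on a branch of
  length b each site is redrawn uniformly over {A,C,G,T} with
  probability 1 − e^(−rate·b), so the observed per-branch difference
  fraction is (3/4)(1 − e^(−rate·b)), saturating at 3/4.

What the system does **not** emulate: realistic base composition or
isochore structure, multi-exon genes in the generated GFF3 (the readers
and promoter logic support them; the generator plants single-CDS
genes), biological replicate structure for the seasonal contrast,
sequencing-level artifacts (reads are never simulated, counts are), or
real annotation databases. Passing tests therefore demonstrate
algorithmic correctness against planted ground truth and independent
oracles, not performance on any particular real genome.

## Pipeline and problem sizes

`run_all` chains identify → props → tree → promoters → scan → fpkm →
survey, writes every intermediate as TSV/FASTA/Newick/JSON plus the
merged effective config, logs one structured entry per stage with
input/output record counts, and aborts with a stage-named error on any
failure. All randomness flows from one master seed fanned out by a
CRC32 hash of the stage name. Floating-point output uses fixed formats,
so identical configs give byte-identical files.

Default study sizes — 200 genes (30 up / 80 down / 90 decoys at 200;
the split scales proportionally), 1000-bp promoters, five family
members over 50 background proteins, six-taxon trees with 1000 sites,
1000 bootstrap replicates — keep the full suite and the acceptance
script in the seconds-to-minutes range while leaving planted effects
comfortably identifiable.

## Known limitations

- Homology screening is exact Smith–Waterman, not a seeded heuristic:
  appropriate at proteome scale for a small family screen, quadratic in
  sequence length.
- The pairwise-distance phylogeny is not an MSA pipeline; bootstrap
  column resampling is joint only to the extent the master-coordinate
  fan-out allows for unequal pair alignment lengths (it is exact for
  pre-aligned input).
- The cis-element catalogue is a canonical-consensus convenience set;
  counts against it are not comparable to any specific PlantCARE
  release.
- Enrichment assumes the user-supplied term map is complete over the
  annotated universe; genes absent from every term are treated as
  unannotated and drop out of M and n.
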