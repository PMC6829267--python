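# cbfsurvey

Tools for the classic cold-response workflow in plant regulatory
genomics: characterize a CBF/DREB1 transcription-factor family and
survey its putative low-temperature target genes.

CBFs (C-repeat binding factors) are AP2/ERF transcription factors that
are rapidly induced by cold and bind the C-repeat/dehydration-responsive
element **CRT/DRE (G/ACCGAC, IUPAC `RCCGAC`)** in the promoters of
downstream cold-responsive (*COR*) genes. Given a genome, gene models,
a proteome and expression data, this package covers the whole chain:

1. **Family identification** (`family_id`) — Smith–Waterman homology
   screen against seed CBFs (BLOSUM62, affine gaps) plus verification of
   the two signature sequences flanking the AP2 DNA-binding domain,
   `PKK/RPAGRxKFxETRHP` and `DSAWR`, in order and at a plausible
   separation.
2. **Physicochemical profiling** (`protein_props`) — length, molecular
   weight (average masses, kDa), isoelectric point (Bjellqvist pKa set),
   GRAVY (mean Kyte–Doolittle hydropathy), Guruprasad instability index
   (< 40 ⇒ stable) and Ikai aliphatic index
   X<sub>Ala</sub> + 2.9·X<sub>Val</sub> + 3.9·(X<sub>Ile</sub> + X<sub>Leu</sub>).
3. **Phylogeny** (`phylo`) — pairwise p-distances (Needleman–Wunsch for
   unaligned proteins, positional for alignments), Saitou–Nei neighbor
   joining with the Studier–Keppler Q criterion, seeded column-resampling
   bootstrap, Newick output.
4. **Promoters and cis-elements** (`promoter_scan`) — 1000-bp windows
   upstream of the start codon on the gene's strand, scanned for CRT/DRE
   (both strands) and a catalogue of named IUPAC consensus elements
   (G-box, ABRE, MBS, LTR, …), producing a gene × element count grid.
5. **Expression** (`expression`) — FPKM = c·10⁹/(N·L) from fragment
   counts, fold changes with a 0.1-FPKM ratio floor, and qPCR relative
   expression by 2^−ΔΔCt with Welch-t significance on replicate ΔCt.
6. **Target survey** (`target_survey`) — the two-criterion rule: a gene
   is a putative CBF target when it changes **at least 2-fold** between
   the contrast conditions (e.g. winter vs. summer mature leaves) *and*
   its promoter carries **at least one CRT/DRE** motif. Survivors are
   classified into 11 functional categories by annotation keywords and
   tested for term enrichment with the hypergeometric tail
   (Benjamini–Hochberg adjusted).
7. **Synthetic fixtures** (`synthetic_data`) — seeded generators for
   genomes with planted motifs, count tables with planted ≥ 2-fold
   effects, signature-carrying protein families and sequences evolved
   along known trees, each with a machine-readable truth file.

## Worked example

Run the full pipeline on a synthetic study system (200 genes, 30 planted
up- and 80 down-regulated at 3 log2 units, 90 near-boundary decoys, one
CRT/DRE copy planted per promoter, a five-member signature family):

```bash
cbfsurvey run-all --simulate --seed 20191017 --out demo
```

prints the survey summary:

```json
{
 "total": 110,
 "up": 30,
 "down": 80,
 "statement": "A total of 110 potential target genes were identified, including 30 upregulated genes and 80 downregulated genes."
}
```

Exactly the 110 planted genes survive both criteria — the 90 decoys are
excluded by the 2-fold rule. `demo/` then contains `survey.tsv` (per-gene
fold change, direction, CRT/DRE count, categories), `props.tsv`:

```text
Gene     Length  MW_kDa  pI    Instability  Aliphatic  GRAVY  Stable
member1  300     36.04   9.24  62.51        50.40      -0.81  False
member2  300     35.96   9.33  61.22        52.67      -0.70  False
...
```

`tree.nwk` with 1000-replicate bootstrap supports as internal labels:

```text
(member5:0.0167,(member1:0.0217,member2:0.025)100:0.0017,(member3:0.0133,member4:0.02)100:0);
```

plus the promoter FASTA, CRT/DRE hits as BED6, the gene × cis-element
count grid, the FPKM matrix, `truth.json` (the planted ground truth) and
`effective_config.yaml` (the merged config actually used). Reruns with
the same config are byte-identical.

Library use mirrors the CLI:

```python
from cbfsurvey import synthetic_data as sd
from cbfsurvey import expression, promoter_scan, target_survey

spec = sd.FixtureSpec(seed=7)
genome = sd.make_genome(spec)
counts = sd.make_counts(spec, [g.gene_id for g in genome.genes])
fpkm = expression.expression_matrix(counts.table)
hits = promoter_scan.count_hits(
    promoter_scan.extract_promoters(genome.genes, genome.contigs))
records, summary = target_survey.survey(fpkm, hits, sd.WINTER, sd.SUMMER)
print(summary["statement"])
```

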