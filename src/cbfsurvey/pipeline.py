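"""The end-to-end survey pipeline: identify -> props -> tree ->
promoters -> scan -> fpkm -> survey, chained on a config-declared input
set (or on synthetic fixtures in simulate mode), with one structured
log entry per stage and deterministic outputs for a fixed config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import (
    expression,
    family_id,
    phylo,
    promoter_scan,
    protein_props,
    synthetic_data,
    target_survey,
)
from .config import ConfigError, PipelineConfig, stage_seed
from .promoter_scan import DEFAULT_CATALOGUE, MotifPattern
from .seqio import read_fasta, read_gff3, write_fasta, write_gff3

logger = logging.getLogger("cbfsurvey.pipeline")

__all__ = ["run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc
            return result

        return wrapper

    return deco


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the report.

    Outputs (TSV/FASTA/Newick/JSON plus the effective config) land in
    ``config.outdir``. All randomness flows from ``config.seed``,
    fanned out per stage, so reruns are byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "effective_config.yaml")
    report: dict = {"stages": {}}

    def log_stage(name: str, n_in: int, n_out: int) -> None:
        logger.info("stage=%s inputs=%d outputs=%d", name, n_in, n_out)
        report["stages"][name] = {"inputs": n_in, "outputs": n_out}

    motif = MotifPattern("CRT/DRE", config.motif, both_strands=config.both_strands)

    # ------------------------------------------------------------------
    # inputs: read from declared paths, or simulate with planted truth
    # ------------------------------------------------------------------
    if config.simulate:
        n = config.n_genes
        # planted DE structure scales with the gene count (15% up, 40%
        # down, 45% decoy — the default 30/80/90 split at 200 genes)
        spec = synthetic_data.FixtureSpec(
            seed=stage_seed(config.seed, "simulate"),
            n_genes=n,
            promoter_len=config.promoter_len,
            n_up=round(0.15 * n),
            n_down=round(0.40 * n),
            n_decoy=n - round(0.15 * n) - round(0.40 * n),
        )
        genome_fx = synthetic_data.make_genome(spec, motif=motif)
        counts_fx = synthetic_data.make_counts(spec, [g.gene_id for g in genome_fx.genes])
        family_fx = synthetic_data.make_family(spec)
        contigs = genome_fx.contigs
        genes = genome_fx.genes
        count_table = counts_fx.table
        proteins = family_fx.records
        seeds = [r for r in family_fx.records if family_fx.truth[r[0]]["member"]][:2]
        annotations: dict[str, str] = {}
        write_fasta(out / "genome.fa", sorted(contigs.items()))
        write_gff3(out / "genes.gff3", genes)
        synthetic_data.write_truth_json(
            {
                "genome": genome_fx.truth,
                "counts": counts_fx.truth,
                "family": family_fx.truth,
            },
            out / "truth.json",
        )
        log_stage("simulate", 0, len(genes))
    else:
        if not (config.genome and config.gff and config.counts and config.totals):
            raise ConfigError(
                "non-simulate runs need genome, gff, counts and totals paths"
            )
        contigs = dict(read_fasta(config.genome, alphabet="nucleotide"))
        genes = read_gff3(config.gff)
        count_table = expression.read_counts_tsv(config.counts, config.totals)
        proteins = (
            read_fasta(config.proteins, alphabet="protein")
            if config.proteins
            else []
        )
        if config.seeds:
            seeds = read_fasta(config.seeds, alphabet="protein")
        else:
            seeds = proteins[:2]
        annotations = {}
        if config.annotations:
            df = pd.read_csv(config.annotations, sep="\t", header=None,
                             names=["gene_id", "annotation"])
            annotations = dict(zip(df["gene_id"], df["annotation"].fillna("")))
        log_stage("load", len(contigs) + len(genes), len(genes))

    # ------------------------------------------------------------------
    # identify: homology + signature screen of the proteome
    # ------------------------------------------------------------------
    hits = []
    if proteins and seeds:
        hits = _stage("identify")(family_id.identify_family)(
            seeds,
            proteins,
            min_score_frac=config.min_score_frac,
            separation=(config.sep_lo, config.sep_hi),
        )
        family_id.write_hits_tsv(hits, out / "identify.tsv")
        log_stage("identify", len(proteins), sum(h.accepted for h in hits))
    accepted_ids = {h.protein_id for h in hits if h.accepted}
    members = [(pid, seq) for pid, seq in proteins if pid in accepted_ids]

    # props: physicochemical table of the accepted family
    if members:
        props = _stage("props")(protein_props.property_table)(members)
        props.to_csv(out / "props.tsv", sep="\t", index=False, float_format="%.2f")
        log_stage("props", len(members), len(props))

    # tree: NJ with bootstrap over the accepted family
    if len(members) >= 3:
        tree = _stage("tree")(phylo.build_tree)(
            members,
            bootstrap_reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, "bootstrap"),
        )
        (out / "tree.nwk").write_text(phylo.write_newick(tree) + "\n")
        log_stage("tree", len(members), 1)

    # promoters + scan
    promoters = _stage("promoters")(promoter_scan.extract_promoters)(
        genes, contigs, length=config.promoter_len
    )
    write_fasta(out / "promoters.fa", [(p.gene_id, p.sequence) for p in promoters])
    log_stage("promoters", len(genes), len(promoters))

    hit_counts = _stage("scan")(promoter_scan.count_hits)(promoters, motif)
    all_hits = [h for p in promoters for h in promoter_scan.scan_motif(p, motif)]
    (out / "crtdre_hits.bed").write_text(promoter_scan.hits_to_bed(all_hits))
    grid = promoter_scan.scan_catalogue(promoters, DEFAULT_CATALOGUE)
    grid.to_csv(out / "cis_element_grid.tsv", sep="\t")
    log_stage("scan", len(promoters), len(all_hits))

    # fpkm
    fpkm_table = _stage("fpkm")(expression.expression_matrix)(count_table)
    fpkm_table.to_csv(out / "fpkm.tsv", sep="\t", float_format="%.6g")
    log_stage("fpkm", int(count_table.counts.size), int(fpkm_table.size))

    # survey + classify + enrich + report
    records, summary = _stage("survey")(target_survey.survey)(
        fpkm_table,
        hit_counts,
        cond_a=config.cond_a,
        cond_b=config.cond_b,
        fold_threshold=config.fold_threshold,
        floor=config.fpkm_floor,
    )
    target_survey.classify(records, annotations)
    enrichments = []
    if config.terms:
        terms_df = pd.read_csv(config.terms, sep="\t", header=None,
                               names=["term", "gene_id"])
        term_map: dict[str, set] = {}
        for term, gid in zip(terms_df["term"], terms_df["gene_id"]):
            term_map.setdefault(term, set()).add(gid)
        enrichments = _stage("enrich")(target_survey.enrich)(
            [r.gene_id for r in records],
            list(fpkm_table.index),
            term_map,
        )
        target_survey.write_enrichment_tsv(enrichments, out / "enrichment.tsv")
    target_survey.write_survey_tsv(records, out / "survey.tsv")
    log_stage("survey", len(fpkm_table.index), len(records))

    report["survey"] = summary
    report["report"] = target_survey.report(records, enrichments)
    with open(out / "report.json", "w", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
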