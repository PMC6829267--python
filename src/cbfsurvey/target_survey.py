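"""The two-criterion CBF target-gene survey.

A gene is a putative CBF target when (1) it is up- or downregulated at
least 2-fold between the contrast conditions (winter vs. summer mature
leaves in the motivating study) and (2) its promoter carries at least
one CRT/DRE motif (either strand by default). Surviving genes are
classified into functional categories by keyword matching of their
annotations and tested for term enrichment with the hypergeometric
tail, Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import fold_change

__all__ = [
    "SurveyRecord",
    "EnrichmentResult",
    "DEFAULT_CATEGORIES",
    "survey",
    "classify",
    "enrich",
    "report",
    "write_survey_tsv",
    "write_enrichment_tsv",
]


@dataclass
class SurveyRecord:
    """One surviving gene: fold change, direction, motif count,
    categories and annotation."""

    gene_id: str
    fc: float
    log2fc: float
    direction: str  # "up" | "down"
    n_crtdre: int
    categories: tuple[str, ...] = ()
    annotation: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one functional term.

    k of n annotated survey genes carry the term; K of M annotated
    background genes do. p is the upper tail P(X >= k); p_adj is
    Benjamini-Hochberg.
    """

    term: str
    k: int
    n: int
    K: int
    M: int
    p: float
    p_adj: float


# The 11 functional categories used to classify CBF target genes, with
# annotation keywords (case-insensitive substrings). "other" is the
# fallback for unmatched annotations.
DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "carbohydrate metabolism": (
        "galactinol", "raffinose", "glucosidase", "galactosidase", "sucrose",
        "starch", "trehalose", "invertase", "amylase", "sugar",
    ),
    "lipid metabolism": (
        "lipase", "lipid", "wax", "phospholipase", "fatty acid",
        "aldehyde decarboxylase", "desaturase",
    ),
    "cell wall modification": (
        "chitinase", "pectate", "pectin", "cellulose", "polygalacturonase",
        "xyloglucan", "expansin", "cell wall",
    ),
    "circadian rhythm": ("circadian", "clock", "CONSTANS", "flowering time"),
    "calcium signaling": (
        "calcium", "calmodulin", "Ca2+", "annexin", "calcineurin",
    ),
    "transcription factor": (
        "transcription factor", "bHLH", "WRKY", "MYB", "zinc finger", "ERF",
        "GRAS", "Dof", "LOB", "GNAT", "C2H2", "bZIP", "NAC",
    ),
    "hormone signaling": (
        "auxin", "gibberellin", "abscisic", "ethylene", "jasmon", "DELLA",
        "JAZ", "MYC2", "GH3", "IAA", "hormone",
    ),
    "kinase": ("kinase",),
    "chloroplast": ("chloroplast", "photosystem", "chlorophyll", "thylakoid"),
    "transporter": ("transporter", "channel", "ATPase", "carrier", "permease"),
    "other": (),
}


def survey(
    fpkm_table: pd.DataFrame,
    hit_counts: Mapping[str, int],
    cond_a: str,
    cond_b: str,
    fold_threshold: float = 2.0,
    floor: float = 0.1,
) -> tuple[list[SurveyRecord], dict]:
    """Apply both target criteria and return survivors plus a summary.

    ``fpkm_table``: genes x conditions FPKM; ``hit_counts``: CRT/DRE
    occurrences per gene (genes absent from the map count 0).
    Criterion 1: fold change of ``cond_a`` over ``cond_b`` at least
    ``fold_threshold`` in either direction. Criterion 2: at least one
    motif hit. The summary reports total / up / down counts.
    """
    for cond in (cond_a, cond_b):
        if cond not in fpkm_table.columns:
            raise KeyError(f"condition {cond!r} not in expression table")
    records: list[SurveyRecord] = []
    for gene in fpkm_table.index:
        n_hits = int(hit_counts.get(gene, 0))
        if n_hits < 1:
            continue
        f = fold_change(
            float(fpkm_table.at[gene, cond_a]),
            float(fpkm_table.at[gene, cond_b]),
            floor=floor,
            threshold=fold_threshold,
        )
        if f.direction == "unchanged":
            continue
        records.append(
            SurveyRecord(
                gene_id=gene,
                fc=f.fc,
                log2fc=f.log2fc,
                direction=f.direction,
                n_crtdre=n_hits,
            )
        )
    n_up = sum(1 for r in records if r.direction == "up")
    n_down = sum(1 for r in records if r.direction == "down")
    summary = {
        "total": len(records),
        "up": n_up,
        "down": n_down,
        "statement": (
            f"A total of {len(records)} potential target genes were "
            f"identified, including {n_up} upregulated genes and "
            f"{n_down} downregulated genes."
        ),
    }
    return records, summary


def classify(
    records: Sequence[SurveyRecord],
    annotations: Mapping[str, str],
    keyword_map: Mapping[str, Sequence[str]] = DEFAULT_CATEGORIES,
) -> list[SurveyRecord]:
    """Assign functional categories by case-insensitive keyword matching.

    A record may receive several categories (in the keyword map's
    order); records matching nothing get ("other",). Returns the same
    records, mutated in place, for chaining.
    """
    if not keyword_map:
        raise ValueError("empty keyword map")
    for rec in records:
        ann = annotations.get(rec.gene_id, "")
        rec.annotation = ann
        low = ann.lower()
        cats = [
            cat
            for cat, keywords in keyword_map.items()
            if any(kw.lower() in low for kw in keywords)
        ]
        rec.categories = tuple(cats) if cats else ("other",)
    return list(records)


def enrich(
    survey_genes: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of the survey set vs. background.

    The annotated universe is the background genes present in any term;
    n is the survey genes within that universe. For each term,
    p = P(X >= k) with X ~ Hypergeom(M, K, n), BH-adjusted across
    terms; results are sorted by p (ties by term name).
    """
    surv = set(survey_genes)
    bg = set(background)
    if not surv <= bg:
        missing = sorted(surv - bg)[:3]
        raise ValueError(f"survey genes absent from background: {missing}")
    annotated = set()
    for genes in term_map.values():
        annotated |= set(genes)
    annotated &= bg
    M = len(annotated)
    n = len(surv & annotated)
    results = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & annotated
        K = len(term_genes)
        k = len(term_genes & surv)
        if M == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        results.append((term, k, K, p))
    if not results:
        return []
    pvals = [r[3] for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichmentResult(term=t, k=k, n=n, K=K, M=M, p=p, p_adj=float(pa))
        for (t, k, K, p), pa in zip(results, p_adj)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def report(
    records: Sequence[SurveyRecord],
    enrichments: Sequence[EnrichmentResult] = (),
    hormone_category: str = "hormone signaling",
    top_terms: int = 20,
) -> dict:
    """Machine-readable survey report.

    Totals and up/down splits overall and per category, a hormone-
    pathway subtable, and the top enrichment rows.
    """
    n_up = sum(1 for r in records if r.direction == "up")
    n_down = sum(1 for r in records if r.direction == "down")
    per_category: dict[str, dict[str, int]] = {}
    for r in records:
        for cat in r.categories or ("other",):
            c = per_category.setdefault(cat, {"total": 0, "up": 0, "down": 0})
            c["total"] += 1
            c[r.direction] += 1
    hormone = [
        {
            "gene_id": r.gene_id,
            "fc": round(r.fc, 4),
            "log2fc": round(r.log2fc, 4),
            "direction": r.direction,
            "annotation": r.annotation,
        }
        for r in records
        if hormone_category in (r.categories or ())
    ]
    return {
        "totals": {"total": len(records), "up": n_up, "down": n_down},
        "categories": per_category,
        "hormone_pathway": hormone,
        "enrichment": [
            {
                "term": e.term, "k": e.k, "n": e.n, "K": e.K, "M": e.M,
                "p": e.p, "p_adj": e.p_adj, "significant": e.p < 0.05,
            }
            for e in enrichments[:top_terms]
        ],
    }


def write_survey_tsv(records: Sequence[SurveyRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tfc\tlog2fc\tdirection\tn_crtdre\tcategories\tannotation\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.fc:.6g}\t{r.log2fc:.6g}\t{r.direction}"
                f"\t{r.n_crtdre}\t{';'.join(r.categories)}\t{r.annotation}\n"
            )


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("term\tk\tn\tK\tM\tp\tp_adj\n")
        for e in results:
            fh.write(f"{e.term}\t{e.k}\t{e.n}\t{e.K}\t{e.M}\t{e.p:.6g}\t{e.p_adj:.6g}\n")
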