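"""Expression quantification: FPKM from fragment counts, winter/summer
fold changes, and qPCR relative expression by the 2^-ddCt method.

FPKM = c * 1e9 / (N * L) for c fragments on a gene of exonic length L bp
in a library of N total mapped fragments. Fold changes guard zero
expression with a floor (default 0.1 FPKM) applied to the ratio only,
so printed FPKM values are never modified. qPCR relative quantities
normalise the target Ct to a reference gene per replicate (dCt), then
to a calibrator sample (ddCt), and report RQ = 2^-ddCt; significance is
a two-sided Welch t-test on the replicate dCt values (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "FoldChange",
    "fpkm",
    "expression_matrix",
    "fold_change",
    "ddct",
    "read_counts_tsv",
    "read_qpcr_tsv",
]


@dataclass
class CountTable:
    """Genes x samples fragment counts with gene lengths and library sizes.

    ``counts``: integer DataFrame (index = gene ids, columns = samples);
    ``lengths``: per-gene exonic length in bp; ``totals``: per-sample
    total mapped fragments (library-wide, so they may exceed column
    sums).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = list(self.lengths[self.lengths.isna()].index[:3])
            raise ValueError(f"missing gene length for {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any() or (self.totals <= 0).any():
            raise ValueError("sample totals must be positive for every sample")


def fpkm(c: float, length_bp: float, total_fragments: float) -> float:
    """Fragments per kilobase of gene per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_fragments <= 0:
        raise ValueError("total mapped fragments must be positive")
    if c < 0:
        raise ValueError("count must be nonnegative")
    return c * 1e9 / (total_fragments * length_bp)


def expression_matrix(
    table: CountTable,
    log2: bool = False,
    zscore: bool = False,
) -> pd.DataFrame:
    """Element-wise FPKM; optionally log2(FPKM+1) and per-gene z-scaling
    (the heat-map export transform)."""
    m = table.counts.astype(float).mul(1e9)
    m = m.div(table.totals, axis=1).div(table.lengths, axis=0)
    if log2:
        m = np.log2(m + 1.0)
    if zscore:
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0).replace(0.0, 1.0)
        m = m.sub(mu, axis=0).div(sd, axis=0)
    return m


@dataclass(frozen=True)
class FoldChange:
    fc: float
    log2fc: float
    direction: str  # "up" | "down" | "unchanged"


def fold_change(
    fpkm_a: float,
    fpkm_b: float,
    floor: float = 0.1,
    threshold: float = 2.0,
) -> FoldChange:
    """Ratio of condition A over condition B with a zero-expression floor.

    fc = max(a, floor) / max(b, floor). Direction is "up" when
    fc >= threshold ("at least" threshold-fold, boundary inclusive),
    "down" when fc <= 1/threshold, else "unchanged".
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValueError("FPKM values must be nonnegative")
    fc = max(fpkm_a, floor) / max(fpkm_b, floor)
    log2fc = float(np.log2(fc))
    if fc >= threshold:
        direction = "up"
    elif fc <= 1.0 / threshold:
        direction = "down"
    else:
        direction = "unchanged"
    return FoldChange(fc=fc, log2fc=log2fc, direction=direction)


def ddct(qpcr: pd.DataFrame, calibrator: str, alpha: float = 0.05) -> pd.DataFrame:
    """2^-ddCt relative expression per sample.

    ``qpcr`` columns: sample, replicate, ct_target, ct_reference. Per
    replicate dCt = ct_target - ct_reference; ddCt subtracts the
    calibrator's mean dCt. The summary RQ is 2^(-mean ddCt) — so the
    calibrator's RQ is identically 1 — and ``se_rq`` is the SEM of the
    per-replicate RQs. Significance: Welch t of the sample's replicate
    dCt against the calibrator's (p < ``alpha``), requiring >= 2
    replicates on both sides.
    """
    required = {"sample", "replicate", "ct_target", "ct_reference"}
    if not required <= set(qpcr.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ct = qpcr.copy()
    if ((ct["ct_target"] <= 0) | (ct["ct_target"] >= 45)).any() or (
        (ct["ct_reference"] <= 0) | (ct["ct_reference"] >= 45)
    ).any():
        raise ValueError("Ct values must lie in (0, 45)")
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    if calibrator not in set(ct["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    cal_dct = ct.loc[ct["sample"] == calibrator, "dct"].to_numpy()
    cal_mean = float(cal_dct.mean())

    rows = []
    for sample, grp in ct.groupby("sample", sort=False):
        dd = grp["dct"].to_numpy() - cal_mean
        rqs = np.power(2.0, -dd)
        n = len(dd)
        if sample == calibrator:
            p = 1.0
        elif n >= 2 and len(cal_dct) >= 2:
            p = float(
                stats.ttest_ind(grp["dct"], cal_dct, equal_var=False).pvalue
            )
        else:
            raise ValueError(
                f"sample {sample!r}: significance testing needs >= 2 replicates"
            )
        rows.append(
            {
                "sample": sample,
                "n_replicates": n,
                "rq": float(2.0 ** (-dd.mean())),
                "se_rq": float(rqs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "mean_ddct": float(dd.mean()),
                "p_value": p,
                "significant": bool(p < alpha) and sample != calibrator,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def replicate_rq(qpcr: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-replicate RQ values (2^-ddCt for each replicate)."""
    ct = qpcr.copy()
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    cal_mean = float(ct.loc[ct["sample"] == calibrator, "dct"].mean())
    ct["ddct"] = ct["dct"] - cal_mean
    ct["rq"] = np.power(2.0, -ct["ddct"])
    return ct[["sample", "replicate", "dct", "ddct", "rq"]]


def read_counts_tsv(path: str | Path, totals_path: str | Path) -> CountTable:
    """Counts TSV (gene, length, one column per sample) plus a sidecar
    totals TSV (sample, total)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene" or df.columns[1] != "length":
        raise ValueError("counts TSV must start with 'gene' and 'length' columns")
    df = df.set_index("gene")
    totals = pd.read_csv(totals_path, sep="\t").set_index("sample")["total"]
    return CountTable(
        counts=df.drop(columns=["length"]).astype(int),
        lengths=df["length"].astype(float),
        totals=totals.astype(float),
    )


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """qPCR TSV with columns sample, replicate, ct_target, ct_reference."""
    return pd.read_csv(path, sep="\t")
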