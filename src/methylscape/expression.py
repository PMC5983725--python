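"""Methylation-expression association.

Covers: the DEG threshold filter (linear fold change >= 2 in either
direction and Q <= 0.01, both boundaries inclusive), expression grouping
(highest >= 10 RPKM; 1 < medium < 10; 0 < lowest <= 1; silent = 0),
rank-based methylation terciles per genic region, association of DMRs with
DEGs into Pro-methDEGs (DMR in the 2-kb upstream window) and Gb-methDEGs
(DMR in the gene body), and set comparison of methDEGs across time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FeatureIndex
from .calling import MethylationCallingResults

EXPRESSION_GROUPS = ("highest", "medium", "lowest", "silent")


def group_by_expression(expr: pd.DataFrame, rpkm_column: str = "rpkm_ctrl") -> pd.Series:
    """Assign each gene to an expression group by its RPKM.

    Boundary semantics: >= 10 highest; strictly between 1 and 10 medium;
    (0, 1] lowest; exactly 0 silent.  Negative RPKM is rejected.
    """
    rpkm = expr[rpkm_column].to_numpy(dtype=float)
    if (rpkm < 0).any():
        raise ValueError("negative RPKM encountered")
    group = np.select(
        [rpkm >= 10, rpkm > 1, rpkm > 0],
        ["highest", "medium", "lowest"],
        default="silent",
    )
    return pd.Series(group, index=expr["gene_id"].to_numpy(), name="group")


@dataclass
class Terciles:
    """Rank-based thirds of genes by a per-gene methylation level."""

    low: list[str]
    mid: list[str]
    high: list[str]
    degenerate: bool = False  # all levels equal; split is by stable id order only


def methylation_terciles(gene_levels: pd.Series | dict) -> Terciles:
    """Split genes into low/mid/high methylation thirds by rank.

    Ties (and the fully degenerate all-equal case) are broken by stable
    gene-id order; when the gene count is not divisible by 3, the lower
    groups absorb the extras (n = 10 -> sizes 4/3/3).
    """
    s = pd.Series(gene_levels).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 genes with defined levels")
    order = s.reset_index()
    order.columns = ["gene_id", "level"]
    order = order.sort_values(["level", "gene_id"], kind="mergesort")
    ids = order["gene_id"].tolist()
    n = len(ids)
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem == 2 else 0)
    return Terciles(
        low=ids[:n_low],
        mid=ids[n_low:n_low + n_mid],
        high=ids[n_low + n_mid:],
        degenerate=bool(s.nunique() == 1),
    )


def gene_region_levels(
    calls,
    index: FeatureIndex,
    region: str,
    context: str,
) -> pd.Series:
    """Mean per-site methylation level of one genic region, per gene.

    ``region`` is one of ``upstream`` (2 kb), ``gene_body``, ``exon``,
    ``intron``, ``downstream`` (2 kb); every covered cytosine of the given
    context in the region contributes level = meth/total.  Genes without
    covered sites are absent from the result.
    """
    df = calls.calls if isinstance(calls, MethylationCallingResults) else calls
    df = df[df["context"] == context]
    by_chrom = {
        chrom: sub.sort_values("pos") for chrom, sub in df.groupby("chrom", sort=False)
    }
    out: dict[str, float] = {}
    for g in index.annotation.genes:
        if g.chrom not in by_chrom:
            continue
        sub = by_chrom[g.chrom]
        pos0 = sub["pos"].to_numpy() - 1
        if region == "upstream":
            intervals = [index.upstream_interval(g, index.upstream_bp)]
        elif region == "downstream":
            intervals = [index.downstream_interval(g, index.downstream_bp)]
        elif region == "gene_body":
            intervals = [(g.start, g.end)]
        elif region == "exon":
            intervals = g.exons
        elif region == "intron":
            intervals = g.introns
        else:
            raise ValueError(f"unknown region {region!r}")
        levels = []
        L = index.chrom_lengths[g.chrom]
        for s, e in intervals:
            s, e = max(0, s), min(L, e)
            lo, hi = np.searchsorted(pos0, [s, e])
            if hi > lo:
                levels.append(sub["level"].to_numpy()[lo:hi])
        if levels:
            out[g.gene_id] = float(np.concatenate(levels).mean())
    return pd.Series(out, name=f"{region}_{context}_level")


def filter_degs(
    expr: pd.DataFrame,
    min_fold: float = 2.0,
    max_q: float = 0.01,
) -> pd.DataFrame:
    """Apply the DEG threshold filter: fold change >= 2 and Q <= 0.01.

    ``fold_change`` is a linear treatment/control ratio; the magnitude in
    either direction is thresholded (ratio >= 2 or <= 1/2).  Returns the
    passing rows with a ``deg_status`` column (``up``/``down``).
    """
    for col in ("fold_change", "q_value"):
        if col not in expr.columns:
            raise ValueError(f"expression table lacks required column {col!r}")
    fc = expr["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(fc >= 1.0, fc, 1.0 / fc)
    passing = (
        np.isfinite(fc) & (fc > 0) & (mag >= min_fold)
        & (expr["q_value"].to_numpy(dtype=float) <= max_q)
    )
    out = expr[passing].copy()
    out["deg_status"] = np.where(out["fold_change"] >= 1.0, "up", "down")
    return out


def associate_dmr_deg(
    dmrs: pd.DataFrame,
    degs: pd.DataFrame,
    index: FeatureIndex,
    upstream_window: int = 2000,
    condition: str = "",
) -> pd.DataFrame:
    """Link DMRs to DEGs of the same comparison into methDEG records.

    A DMR overlapping (>= 1 bp) a DEG's strand-aware upstream window yields
    a Pro-methDEG record (``region='upstream'``); overlapping the gene body
    yields a Gb-methDEG record (``region='gene_body'``).  One gene can
    yield both.  Columns: gene_id, region, chrom, dmr_start, dmr_end,
    context, dmr_direction, deg_direction, condition.
    """
    deg_dir = dict(zip(degs["gene_id"], degs["deg_status"]))
    rows = []
    for r in dmrs.itertuples(index=False):
        for region, kind in (("upstream", "upstream"), ("gene_body", "gene_body")):
            for gid in index.genes_overlapping(r.chrom, int(r.start), int(r.end), kind):
                if gid not in deg_dir:
                    continue
                rows.append(
                    (gid, region, r.chrom, int(r.start), int(r.end),
                     r.context, r.direction, deg_dir[gid], condition)
                )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "region", "chrom", "dmr_start", "dmr_end",
                 "context", "dmr_direction", "deg_direction", "condition"],
    )
    return out.drop_duplicates(ignore_index=True)


def methdeg_crosstab(methdegs: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate methDEG records by context, DMR and DEG direction."""
    if len(methdegs) == 0:
        return pd.DataFrame(
            columns=["region", "context", "dmr_direction", "deg_direction", "n_genes"]
        )
    g = (
        methdegs.groupby(["region", "context", "dmr_direction", "deg_direction"])
        ["gene_id"].nunique().reset_index(name="n_genes")
    )
    return g


def compare_time_points(
    methdegs_t1: pd.DataFrame | set,
    methdegs_t2: pd.DataFrame | set,
) -> dict[str, set[str]]:
    """Unique and shared methDEG gene ids between two sampling times."""
    def _ids(x):
        if isinstance(x, pd.DataFrame):
            return set(x["gene_id"])
        return set(x)

    s1, s2 = _ids(methdegs_t1), _ids(methdegs_t2)
    return {
        "unique_t1": s1 - s2,
        "unique_t2": s2 - s1,
        "shared": s1 & s2,
    }


def electrolyte_leakage(r1: float, r2: float) -> float:
    """Relative electrolyte leakage E = 100 * R1 / R2 (conductivities)."""
    if r2 <= 0:
        raise ValueError("total conductivity R2 must be positive")
    if r1 < 0 or r1 > r2:
        raise ValueError("initial conductivity R1 must satisfy 0 <= R1 <= R2")
    return 100.0 * r1 / r2
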