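"""Windowed Fisher-exact detection of differentially methylated regions.

Chromosomes are tiled into windows (default 200 bp, non-overlapping) and,
within each window, methylated/unmethylated read counts of one sequence
context are pooled over the cytosine sites covered in both samples.  A
window is eligible when it contains at least ``min_sites`` context sites;
eligible windows are tested with a two-tailed Fisher exact test on the
2x2 table [[meth_a, unmeth_a], [meth_b, unmeth_b]].  A DMR is an eligible
window with a fold change of at least ``min_fold`` between the two pooled
methylation levels and a Fisher p-value below ``p_threshold`` (default
1e-20, applied to the raw p-value; BH-adjusted q-values are reported
alongside).  Adjacent or overlapping passing windows of the same direction
are merged into maximal runs by default; ``hyper`` means a higher level in
the treatment (sample b).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import MethylationCallingResults
from .contexts import CONTEXTS

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context", "n_sites",
    "meth_a", "unmeth_a", "meth_b", "unmeth_b", "level_a", "level_b",
]


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, MethylationCallingResults):
        return calls.calls
    return calls


def fold_change(level_a: float, level_b: float) -> float:
    """Ratio of the larger to the smaller methylation level.

    Infinite when exactly one level is zero; 1 when both are zero.
    """
    lo, hi = min(level_a, level_b), max(level_a, level_b)
    if hi == 0.0:
        return 1.0
    if lo == 0.0:
        return math.inf
    return hi / lo


def fisher_two_tailed_pvalues(n: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed Fisher exact p-values for every table with the given margins.

    For a 2x2 table [[a, b], [c, d]] with total ``n``, first-row sum
    ``row1`` and first-column sum ``col1``, the cell ``a`` ranges over the
    hypergeometric support; the two-tailed p-value of each ``a`` is the sum
    of the probabilities of all tables at the same margins that are no more
    probable than the observed one (the convention of R's ``fisher.test``,
    with a 1e-7 relative tie tolerance absorbing float rounding).  Returns
    ``(support, pvalues)``.  Computing the whole support at once is what
    makes window scans and exhaustive enumerations cheap.
    """
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    order = np.argsort(pmf, kind="mergesort")
    csum = np.cumsum(pmf[order])
    # rank of the largest pmf still counted as "no more probable" than each a
    idx = np.searchsorted(pmf[order], pmf * (1 + 1e-7), side="right") - 1
    # a table whose tail includes the whole support has p exactly 1
    pvals = np.where(idx == len(support) - 1, 1.0, np.minimum(csum[idx], 1.0))
    return support, pvals


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p-value of one 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    support, pvals = fisher_two_tailed_pvalues(n, a + b, a + c)
    return float(pvals[a - support[0]])


def test_window(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> tuple[float, float]:
    """Fold change and two-tailed Fisher exact p for one window's 2x2 table."""
    tot_a, tot_b = meth_a + unmeth_a, meth_b + unmeth_b
    if tot_a == 0 and tot_b == 0:
        return 1.0, 1.0
    level_a = meth_a / tot_a if tot_a else 0.0
    level_b = meth_b / tot_b if tot_b else 0.0
    p = fisher_two_tailed(meth_a, unmeth_a, meth_b, unmeth_b)
    return fold_change(level_a, level_b), p


def make_windows(
    calls_a,
    calls_b,
    context: str,
    window_size: int = 200,
    step: int = 200,
    chrom_lengths: dict[str, int] | None = None,
    allow_gaps: bool = False,
) -> pd.DataFrame:
    """Pool context-site read counts of two samples into genomic windows.

    Only sites covered in both samples contribute.  Windows start at
    multiples of ``step`` and span ``window_size`` bp (0-based half-open);
    ``window_size < step`` leaves uncovered gaps and must be enabled with
    ``allow_gaps``.  Returns a frame with :data:`WINDOW_COLUMNS`, one row
    per window containing at least one shared site.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if window_size < step and not allow_gaps:
        raise ValueError("window_size < step leaves gaps; pass allow_gaps=True to permit")
    a = _calls_frame(calls_a)
    b = _calls_frame(calls_b)
    a = a[a["context"] == context]
    b = b[b["context"] == context]
    j = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"),
        validate="one_to_one",
    )
    if len(j) == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    pos0 = j["pos"].to_numpy() - 1
    n_off = -(-window_size // step)  # windows covering any given position
    parts = []
    for off in range(n_off):
        w = pos0 // step - off
        keep = (w >= 0) & (w * step + window_size > pos0)
        if not keep.any():
            continue
        part = j[keep].copy()
        part["_w"] = w[keep]
        parts.append(part)
    stacked = pd.concat(parts, ignore_index=True)
    g = stacked.groupby(["chrom", "_w"], as_index=False).agg(
        n_sites=("pos", "size"),
        meth_a=("meth_reads_a", "sum"),
        total_a=("total_reads_a", "sum"),
        meth_b=("meth_reads_b", "sum"),
        total_b=("total_reads_b", "sum"),
    )
    g["start"] = g["_w"] * step
    g["end"] = g["start"] + window_size
    if chrom_lengths:
        g["end"] = np.minimum(g["end"], g["chrom"].map(chrom_lengths))
    g["context"] = context
    g["unmeth_a"] = g["total_a"] - g["meth_a"]
    g["unmeth_b"] = g["total_b"] - g["meth_b"]
    g["level_a"] = g["meth_a"] / g["total_a"]
    g["level_b"] = g["meth_b"] / g["total_b"]
    return (
        g[WINDOW_COLUMNS]
        .sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    )


class DmrModel:
    """Two-sample windowed DMR model for one sequence context.

    Parameters
    ----------
    calls_control, calls_treatment
        Merged-replicate call sets (:class:`MethylationCallingResults` or
        plain call frames) of the two conditions; ``hyper`` direction means
        a higher level in the treatment.
    context
        ``CG``, ``CHG`` or ``CHH``; contexts are tested independently.
    """

    def __init__(
        self,
        calls_control,
        calls_treatment,
        context: str,
        window_size: int = 200,
        step: int = 200,
        min_sites: int = 5,
        min_fold: float = 2.0,
        p_threshold: float = 1e-20,
        merge_adjacent: bool = True,
        chrom_lengths: dict[str, int] | None = None,
        allow_gaps: bool = False,
    ) -> None:
        if not 0.0 < p_threshold <= 1.0:
            raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
        if min_fold < 1.0:
            raise ValueError(f"min_fold must be >= 1, got {min_fold}")
        if min_sites < 1:
            raise ValueError(f"min_sites must be >= 1, got {min_sites}")
        self.calls_control = calls_control
        self.calls_treatment = calls_treatment
        self.context = context
        self.window_size = window_size
        self.step = step
        self.min_sites = min_sites
        self.min_fold = min_fold
        self.p_threshold = p_threshold
        self.merge_adjacent = merge_adjacent
        self.chrom_lengths = chrom_lengths
        self.allow_gaps = allow_gaps

    def fit(self) -> "DmrResults":
        windows = make_windows(
            self.calls_control, self.calls_treatment, self.context,
            self.window_size, self.step, self.chrom_lengths, self.allow_gaps,
        )
        windows["eligible"] = windows["n_sites"] >= self.min_sites
        windows["fold"] = np.nan
        windows["p_value"] = np.nan
        windows["q_value"] = np.nan
        elig = windows.index[windows["eligible"]]
        folds, pvals = [], []
        for i in elig:
            r = windows.loc[i]
            f, p = test_window(
                int(r["meth_a"]), int(r["unmeth_a"]), int(r["meth_b"]), int(r["unmeth_b"])
            )
            folds.append(f)
            pvals.append(p)
        if len(elig):
            windows.loc[elig, "fold"] = folds
            windows.loc[elig, "p_value"] = pvals
            _, q, *_ = multipletests(pvals, method="fdr_bh")
            windows.loc[elig, "q_value"] = q
        passing = (
            windows["eligible"]
            & (windows["p_value"] < self.p_threshold)
            & (windows["fold"] >= self.min_fold)
        )
        windows["is_dmr"] = passing.fillna(False)
        windows["direction"] = np.where(
            windows["level_b"] > windows["level_a"], "hyper", "hypo"
        )
        unmerged = windows[windows["is_dmr"]].copy()
        merged = _merge_runs(unmerged) if self.merge_adjacent else unmerged.copy()
        return DmrResults(self, windows, merged, unmerged)


def _merge_runs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent/overlapping same-direction DMR windows into maximal runs."""
    if len(dmrs) == 0:
        return dmrs.copy()
    rows = []
    for (chrom, direction), sub in dmrs.groupby(["chrom", "direction"], sort=True):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start <= cur["end"]:
                cur["end"] = max(cur["end"], r.end)
                for k in ("meth_a", "unmeth_a", "meth_b", "unmeth_b", "n_sites"):
                    cur[k] += getattr(r, k)
                cur["p_value"] = min(cur["p_value"], r.p_value)
                cur["q_value"] = min(cur["q_value"], r.q_value)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom, "start": r.start, "end": r.end,
                    "context": r.context, "direction": direction,
                    "n_sites": r.n_sites, "n_windows": 1,
                    "meth_a": r.meth_a, "unmeth_a": r.unmeth_a,
                    "meth_b": r.meth_b, "unmeth_b": r.unmeth_b,
                    "p_value": r.p_value, "q_value": r.q_value,
                }
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows)
    out["level_a"] = out["meth_a"] / (out["meth_a"] + out["unmeth_a"])
    out["level_b"] = out["meth_b"] / (out["meth_b"] + out["unmeth_b"])
    out["fold"] = [fold_change(a, b) for a, b in zip(out["level_a"], out["level_b"])]
    return out.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


class DmrResults:
    """Windows, tests and called DMRs of one two-sample comparison.

    Attributes
    ----------
    windows
        Every window with pooled counts, eligibility, fold, p and BH q.
    dmrs
        Called DMRs with adjacent same-direction windows merged (the
        default report); ``dmrs_unmerged`` keeps the raw window calls.
    """

    def __init__(self, model: DmrModel, windows: pd.DataFrame,
                 dmrs: pd.DataFrame, dmrs_unmerged: pd.DataFrame) -> None:
        self.model = model
        self.context = model.context
        self.windows = windows
        self.dmrs = dmrs
        self.dmrs_unmerged = dmrs_unmerged

    def assign_categories(self, index) -> pd.DataFrame:
        """Label each merged DMR with its five-way genomic category."""
        cats = [
            index.dmr_category(r.chrom, int(r.start), int(r.end))
            for r in self.dmrs.itertuples(index=False)
        ]
        self.dmrs = self.dmrs.assign(category=cats)
        return self.dmrs

    def summary(self) -> str:
        n_hyper = int((self.dmrs["direction"] == "hyper").sum()) if len(self.dmrs) else 0
        n_hypo = len(self.dmrs) - n_hyper
        lines = [
            f"DMR analysis ({self.context}): window={self.model.window_size} "
            f"step={self.model.step} min_sites={self.model.min_sites} "
            f"min_fold={self.model.min_fold} p<{self.model.p_threshold:g}",
            f"  windows: {len(self.windows)} total, "
            f"{int(self.windows['eligible'].sum())} eligible",
            f"  DMRs (merged runs): {len(self.dmrs)} "
            f"({n_hyper} hyper, {n_hypo} hypo)",
            f"  DMR windows (unmerged): {len(self.dmrs_unmerged)}",
        ]
        if "category" in self.dmrs.columns and len(self.dmrs):
            counts = self.dmrs["category"].value_counts()
            lines.append("  categories: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        """Write merged DMRs as BED6+ (0-based half-open)."""
        with open(path, "w") as fh:
            for r in self.dmrs.itertuples(index=False):
                score = min(1000, int(round(-math.log10(max(r.p_value, 1e-300)))))
                extra = [
                    f"{r.level_a:.4f}", f"{r.level_b:.4f}",
                    "inf" if math.isinf(r.fold) else f"{r.fold:.4f}",
                    f"{r.q_value:.3e}", r.direction,
                ]
                if hasattr(r, "category"):
                    extra.append(r.category)
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.context}\t{score}\t.\t"
                    + "\t".join(extra) + "\n"
                )
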