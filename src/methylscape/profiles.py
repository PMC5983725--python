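"""Methylome summaries: global levels, proportion reports, metaplots.

Percentages in the reports are rounded half-up to the requested number of
decimals (matching how such tables are printed), via exact decimal
arithmetic rather than binary-float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureIndex
from .calling import MethylationCallingResults
from .contexts import CONTEXTS


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, MethylationCallingResults):
        return calls.calls
    return calls


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01 at two decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------------
# proportion reports
# ----------------------------------------------------------------------

@dataclass
class ProportionReport:
    """Labelled counts with percentages of a stated denominator."""

    table: pd.DataFrame  # columns: label, count, percentage
    denominator: int
    denominator_description: str
    decimals: int = 2

    def __getitem__(self, label: str) -> float:
        row = self.table[self.table["label"] == label]
        if len(row) == 0:
            raise KeyError(label)
        return float(row["percentage"].iloc[0])

    def percentage(self, label: str, decimals: int | None = None) -> float:
        """Percentage for one label, optionally re-rounded to ``decimals``."""
        row = self.table[self.table["label"] == label]
        if len(row) == 0:
            raise KeyError(label)
        raw = 100.0 * int(row["count"].iloc[0]) / self.denominator
        return round_half_up(raw, self.decimals if decimals is None else decimals)

    def summary(self) -> str:
        lines = [f"Proportions of {self.denominator_description} (n={self.denominator}):"]
        for r in self.table.itertuples(index=False):
            lines.append(f"  {r.label}: {r.count} ({r.percentage:.{self.decimals}f}%)")
        return "\n".join(lines)


def proportion_report(
    counts: Mapping[str, int],
    denominator_description: str,
    decimals: int = 2,
) -> ProportionReport:
    """Build a :class:`ProportionReport` from labelled counts.

    The denominator is the sum of the counts; each percentage is
    ``100 * count / denominator`` rounded half-up to ``decimals``.
    """
    denom = int(sum(counts.values()))
    if denom == 0:
        raise ValueError("cannot report proportions of an empty count set")
    rows = [
        (label, int(c), round_half_up(100.0 * c / denom, decimals))
        for label, c in counts.items()
    ]
    return ProportionReport(
        pd.DataFrame(rows, columns=["label", "count", "percentage"]),
        denom, denominator_description, decimals,
    )


def global_levels(calls) -> pd.DataFrame:
    """Per-context mean methylation level over called mC sites.

    ``mean_level`` is the unweighted mean of per-site levels; the
    read-weighted alternative (pooled meth/total) is reported as a
    secondary column.  Contexts with no mC sites appear with NaN, not 0.
    """
    df = _calls_frame(calls)
    mc = df[df["called"]] if "called" in df.columns else df
    rows = []
    for ctx in CONTEXTS:
        sub = mc[mc["context"] == ctx]
        if len(sub) == 0:
            rows.append((ctx, 0, np.nan, np.nan))
        else:
            rows.append(
                (ctx, len(sub), float(sub["level"].mean()),
                 float(sub["meth_reads"].sum() / sub["total_reads"].sum()))
            )
    return pd.DataFrame(rows, columns=["context", "n_sites", "mean_level", "weighted_level"])


def context_proportions(calls, decimals: int = 2) -> ProportionReport:
    """Share of called mC sites in each context (CG/CHG/CHH)."""
    df = _calls_frame(calls)
    mc = df[df["called"]] if "called" in df.columns else df
    counts = {ctx: int((mc["context"] == ctx).sum()) for ctx in CONTEXTS}
    return proportion_report(counts, "mC sites by context", decimals)


def region_proportions(
    assignments: pd.DataFrame,
    per_context: bool = False,
    decimals: int = 2,
) -> ProportionReport | dict[str, ProportionReport]:
    """Share of mC sites per genomic category.

    ``assignments`` needs a ``category`` column and, for the per-context
    report, a ``context`` column.  With ``per_context=True`` a report is
    returned for each context, whose denominator is that context's site
    total.
    """
    if not per_context:
        counts = assignments["category"].value_counts().to_dict()
        return proportion_report(counts, "mC sites by genomic category", decimals)
    out: dict[str, ProportionReport] = {}
    for ctx in CONTEXTS:
        sub = assignments[assignments["context"] == ctx]
        if len(sub) == 0:
            continue
        counts = sub["category"].value_counts().to_dict()
        out[ctx] = proportion_report(counts, f"m{ctx} sites by genomic category", decimals)
    return out


# ----------------------------------------------------------------------
# metaplot
# ----------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Average methylation profile over aligned genes or TEs.

    ``table`` has one row per (context, segment, bin): segments are
    ``upstream`` (5' flank, bins ordered towards the feature), ``body``
    (length-normalised into ``body_bins`` bins) and ``downstream`` (3'
    flank, bins ordered away from the feature).  Minus-strand features are
    reversed so the profile is always 5'->3'.
    """

    feature_class: str
    flank: int
    window: int
    step: int
    body_bins: int
    table: pd.DataFrame  # context, segment, bin, mean_level, n_sites
    n_features: int
    n_skipped: int

    @property
    def flank_bins(self) -> int:
        return self.flank // self.step

    def values(self, context: str, segment: str) -> np.ndarray:
        sub = self.table[
            (self.table["context"] == context) & (self.table["segment"] == segment)
        ].sort_values("bin")
        return sub["mean_level"].to_numpy()


def metaplot(
    calls,
    index: FeatureIndex,
    feature_class: str = "gene",
    flank: int = 2000,
    window: int = 50,
    step: int = 50,
    body_bins: int = 40,
    mc_only: bool = False,
) -> MetaProfile:
    """Sliding-window metaplot across all genes or all TEs.

    Flanks are tiled in fixed ``window``-bp bins (40 per 2-kb flank at the
    50/50 default); bodies are split into ``body_bins`` proportional bins.
    Each bin's value is the mean of per-site levels over all contributing
    sites across all features.  By default every covered cytosine
    contributes level = meth/total; with ``mc_only`` only called mC sites
    contribute.  Features shorter than ``body_bins`` bp are skipped (their
    count is reported on the profile).
    """
    if window != step:
        raise NotImplementedError("flank tiling currently requires window == step")
    df = _calls_frame(calls)
    if mc_only and "called" in df.columns:
        df = df[df["called"]]
    flank_bins = flank // step

    if feature_class == "gene":
        feats = [(g.chrom, g.start, g.end, g.strand) for g in index.annotation.genes]
    elif feature_class in ("te", "TE"):
        feats = [(t.chrom, t.start, t.end, t.strand) for t in index.annotation.tes]
    else:
        raise ValueError("feature_class must be 'gene' or 'te'")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub["pos"].to_numpy() - 1,
            sub["level"].to_numpy(dtype=float),
            sub["context"].to_numpy(),
        )

    sums = {ctx: {seg: np.zeros(nb) for seg, nb in
                  (("upstream", flank_bins), ("body", body_bins), ("downstream", flank_bins))}
            for ctx in CONTEXTS}
    counts = {ctx: {seg: np.zeros(nb, dtype=int) for seg, nb in
                    (("upstream", flank_bins), ("body", body_bins), ("downstream", flank_bins))}
              for ctx in CONTEXTS}

    n_skipped = 0
    for chrom, start, end, strand in feats:
        if chrom not in by_chrom:
            continue
        if end - start < body_bins:
            n_skipped += 1
            continue
        pos0, level, ctxs = by_chrom[chrom]
        L = index.chrom_lengths[chrom]
        if strand == "+":
            segments = (
                ("upstream", max(0, start - flank), start, start - flank, False),
                ("body", start, end, start, None),
                ("downstream", end, min(L, end + flank), end, False),
            )
        else:
            segments = (
                ("upstream", end, min(L, end + flank), end, True),
                ("body", start, end, start, None),
                ("downstream", max(0, start - flank), start, start - flank, True),
            )
        for seg, s, e, origin, flip in segments:
            if e <= s:
                continue
            lo, hi = np.searchsorted(pos0, [s, e])
            if hi <= lo:
                continue
            p = pos0[lo:hi]
            if seg == "body":
                rel = (p - start) / (end - start)
                bins = np.minimum((rel * body_bins).astype(int), body_bins - 1)
                if strand == "-":
                    bins = body_bins - 1 - bins
            else:
                bins = (p - origin) // step
                if flip:
                    # minus strand: genomic right is the feature's 5' side
                    bins = flank_bins - 1 - bins
                bins = np.clip(bins, 0, flank_bins - 1)
            for ctx in CONTEXTS:
                m = ctxs[lo:hi] == ctx
                if not m.any():
                    continue
                np.add.at(sums[ctx][seg], bins[m], level[lo:hi][m])
                np.add.at(counts[ctx][seg], bins[m], 1)

    rows = []
    for ctx in CONTEXTS:
        for seg, nb in (("upstream", flank_bins), ("body", body_bins), ("downstream", flank_bins)):
            for b in range(nb):
                c = counts[ctx][seg][b]
                mean = sums[ctx][seg][b] / c if c else np.nan
                rows.append((ctx, seg, b, mean, int(c)))
    table = pd.DataFrame(rows, columns=["context", "segment", "bin", "mean_level", "n_sites"])
    return MetaProfile(
        feature_class="gene" if feature_class == "gene" else "te",
        flank=flank, window=window, step=step, body_bins=body_bins,
        table=table, n_features=len(feats), n_skipped=n_skipped,
    )
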