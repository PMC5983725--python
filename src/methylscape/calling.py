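"""Binomial methylcytosine calling calibrated on an unmethylated spike-in.

The probability that a truly unmethylated cytosine reads as methylated (the
*error rate*: bisulfite nonconversion plus sequencing error) is estimated
as the pooled methylated-read fraction over all spike-in cytosines.  Each
genomic cytosine with ``k`` methylated of ``n`` total reads is then tested
against Binomial(n, error_rate): the p-value is the upper tail
P(X >= k), Benjamini-Hochberg adjusted separately within each sequence
context, and a site is called methylated when its q-value falls below the
FDR threshold (default 0.01).

Biological replicates are merged under a coverage/consistency rule: a site
is retained only if it is covered at >= 10 reads in both replicates and the
methylated/unmethylated determination agrees between them; retained counts
are summed and the level recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contexts import CONTEXTS

_SITE_KEY = ["chrom", "pos", "strand"]
CALL_COLUMNS = [
    "chrom", "pos", "strand", "context", "meth_reads", "total_reads",
    "level", "p_value", "q_value", "called",
]


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Pooled error rate from spike-in cytosines.

    rate = sum(meth_reads) / sum(total_reads); ``n_sites`` and ``n_reads``
    record the evidence behind the estimate.
    """

    rate: float
    n_sites: int
    n_reads: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"error rate must be in [0, 1), got {self.rate}")


def estimate_error_rate(spike_in_records: pd.DataFrame) -> ErrorRateEstimate:
    """Estimate the conversion error rate from spike-in count records.

    Raises ``ValueError`` on empty input or zero total reads: calling must
    not proceed uncalibrated.
    """
    if len(spike_in_records) == 0:
        raise ValueError("no spike-in records: cannot estimate the error rate")
    total = int(spike_in_records["total_reads"].sum())
    meth = int(spike_in_records["meth_reads"].sum())
    if total == 0:
        raise ValueError("spike-in records carry zero total reads")
    return ErrorRateEstimate(rate=meth / total, n_sites=len(spike_in_records), n_reads=total)


class MethylationCallingModel:
    """Binomial mC-calling model for one sample's count table.

    Parameters
    ----------
    counts
        Per-cytosine table with columns
        ``chrom pos strand context meth_reads total_reads``.  Rows on the
        spike-in chromosome (matched by name) calibrate the error rate and
        are excluded from genome-wide calls.
    spike_in_name
        Chromosome name of the unmethylated spike-in.  Ignored when
        ``error_rate`` is given explicitly.
    error_rate
        Optional pre-computed :class:`ErrorRateEstimate`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        spike_in_name: str = "lambda",
        error_rate: ErrorRateEstimate | None = None,
        sample_id: str = "sample",
        condition: str = "condition",
    ) -> None:
        required = {"chrom", "pos", "strand", "context", "meth_reads", "total_reads"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (counts["meth_reads"] > counts["total_reads"]).any():
            raise ValueError("meth_reads exceeds total_reads in count table")
        self.counts = counts
        self.spike_in_name = spike_in_name
        self.sample_id = sample_id
        self.condition = condition
        spike_mask = counts["chrom"] == spike_in_name
        self.spike_in = counts[spike_mask]
        self.genomic = counts[~spike_mask & counts["context"].isin(CONTEXTS)]
        self._error_rate = error_rate

    def fit(self, fdr: float = 0.01) -> "MethylationCallingResults":
        """Call methylcytosines at the given BH-FDR threshold."""
        if not 0.0 < fdr < 1.0:
            raise ValueError(f"fdr must be in (0, 1), got {fdr}")
        error = self._error_rate or estimate_error_rate(self.spike_in)
        df = self.genomic.copy().reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no genomic cytosine records to call")
        k = df["meth_reads"].to_numpy()
        n = df["total_reads"].to_numpy()
        # upper-tail P(X >= k); sf(k-1) is exact for integer k
        df["level"] = k / n
        df["p_value"] = stats.binom.sf(k - 1, n, error.rate)
        df["q_value"] = np.nan
        df["called"] = False
        # contexts are considered independently: BH within each context
        for ctx in CONTEXTS:
            mask = (df["context"] == ctx).to_numpy()
            if not mask.any():
                continue
            rejected, q, *_ = multipletests(
                df.loc[mask, "p_value"].to_numpy(), alpha=fdr, method="fdr_bh"
            )
            df.loc[mask, "q_value"] = q
            df.loc[mask, "called"] = rejected
        return MethylationCallingResults(
            calls=df[CALL_COLUMNS],
            error_rate=error,
            fdr=fdr,
            sample_id=self.sample_id,
            condition=self.condition,
        )


class MethylationCallingResults:
    """Per-site methylation calls with calibration diagnostics.

    Attributes
    ----------
    calls
        DataFrame with columns :data:`CALL_COLUMNS`; ``level`` is
        meth_reads/total_reads, ``q_value`` the BH-adjusted p-value within
        the site's context, ``called`` the mC determination.
    error_rate
        The :class:`ErrorRateEstimate` used.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        error_rate: ErrorRateEstimate,
        fdr: float,
        sample_id: str = "sample",
        condition: str = "condition",
    ) -> None:
        self.calls = calls
        self.error_rate = error_rate
        self.fdr = fdr
        self.sample_id = sample_id
        self.condition = condition

    @property
    def mc_sites(self) -> pd.DataFrame:
        """Only the sites called methylated."""
        return self.calls[self.calls["called"]]

    def expected_false_positive_fraction(self) -> float:
        """Expected FP fraction among calls: sum of called p-values / #calls.

        Under the error model, a called site's p-value is its probability of
        arising from an unmethylated cytosine, so the sum over called sites
        bounds the expected number of false mC calls.  Returns NaN when
        nothing is called.
        """
        called = self.mc_sites
        if len(called) == 0:
            return float("nan")
        return float(called["p_value"].sum() / len(called))

    @property
    def false_positive_flag(self) -> bool:
        """True when the expected FP fraction among calls exceeds 1%."""
        f = self.expected_false_positive_fraction()
        return bool(f > 0.01) if np.isfinite(f) else False

    def summary(self) -> str:
        lines = [
            f"Methylcytosine calls: sample={self.sample_id} condition={self.condition}",
            f"  error rate: {self.error_rate.rate:.6f} "
            f"({self.error_rate.n_reads} spike-in reads, {self.error_rate.n_sites} sites)",
            f"  FDR threshold: {self.fdr}",
        ]
        for ctx in CONTEXTS:
            sub = self.calls[self.calls["context"] == ctx]
            if len(sub) == 0:
                continue
            nc = int(sub["called"].sum())
            lines.append(
                f"  {ctx}: {nc} mC of {len(sub)} covered sites "
                f"({100 * nc / len(sub):.2f}%)"
            )
        fp = self.expected_false_positive_fraction()
        lines.append(
            f"  expected FP fraction among calls: {fp:.4f}"
            + ("  [WARNING: exceeds 1%]" if self.false_positive_flag else "")
        )
        return "\n".join(lines)


def merge_replicates(
    rep1: MethylationCallingResults,
    rep2: MethylationCallingResults,
    min_coverage: int = 10,
) -> MethylationCallingResults:
    """Merge two biological replicates under the coverage/consistency rule.

    A site is kept only when present in both replicates with
    ``total_reads >= min_coverage`` in each and the same mC determination.
    Kept counts are summed, the level recomputed from the summed counts, and
    the more conservative (larger) p/q of the two replicates carried over.
    """
    a, b = rep1.calls, rep2.calls
    if not (set(a["chrom"]) & set(b["chrom"])):
        raise ValueError("replicate call sets share no chromosomes: mismatched builds?")
    merged = a.merge(b, on=_SITE_KEY + ["context"], suffixes=("_1", "_2"))
    ok = (
        (merged["total_reads_1"] >= min_coverage)
        & (merged["total_reads_2"] >= min_coverage)
        & (merged["called_1"] == merged["called_2"])
    )
    merged = merged[ok]
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "strand": merged["strand"],
            "context": merged["context"],
            "meth_reads": merged["meth_reads_1"] + merged["meth_reads_2"],
            "total_reads": merged["total_reads_1"] + merged["total_reads_2"],
            "p_value": np.maximum(merged["p_value_1"], merged["p_value_2"]),
            "q_value": np.maximum(merged["q_value_1"], merged["q_value_2"]),
            "called": merged["called_1"],
        }
    )
    out["level"] = out["meth_reads"] / out["total_reads"]
    out = out[CALL_COLUMNS].sort_values(_SITE_KEY, kind="mergesort", ignore_index=True)
    return MethylationCallingResults(
        calls=out,
        error_rate=rep1.error_rate,
        fdr=rep1.fdr,
        sample_id=f"{rep1.sample_id}+{rep2.sample_id}",
        condition=rep1.condition,
    )


def merge_symmetric_cg(calls: pd.DataFrame) -> pd.DataFrame:
    """Optionally pool the two strands of each symmetric CpG dyad.

    The plus-strand C at position p and the minus-strand C at p+1 belong to
    the same CpG; their counts are summed into one record reported at the
    plus-strand position.  Non-CG records and unpaired CG sites pass
    through unchanged.  Off by default in the pipeline; strand cytosines
    are otherwise treated as independent sites.
    """
    cg = calls[calls["context"] == "CG"].copy()
    other = calls[calls["context"] != "CG"]
    cg["dyad"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    grouped = (
        cg.groupby(["chrom", "dyad"], as_index=False)
        .agg(meth_reads=("meth_reads", "sum"), total_reads=("total_reads", "sum"))
        .rename(columns={"dyad": "pos"})
    )
    grouped["strand"] = "+"
    grouped["context"] = "CG"
    grouped["level"] = grouped["meth_reads"] / grouped["total_reads"]
    keep = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads", "level"]
    out = pd.concat([grouped[keep], other[keep]], ignore_index=True)
    return out.sort_values(_SITE_KEY, kind="mergesort", ignore_index=True)
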